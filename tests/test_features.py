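"""Feature-table assembly and co-correlation pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from arcvir.features import (
    FEATURE_NAMES,
    FeatureTable,
    build_feature_table,
    compute_features,
    prune_correlated,
)
from arcvir.homology import HitRecord, summarize_hits
from arcvir.seqio import Contig, OrfRecord


def _hit(orf, target="t", evalue=1e-8, bitscore=100.0, cls="archaeal_virus", db="protein_nr"):
    return HitRecord(orf, orf.rsplit("_", 1)[0], target, evalue, bitscore, cls, db)


def _mini_dataset():
    c1 = Contig("c1", "A" * 10_000)
    c2 = Contig("c2", "A" * 8_000)
    orfs = {
        "c1": [
            OrfRecord("c1", "c1_1", 1, 300, 1),
            OrfRecord("c1", "c1_2", 401, 1000, -1),
            OrfRecord("c1", "c1_3", 2001, 2900, 1),
        ],
        "c2": [OrfRecord("c2", "c2_1", 1, 600, 1)],
    }
    hits = [
        _hit("c1_1", "ta", 1e-8, 100.0, "archaeal_virus"),
        _hit("c1_1", "tb", 1e-7, 90.0, "phage"),
        _hit("c1_2", "tc", 1e-9, 80.0, "phage"),
        _hit("c1_2", "VOG1", 1e-12, 60.0, "phage", "pvog_hmm"),
        _hit("c1_1", "oc1", 1e-9, 70.0, "archaeal_virus", "ocav_profile"),
        _hit("c1_1", "oc2", 1e-9, 65.0, "archaeal_virus", "ocav_profile"),
    ]
    return [c1, c2], orfs, hits


def test_table_shape_and_row_ids():
    contigs, orfs, hits = _mini_dataset()
    table = compute_features(contigs, orfs, hits)
    assert table.data.shape == (2, 27)
    assert list(table.data.index) == ["c1", "c2"]
    assert list(table.data.columns) == FEATURE_NAMES
    assert not table.data.isna().any().any()


def test_feature_values_match_hand_computation():
    """Every feature of the fixture contig equals an independent recomputation."""
    contigs, orfs, hits = _mini_dataset()
    row = compute_features(contigs, orfs, hits).data.loc["c1"]
    # genomic attributes: lengths {300, 600, 900}; strands +,-,+; gaps 100, 1000
    assert row["mean_gene_length"] == pytest.approx(600)
    assert row["median_gene_length"] == pytest.approx(600)
    assert row["gene_density"] == pytest.approx(3 / 10.0)
    assert row["coding_fraction"] == pytest.approx(1800 / 10_000)
    assert row["strand_bias"] == pytest.approx(2 / 3)
    assert row["strand_switch_rate"] == pytest.approx(1.0)
    assert row["contig_length"] == 10_000
    assert row["gc_content"] == 0.0
    assert row["mean_intergenic_gap"] == pytest.approx(550)
    # protein db: 3 hits on 2 ORFs; best hits 100 (archaeal) and 80 (phage)
    assert row["protein_nr_n_orfs_with_hit"] == 2
    assert row["protein_nr_frac_orfs_annotated"] == pytest.approx(2 / 3)
    assert row["protein_nr_n_best_archaeal"] == 1
    assert row["protein_nr_n_best_phage"] == 1
    assert row["protein_nr_mean_best_bitscore"] == pytest.approx(90.0)
    # profile-HMM db: single phage hit at bitscore 60
    assert row["pvog_hmm_n_orfs_with_hit"] == 1
    assert row["pvog_hmm_mean_best_bitscore"] == pytest.approx(60.0)
    # iterative-profile db: 2 hits on one ORF, best 70
    assert row["ocav_profile_n_orfs_with_hit"] == 1
    assert row["ocav_profile_mean_best_bitscore"] == pytest.approx(70.0)
    assert row["ocav_hit_count"] == 2
    # overall: ORFs c1_1 (best 100, archaeal) and c1_2 (best 80, phage)
    assert row["archaeal_frac_of_annotated"] == pytest.approx(0.5)
    assert row["no_genes"] == 0.0


def test_contig_with_no_hits_gets_zero_hit_features():
    contigs, orfs, hits = _mini_dataset()
    row = compute_features(contigs, orfs, hits).data.loc["c2"]
    hit_cols = [c for c in FEATURE_NAMES if any(db in c for db in ("protein_nr", "pvog", "ocav"))]
    assert (row[hit_cols] == 0).all()


def test_missing_contig_inputs_listed_in_error():
    contigs, orfs, hits = _mini_dataset()
    del orfs["c2"]
    with pytest.raises(ValueError, match="c2"):
        compute_features(contigs, orfs, hits)


def test_row_order_follows_input_order():
    contigs, orfs, hits = _mini_dataset()
    fwd = compute_features(contigs, orfs, hits)
    rev = compute_features(contigs[::-1], orfs, hits)
    assert list(rev.data.index) == ["c2", "c1"]
    pd.testing.assert_frame_equal(fwd.data, rev.data.loc[fwd.data.index])


def test_labels_validated():
    contigs, orfs, hits = _mini_dataset()
    with pytest.raises(ValueError, match="unknown labels"):
        compute_features(contigs, orfs, hits, labels={"c1": "weird", "c2": "phage"})


def test_tsv_roundtrip(tmp_path):
    contigs, orfs, hits = _mini_dataset()
    table = compute_features(contigs, orfs, hits, labels={"c1": "archaeal_virus", "c2": "phage"})
    p = tmp_path / "features.tsv"
    table.to_tsv(p)
    back = FeatureTable.from_tsv(p)
    pd.testing.assert_frame_equal(back.data, table.data)
    assert back.labels.to_dict() == table.labels.to_dict()
    assert back.catalog_version == table.catalog_version


# ------------------------------------------------------------------ pruning


def _table(arrs, names=None):
    arrs = np.asarray(arrs, dtype=float)
    names = names or [f"f{i}" for i in range(arrs.shape[1])]
    return FeatureTable(data=pd.DataFrame(arrs, columns=names))


def oracle_greedy_prune(X, r_max):
    """Brute-force all-pairs Pearson r, then greedy later-column drops."""
    n = X.shape[1]
    sd = X.std(axis=0)
    kept = []
    removed = []
    for j in range(n):
        if sd[j] == 0:
            kept.append(j)
            continue
        clash = [i for i in kept if sd[i] > 0 and abs(np.corrcoef(X[:, i], X[:, j])[0, 1]) > r_max]
        (removed if clash else kept).append(j)
    return kept, removed


def test_duplicated_column_drops_exactly_one():
    x = np.random.default_rng(0).normal(size=10)
    t = _table(np.column_stack([x, x, np.random.default_rng(1).normal(size=10)]))
    pruned, removed = prune_correlated(t)
    assert [r[0] for r in removed] == ["f1"]
    assert pruned.feature_names == ["f0", "f2"]


def test_orthogonal_columns_untouched():
    t = _table(np.eye(4))
    pruned, removed = prune_correlated(t)
    assert removed == [] and pruned.feature_names == t.feature_names


@pytest.mark.parametrize("seed", range(10))
def test_pruning_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(12, 4))
    # add near-copies to force removals
    X = np.column_stack([base, base[:, 0] + rng.normal(scale=0.01, size=12), base[:, 2] * -1])
    pruned, removed = prune_correlated(_table(X), r_max=0.95)
    kept_oracle, removed_oracle = oracle_greedy_prune(X, 0.95)
    assert pruned.feature_names == [f"f{i}" for i in kept_oracle]
    assert [int(r[0][1:]) for r in removed] == removed_oracle


def test_pruning_idempotent_and_bounded(seed=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(20, 6))
    X[:, 4] = X[:, 0] * 2 + 0.001 * rng.normal(size=20)
    pruned, _ = prune_correlated(_table(X))
    again, removed2 = prune_correlated(pruned)
    assert removed2 == []
    corr = np.corrcoef(pruned.data.to_numpy().T)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    assert (np.abs(off) <= 0.95).all()


def test_zero_variance_column_retained_with_warning():
    X = np.column_stack([np.ones(8), np.arange(8.0)])
    with pytest.warns(UserWarning, match="zero variance"):
        pruned, removed = prune_correlated(_table(X))
    assert removed == [] and pruned.feature_names == ["f0", "f1"]
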