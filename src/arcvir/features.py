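"""Per-contig feature table: 27 named features plus co-correlation pruning.

The catalog combines nine genomic attributes with per-database homology
summaries for the three search sources and three aggregate columns.  Absent
evidence is encoded as 0 together with the ``no_genes`` flag column, never as
a missing value.  The catalog is versioned; a trained model refuses feature
tables built under a different catalog.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import ContigHitSummary, HitRecord, SearchThresholds, filter_hits, summarize_hits
from .seqio import Contig, OrfRecord, genomic_attributes

CATALOG_VERSION = "arcvir-27f-v1"

_ATTR_FEATURES = [
    "mean_gene_length",
    "median_gene_length",
    "gene_density",
    "coding_fraction",
    "strand_bias",
    "strand_switch_rate",
    "contig_length",
    "gc_content",
    "mean_intergenic_gap",
]
_DB_FEATURES = ["n_orfs_with_hit", "frac_orfs_annotated", "n_best_archaeal", "n_best_phage", "mean_best_bitscore"]
_FEATURE_DBS = ["protein_nr", "pvog_hmm", "ocav_profile"]

#: fixed, ordered 27-feature catalog
FEATURE_NAMES: list[str] = (
    list(_ATTR_FEATURES)
    + [f"{db}_{f}" for db in _FEATURE_DBS for f in _DB_FEATURES]
    + ["ocav_hit_count", "archaeal_frac_of_annotated", "no_genes"]
)
assert len(FEATURE_NAMES) == 27

LABELS = ("archaeal_virus", "phage")


@dataclass
class FeatureTable:
    """Rectangular per-contig feature matrix with optional class labels."""

    data: pd.DataFrame  # index: contig ids; columns: feature names
    labels: pd.Series | None = None  # values in LABELS, aligned to data.index
    catalog_version: str = CATALOG_VERSION
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)
            bad = set(self.labels.dropna().unique()) - set(LABELS)
            if bad:
                raise ValueError(f"unknown labels {sorted(bad)}; expected {LABELS}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data.loc[list(ids)].copy(),
            labels=None if self.labels is None else self.labels.loc[list(ids)].copy(),
            catalog_version=self.catalog_version,
            metadata=dict(self.metadata),
        )

    # -- TSV serialisation (sidecar JSON carries catalog + pruning log) ----
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.data.copy()
        if self.labels is not None:
            out["label"] = self.labels
        out.to_csv(path, sep="\t", index_label="contig_id")
        meta = {"catalog_version": self.catalog_version, **self.metadata}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="contig_id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").dropna()
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            data=df,
            labels=labels,
            catalog_version=meta.pop("catalog_version", CATALOG_VERSION),
            metadata=meta,
        )


def _row_from_summary(attrs, summ: ContigHitSummary) -> dict[str, float]:
    row = {name: float(getattr(attrs, name)) for name in _ATTR_FEATURES}
    for db in _FEATURE_DBS:
        s = summ.per_db[db]
        row[f"{db}_n_orfs_with_hit"] = float(s.n_orfs_with_hit)
        row[f"{db}_frac_orfs_annotated"] = float(s.fraction_orfs_annotated)
        row[f"{db}_n_best_archaeal"] = float(s.n_best_archaeal)
        row[f"{db}_n_best_phage"] = float(s.n_best_phage)
        row[f"{db}_mean_best_bitscore"] = float(s.mean_best_bitscore)
    row["ocav_hit_count"] = float(summ.ocav_hit_count)
    row["archaeal_frac_of_annotated"] = float(summ.archaeal_fraction_of_annotated)
    row["no_genes"] = 1.0 if attrs.no_genes else 0.0
    return row


def build_feature_table(
    contigs: Sequence[Contig],
    orfs_by_contig: Mapping[str, Sequence[OrfRecord]],
    summaries_by_contig: Mapping[str, ContigHitSummary],
    labels: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Assemble the 27-column table, one row per contig, input order kept."""
    missing = [c.id for c in contigs if c.id not in orfs_by_contig or c.id not in summaries_by_contig]
    if missing:
        raise ValueError(f"contigs missing ORFs or hit summaries: {missing}")
    rows, index = [], []
    for c in contigs:
        attrs = genomic_attributes(c, list(orfs_by_contig[c.id]))
        rows.append(_row_from_summary(attrs, summaries_by_contig[c.id]))
        index.append(c.id)
    df = pd.DataFrame(rows, index=pd.Index(index, name="contig_id"), columns=FEATURE_NAMES)
    lab = None
    if labels is not None:
        lab = pd.Series({c.id: labels[c.id] for c in contigs if c.id in labels})
    return FeatureTable(data=df, labels=lab)


def compute_features(
    contigs: Sequence[Contig],
    orfs_by_contig: Mapping[str, Sequence[OrfRecord]],
    hits: Sequence[HitRecord],
    thresholds: SearchThresholds | None = None,
    labels: Mapping[str, str] | None = None,
) -> FeatureTable:
    """Convenience path: filter raw hits, summarise per contig, build table."""
    missing = [c.id for c in contigs if c.id not in orfs_by_contig]
    if missing:
        raise ValueError(f"contigs missing ORFs or hit summaries: {missing}")
    kept = filter_hits(hits, thresholds)
    by_contig: dict[str, list[HitRecord]] = {c.id: [] for c in contigs}
    for h in kept:
        if h.contig_id in by_contig:
            by_contig[h.contig_id].append(h)
    summaries = {
        c.id: summarize_hits(c, list(orfs_by_contig[c.id]), by_contig[c.id]) for c in contigs
    }
    return build_feature_table(contigs, orfs_by_contig, summaries, labels=labels)


def prune_correlated(
    table: FeatureTable, r_max: float = 0.95
) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Drop later columns whose |Pearson r| with an earlier kept column exceeds r_max.

    Greedy scan in fixed column order; zero-variance columns cannot enter a
    correlation (r is undefined) and are retained with a warning.  Returns the
    surviving table and a removal log of (dropped, kept_partner, r).
    """
    if table.n < 2:
        raise ValueError("correlation pruning needs at least 2 rows")
    X = table.data.to_numpy(dtype=float)
    cols = table.feature_names
    sd = X.std(axis=0)
    kept: list[int] = []
    removed: list[tuple[str, str, float]] = []
    for j in range(X.shape[1]):
        if sd[j] == 0.0:
            warnings.warn(f"feature {cols[j]!r} has zero variance; excluded from correlation, retained")
            kept.append(j)
            continue
        drop_for = None
        for i in kept:
            if sd[i] == 0.0:
                continue
            r = float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            if abs(r) > r_max:
                drop_for = (cols[j], cols[i], r)
                break
        if drop_for is None:
            kept.append(j)
        else:
            removed.append(drop_for)
    pruned = FeatureTable(
        data=table.data.iloc[:, kept].copy(),
        labels=table.labels,
        catalog_version=table.catalog_version,
        metadata={**table.metadata, "pruning_log": [list(r) for r in removed], "r_max": r_max},
    )
    return pruned, removed
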