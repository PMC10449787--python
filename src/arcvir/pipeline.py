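"""High-level glue: dataset -> features -> predictions -> benchmark metrics.

These helpers tie the synthetic-data generator, feature builder, classifier
and metric engine together for the perturbation benchmarks (fragmentation,
contamination spiking, subsampling) and for end-to-end runs from the CLI,
tests and examples.  Truth handling: the positive class is the archaeal
virus; phage and cellular (archaea/bacteria) rows all count as negatives, so
a microbial fragment called archaeal is a false positive in the FDR.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .benchmark import (
    ConfusionCounts,
    CurveData,
    MetricReport,
    compute_metrics,
    contamination_count,
    roc_pr,
)
from .classifier import DEFAULT_THRESHOLD, Prediction, TrainedModel, predict
from .features import FeatureTable, compute_features
from .homology import SearchThresholds
from .simulate import SimulationConfig, SyntheticDataset, simulate_contaminants

POSITIVE = "archaeal_virus"


def features_from_dataset(
    ds: SyntheticDataset,
    thresholds: SearchThresholds | None = None,
    with_labels: bool = True,
) -> FeatureTable:
    """Build the feature table for a dataset (labels only for the two viral classes)."""
    labels = None
    if with_labels:
        viral = {k: v for k, v in ds.labels.items() if v in ("archaeal_virus", "phage")}
        labels = viral or None
    return compute_features(ds.contigs, ds.orfs_by_contig, ds.hits, thresholds, labels=labels)


def confusion_from_predictions(
    preds: Sequence[Prediction], truth: Mapping[str, str]
) -> ConfusionCounts:
    tp = fp = tn = fn = 0
    for p in preds:
        is_pos = truth[p.contig_id] == POSITIVE
        called_pos = p.predicted_class == POSITIVE
        if called_pos:
            tp, fp = (tp + 1, fp) if is_pos else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if is_pos else (fn, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def evaluate_dataset(
    model: TrainedModel,
    ds: SyntheticDataset,
    threshold: float = DEFAULT_THRESHOLD,
    thresholds: SearchThresholds | None = None,
) -> tuple[list[Prediction], ConfusionCounts, MetricReport]:
    """Predict every contig in ``ds`` and score against its truth labels."""
    table = features_from_dataset(ds, thresholds, with_labels=False)
    preds = predict(model, table, threshold=threshold)
    counts = confusion_from_predictions(preds, ds.labels)
    return preds, counts, compute_metrics(counts)


def curves_for_dataset(
    model: TrainedModel, ds: SyntheticDataset, thresholds: SearchThresholds | None = None
) -> CurveData:
    table = features_from_dataset(ds, thresholds, with_labels=False)
    preds = predict(model, table)
    scores = [(p.p_archaeal, ds.labels[p.contig_id] == POSITIVE) for p in preds]
    return roc_pr(scores)


def contamination_curve(
    model: TrainedModel,
    viral_ds: SyntheticDataset,
    proportions: Sequence[float],
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    sim_config: SimulationConfig | None = None,
) -> dict[float, MetricReport]:
    """Metrics at increasing microbial contamination of the input dataset.

    One contaminant pool (sized for the largest proportion) is drawn per
    seed and nested subsets are reused across proportions, so comparisons
    across the grid are paired rather than re-randomised.
    """
    n_viral = len(viral_ds.contigs)
    n_max = contamination_count(n_viral, max(proportions))
    pool = simulate_contaminants(max(n_max, 2), seed=seed, config=sim_config)
    arch_ids = [c.id for c in pool.contigs if pool.labels[c.id] == "archaea"]
    bact_ids = [c.id for c in pool.contigs if pool.labels[c.id] == "bacteria"]
    out: dict[float, MetricReport] = {}
    for p in proportions:
        n_mic = contamination_count(n_viral, p)
        take = arch_ids[: n_mic // 2] + bact_ids[: n_mic - n_mic // 2]
        merged = viral_ds.merged_with(pool.subset(take))
        _, _, report = evaluate_dataset(model, merged, threshold=threshold)
        out[p] = report
    return out


def fragmentation_curve(
    model: TrainedModel,
    ds: SyntheticDataset,
    target_sizes: Sequence[int | None],
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[int | None, MetricReport]:
    """Metrics after size-fractioning the dataset to each target size.

    ``None`` is the pass-through (>10 kb) variant.  Fragment pools are
    subsampled back to the original sequence count (seeded).
    """
    out: dict[int | None, MetricReport] = {}
    for size in target_sizes:
        frag = ds.fragment(size, seed=seed)
        _, _, report = evaluate_dataset(model, frag, threshold=threshold)
        out[size] = report
    return out


def subsample_curve(
    model: TrainedModel,
    ds: SyntheticDataset,
    fractions: Sequence[float],
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[float, MetricReport]:
    out: dict[float, MetricReport] = {}
    rng = np.random.default_rng(seed)
    ids = [c.id for c in ds.contigs]
    for f in fractions:
        k = max(1, int(round(f * len(ids))))
        sub = ds.subset(list(rng.choice(ids, size=k, replace=False)))
        _, _, report = evaluate_dataset(model, sub, threshold=threshold)
        out[f] = report
    return out
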