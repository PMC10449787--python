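"""Classification metrics, ROC/PR curves, and dataset-perturbation variants.

The metric engine computes TPR, SPEC, ACC, MCC, FDR and F1 directly from
confusion counts (positive class = archaeal virus); any metric whose
denominator is zero is reported as None, never propagated as NaN.  Curves
are built from the per-contig tree-vote probabilities with equal scores
grouped into a single threshold step; AUROC then equals the concordant-pair
rank statistic and AUPRC is the trapezoid over the PR points.

Perturbation generators reproduce the benchmarking variants: 5'-anchored
size fractionation, microbial contamination spiking at a target proportion
of the final dataset, and random subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .seqio import Contig

POSITIVE = "archaeal_virus"

FRAGMENT_SIZES_BP = (1_000, 2_500, 5_000, 7_500, 10_000, None)  # None = pass-through (>10 kb)
CONTAMINATION_PROPORTIONS = (0.10, 0.25, 0.50, 0.75, 0.95)
SUBSAMPLE_FRACTIONS = (0.05, 0.25, 0.50, 0.75)
CONTAMINANT_MIN_BP = 10_000
CONTAMINANT_MAX_BP = 200_000


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Confusion-derived metrics; None flags an undefined (0/0) metric."""

    tpr: float | None
    spec: float | None
    acc: float | None
    mcc: float | None
    fdr: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """TPR, SPEC, ACC, MCC, FDR and F1 from confusion counts, full precision."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return MetricReport(
        tpr=_ratio(tp, tp + fn),
        spec=_ratio(tn, tn + fp),
        acc=_ratio(tp + tn, counts.total),
        mcc=None if mcc_den == 0 else (tp * tn - fp * fn) / mcc_den,
        fdr=_ratio(fp, fp + tp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def confusion_from_scores(
    scores: Sequence[tuple[float, bool]], threshold: float
) -> ConfusionCounts:
    """Counts at one threshold; predicted positive when score >= threshold."""
    tp = fp = tn = fn = 0
    for s, pos in scores:
        if s >= threshold:
            tp, fp = (tp + 1, fp) if pos else (tp, fp + 1)
        else:
            fn, tn = (fn + 1, tn) if pos else (fn, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class CurveData:
    thresholds: tuple[float, ...]  # ascending
    tpr: tuple[float, ...]
    fpr: tuple[float, ...]
    precision: tuple[float, ...]
    auroc: float
    auprc: float


def roc_pr(scores: Sequence[tuple[float, bool]]) -> CurveData:
    """ROC and PR curves over the unique-score thresholds (plus 0 and 1).

    Equal scores form one threshold step; AUROC is the trapezoid over the
    grouped ROC points (identical to the concordant-pair statistic with ties
    counted half) and AUPRC the trapezoid over the PR points, anchored at
    recall 0 with the precision of the most stringent non-empty step.
    """
    labels = {pos for _, pos in scores}
    if labels != {True, False}:
        raise ValueError("ROC/PR needs both a positive and a negative example")
    P = sum(1 for _, pos in scores if pos)
    N = len(scores) - P
    thresholds = sorted({s for s, _ in scores} | {0.0, 1.0})
    pts = []
    for t in thresholds:
        tp = sum(1 for s, pos in scores if pos and s >= t)
        fp = sum(1 for s, pos in scores if not pos and s >= t)
        prec = tp / (tp + fp) if (tp + fp) else None
        pts.append((t, tp / P, fp / N, prec))

    # ROC: thresholds descending -> (fpr, tpr) ascending; anchor at (0,0)/(1,1)
    roc = [(0.0, 0.0)] + [(fp, tp) for _, tp, fp, _ in reversed(pts)]
    if roc[-1] != (1.0, 1.0):
        roc.append((1.0, 1.0))
    auroc = sum((x2 - x1) * (y1 + y2) / 2 for (x1, y1), (x2, y2) in zip(roc, roc[1:]))

    # PR: recall ascending with defined precision; anchor recall 0
    pr = [(tp, prec) for _, tp, _, prec in reversed(pts) if prec is not None]
    if not pr:
        raise ValueError("no threshold yields a positive prediction")
    if pr[0][0] > 0.0:
        pr = [(0.0, pr[0][1])] + pr
    auprc = sum((r2 - r1) * (p1 + p2) / 2 for (r1, p1), (r2, p2) in zip(pr, pr[1:]))

    return CurveData(
        thresholds=tuple(t for t, _, _, _ in pts),
        tpr=tuple(tp for _, tp, _, _ in pts),
        fpr=tuple(fp for _, _, fp, _ in pts),
        precision=tuple(float("nan") if prec is None else prec for _, _, _, prec in pts),
        auroc=float(auroc),
        auprc=float(auprc),
    )


# ---------------------------------------------------------------------------
# Dataset perturbations (sequence level)


def fragment_dataset(
    contigs: Sequence[Contig],
    target_size: int | None,
    seed: int = 0,
    labels: Mapping[str, str] | None = None,
    subsample_to: int | None = None,
) -> tuple[list[Contig], dict[str, str] | None]:
    """Size-fraction contigs into exact non-overlapping 5'-anchored windows.

    The terminal remainder shorter than ``target_size`` is dropped; fragments
    inherit their parent's label.  The fragment pool is then randomly
    subsampled (seeded, without replacement) back to the original sequence
    count (or ``subsample_to``).  ``target_size=None`` is pass-through.
    """
    if target_size is None:
        return list(contigs), (dict(labels) if labels is not None else None)
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    frags: list[Contig] = []
    frag_labels: dict[str, str] = {}
    for c in contigs:
        n_win = c.length // target_size
        if n_win == 0:
            continue  # too short to contribute, by construction
        for k in range(n_win):
            fid = f"{c.id}|frag{k + 1}"
            frags.append(Contig(id=fid, sequence=c.sequence[k * target_size : (k + 1) * target_size]))
            if labels is not None and c.id in labels:
                frag_labels[fid] = labels[c.id]
    n_out = subsample_to if subsample_to is not None else len(contigs)
    if len(frags) > n_out:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(frags), size=n_out, replace=False)
        frags = [frags[i] for i in sorted(idx)]
    kept_ids = {f.id for f in frags}
    out_labels = {k: v for k, v in frag_labels.items() if k in kept_ids} if labels is not None else None
    return frags, out_labels


def contamination_count(n_viral: int, proportion: float) -> int:
    """Microbial sequences to add so they form ``proportion`` of the final set."""
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    return int(round(proportion / (1.0 - proportion) * n_viral))


def spike_contamination(
    viral: Sequence[Contig],
    viral_labels: Mapping[str, str],
    microbial_pool: Sequence[Contig],
    pool_classes: Mapping[str, str],  # contig id -> 'archaea' | 'bacteria'
    proportion: float,
    seed: int = 0,
) -> tuple[list[Contig], dict[str, str]]:
    """Spike microbial fragments into a labeled viral set at a target proportion.

    Draws ``round(p/(1-p) * n_viral)`` microbial contigs, half from each
    microbial class (seeded, without replacement).  Every pool fragment must
    be 10-200 kb.  Microbial rows carry their cellular class as the label so
    downstream accounting can treat them as non-viral negatives.
    """
    for c in microbial_pool:
        if not CONTAMINANT_MIN_BP <= c.length <= CONTAMINANT_MAX_BP:
            raise ValueError(
                f"contaminant {c.id} has length {c.length}; pool must be "
                f"{CONTAMINANT_MIN_BP}-{CONTAMINANT_MAX_BP} bp"
            )
    n_mic = contamination_count(len(viral), proportion)
    n_arch = n_mic // 2
    n_bact = n_mic - n_arch
    arch_pool = [c for c in microbial_pool if pool_classes.get(c.id) == "archaea"]
    bact_pool = [c for c in microbial_pool if pool_classes.get(c.id) == "bacteria"]
    if len(arch_pool) < n_arch or len(bact_pool) < n_bact:
        raise ValueError(
            f"microbial pool too small: need {n_arch} archaea (have {len(arch_pool)}) "
            f"and {n_bact} bacteria (have {len(bact_pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = [arch_pool[i] for i in rng.choice(len(arch_pool), size=n_arch, replace=False)]
    chosen += [bact_pool[i] for i in rng.choice(len(bact_pool), size=n_bact, replace=False)]
    combined = list(viral) + chosen
    out_labels = dict(viral_labels)
    for c in chosen:
        out_labels[c.id] = pool_classes[c.id]
    return combined, out_labels


def subsample_dataset(
    contigs: Sequence[Contig], fraction: float, seed: int = 0
) -> list[Contig]:
    """Simple random sample without replacement of round(fraction * n) contigs."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(round(fraction * len(contigs)))
    if k == 0:
        raise ValueError(f"fraction {fraction} of {len(contigs)} contigs leaves nothing")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(contigs), size=k, replace=False)
    return [contigs[i] for i in idx]
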