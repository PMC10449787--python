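"""Legacy rule-based archaeal-virus classifier (v1 rules).

Before the random-forest model, archaeal-virus candidates were called by a
fixed rule set over per-gene homology annotations: a gene is affiliated with
the highest-scoring reference hit passing a bitscore/e-value gate; a contig
is a category 1 candidate when over 2/3 of its annotated genes affiliate
with archaea/archaeal viruses (category 2: over 1/2), provided the best
archaeal bitscore exceeds 75 and beats the best phage-affiliated bitscore.

The published e-value gate for the homology annotations reads as a floor
(">0.001"); every other filter in the lineage is a ceiling, so the default
here treats it as a ceiling (<0.001).  The literal floor reading remains
selectable via ``homology_evalue_is_floor``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .homology import ARCHAEAL_CLASSES, PHAGE_CLASSES, HitRecord, _best_hit_key

HOMOLOGY_SOURCES = frozenset({"protein_nr"})
DOMAIN_SOURCES = frozenset({"pfam", "pvog_hmm"})


@dataclass(frozen=True)
class V1Thresholds:
    homology_bitscore_min: float = 50.0
    homology_evalue_max: float = 1e-3
    homology_evalue_is_floor: bool = False  # literal reading of the published gate
    domain_bitscore_min: float = 40.0
    domain_evalue_max: float = 1e-5
    retain_bitscore_min: float = 75.0
    category1_fraction: float = 2.0 / 3.0  # strict "over 66%"
    category2_fraction: float = 0.5  # strict "over 50%"


@dataclass(frozen=True)
class GeneAnnotation:
    orf_id: str
    affiliation: str  # archaeal_virus / phage / none
    bitscore: float
    source: str  # homology / domain_model


@dataclass(frozen=True)
class V1Result:
    contig_id: str
    category: int | None  # 1, 2 or None
    archaeal_fraction_of_annotated: float
    passing_bitscore: bool
    no_annotation: bool = False


def _affiliation(target_class: str) -> str:
    if target_class in ARCHAEAL_CLASSES:
        return "archaeal_virus"
    if target_class in PHAGE_CLASSES:
        return "phage"
    return "none"


def annotate_v1(hits: Sequence[HitRecord], thresholds: V1Thresholds | None = None) -> list[GeneAnnotation]:
    """Per-ORF affiliation from raw (unfiltered) hits under the v1 gates.

    Best hit per ORF per kind (homology vs domain model) by bitscore, ties by
    e-value then target id; homology annotation takes precedence when both
    kinds pass their gate.  ORFs with no passing hit get affiliation 'none'.
    """
    t = thresholds or V1Thresholds()
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.source_db in HOMOLOGY_SOURCES:
            kind = "homology"
        elif h.source_db in DOMAIN_SOURCES:
            kind = "domain_model"
        else:
            continue  # iterative-profile hits play no role in the v1 rules
        key = (h.orf_id, kind)
        cur = best.get(key)
        if cur is None or _best_hit_key(h) < _best_hit_key(cur):
            best[key] = h

    by_orf: dict[str, dict[str, HitRecord]] = defaultdict(dict)
    for (orf_id, kind), h in best.items():
        by_orf[orf_id][kind] = h

    out: list[GeneAnnotation] = []
    for orf_id in sorted(by_orf):
        kinds = by_orf[orf_id]
        ann: GeneAnnotation | None = None
        h = kinds.get("homology")
        if h is not None and h.bitscore > t.homology_bitscore_min:
            ev_ok = h.evalue > t.homology_evalue_max if t.homology_evalue_is_floor else h.evalue < t.homology_evalue_max
            if ev_ok:
                ann = GeneAnnotation(orf_id, _affiliation(h.target_class), h.bitscore, "homology")
        if ann is None:
            d = kinds.get("domain_model")
            if d is not None and d.bitscore > t.domain_bitscore_min and d.evalue < t.domain_evalue_max:
                ann = GeneAnnotation(orf_id, _affiliation(d.target_class), d.bitscore, "domain_model")
        out.append(ann or GeneAnnotation(orf_id, "none", 0.0, "homology"))
    return out


def classify_v1(
    contig_id: str,
    annotations: Iterable[GeneAnnotation],
    thresholds: V1Thresholds | None = None,
) -> V1Result:
    """Apply the category 1/2 rules to one contig's gene annotations.

    The archaeal fraction is computed over annotated genes only (affiliation
    != none).  Category 1 requires fraction > 2/3, category 2 fraction > 1/2,
    both strict, and in addition the best archaeal-affiliated bitscore must
    exceed 75 and strictly beat the best phage-affiliated bitscore.
    """
    t = thresholds or V1Thresholds()
    anns = list(annotations)
    annotated = [a for a in anns if a.affiliation != "none"]
    if not annotated:
        return V1Result(contig_id, None, 0.0, passing_bitscore=False, no_annotation=True)
    arch = [a for a in annotated if a.affiliation == "archaeal_virus"]
    phage = [a for a in annotated if a.affiliation == "phage"]
    frac = len(arch) / len(annotated)
    best_arch = max((a.bitscore for a in arch), default=float("-inf"))
    best_phage = max((a.bitscore for a in phage), default=float("-inf"))
    passing = best_arch > t.retain_bitscore_min and best_arch > best_phage
    category: int | None = None
    if passing:
        if frac > t.category1_fraction:
            category = 1
        elif frac > t.category2_fraction:
            category = 2
    return V1Result(contig_id, category, frac, passing_bitscore=passing)
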