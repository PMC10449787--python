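"""Homology searches, e-value filtering, and per-contig hit summaries.

Three search flavours feed the feature table: a protein-vs-protein search
against a viral protein reference (MMseqs2/BLAST-style tabular output), a
profile-HMM search against a virus-orthologous-group collection (HMMER
tblout), and an iterative profile search against a curated archaeal-virus
reference set (jackhmmer tblout).  Every hit carries a ``target_class``
resolved from a user-supplied reference-metadata map — never guessed from
free text at classification time.

All searches also accept precomputed tabular hit files (or an in-memory mock
table), so the whole pipeline runs offline.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .seqio import Contig, OrfRecord

TARGET_CLASSES = ("archaeal_virus", "phage", "archaea", "bacteria", "other", "unknown")
SOURCE_DBS = ("protein_nr", "pvog_hmm", "ocav_profile", "pfam")

#: classes counted as archaea-affiliated / phage-affiliated in summaries
ARCHAEAL_CLASSES = frozenset({"archaeal_virus", "archaea"})
PHAGE_CLASSES = frozenset({"phage", "bacteria"})


class SearchBackendError(RuntimeError):
    """An external search binary is missing or failed."""


@dataclass(frozen=True)
class HitRecord:
    orf_id: str
    contig_id: str
    target_id: str
    evalue: float
    bitscore: float
    target_class: str
    source_db: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.orf_id}->{self.target_id}: negative e-value")
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"unknown target_class {self.target_class!r}")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")


@dataclass(frozen=True)
class SearchThresholds:
    """Per-search e-value ceilings; comparisons are strict (<)."""

    protein_evalue_max: float = 1e-5
    hmm_fullseq_evalue_max: float = 1e-10
    iterative_evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        for v in (self.protein_evalue_max, self.hmm_fullseq_evalue_max, self.iterative_evalue_max):
            if not v > 0:
                raise ValueError("thresholds must be strictly positive")

    def for_source(self, source_db: str) -> float:
        return {
            "protein_nr": self.protein_evalue_max,
            "pvog_hmm": self.hmm_fullseq_evalue_max,
            "pfam": self.hmm_fullseq_evalue_max,
            "ocav_profile": self.iterative_evalue_max,
        }[source_db]


@dataclass
class ReferenceDB:
    """Descriptor for one reference database.

    ``class_map`` maps target_id -> target_class and is typically loaded from
    a two-column metadata TSV shipped with the database.
    """

    name: str
    source_db: str
    path: str | Path | None = None
    class_map: Mapping[str, str] = field(default_factory=dict)
    n_iterations: int = 3  # iterative-profile search rounds

    def resolve_class(self, target_id: str) -> str:
        cls = self.class_map.get(target_id)
        if cls is None:
            warnings.warn(f"target {target_id!r} missing from {self.name} metadata; class set to 'unknown'")
            return "unknown"
        return cls


def load_class_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (target_id, target_class) metadata TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if parts[1] not in TARGET_CLASSES:
                raise ValueError(f"{path}: line {lineno}: unknown class {parts[1]!r}")
            out[parts[0]] = parts[1]
    return out


def _default_orf_to_contig(orf_id: str) -> str:
    # orf ids follow the "<contig>_<n>" convention used across the package
    return orf_id.rsplit("_", 1)[0]


# ---------------------------------------------------------------------------
# Parsers for the standard tabular outputs


def parse_blast_tabular(
    path: str | Path,
    db: ReferenceDB,
    orf_to_contig: Callable[[str], str] = _default_orf_to_contig,
) -> list[HitRecord]:
    """Parse 12-column BLAST/MMseqs2-style tabular output (outfmt 6)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 tab-separated columns")
            orf_id, target_id = f[0], f[1]
            hits.append(
                HitRecord(
                    orf_id=orf_id,
                    contig_id=orf_to_contig(orf_id),
                    target_id=target_id,
                    evalue=float(f[10]),
                    bitscore=float(f[11]),
                    target_class=db.resolve_class(target_id),
                    source_db=db.source_db,
                )
            )
    return hits


def parse_hmmer_tblout(
    path: str | Path,
    db: ReferenceDB,
    orf_to_contig: Callable[[str], str] = _default_orf_to_contig,
) -> list[HitRecord]:
    """Parse HMMER per-target tblout (hmmsearch/jackhmmer).

    The target column of tblout is the query protein (our ORF); the query
    column is the profile.  The full-sequence e-value and score columns are
    used — the filter the pipeline applies is on the full-protein e-value.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 7:
                raise ValueError(f"{path}: line {lineno}: truncated tblout row")
            orf_id, profile_id = f[0], f[2]
            hits.append(
                HitRecord(
                    orf_id=orf_id,
                    contig_id=orf_to_contig(orf_id),
                    target_id=profile_id,
                    evalue=float(f[4]),
                    bitscore=float(f[5]),
                    target_class=db.resolve_class(profile_id),
                    source_db=db.source_db,
                )
            )
    return hits


_HITS_TSV_COLS = ["orf_id", "contig_id", "target_id", "evalue", "bitscore", "target_class", "source_db"]


def write_hits_tsv(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HITS_TSV_COLS) + "\n")
        for h in hits:
            fh.write(
                f"{h.orf_id}\t{h.contig_id}\t{h.target_id}\t{h.evalue!r}\t"
                f"{h.bitscore!r}\t{h.target_class}\t{h.source_db}\n"
            )


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    hits: list[HitRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HITS_TSV_COLS:
            raise ValueError(f"{path}: unexpected hits header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                HitRecord(
                    orf_id=f[0],
                    contig_id=f[1],
                    target_id=f[2],
                    evalue=float(f[3]),
                    bitscore=float(f[4]),
                    target_class=f[5],
                    source_db=f[6],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Search dispatch


def run_search(
    proteins: str | Path | None,
    db: ReferenceDB,
    mode: str,
    backend: str = "external",
    precomputed: str | Path | None = None,
    mock_hits: Sequence[HitRecord] | None = None,
) -> list[HitRecord]:
    """Run (or ingest) one homology search and return raw HitRecords.

    mode: ``protein`` (BLAST-style tabular), ``hmm`` (hmmsearch tblout) or
    ``iterative`` (jackhmmer tblout).  ``backend="precomputed"`` parses an
    existing tabular output file, ``backend="mock"`` returns ``mock_hits``
    verbatim, and ``backend="external"`` shells out to the search tool.
    """
    if mode not in ("protein", "hmm", "iterative"):
        raise ValueError(f"unknown search mode {mode!r}")
    if backend == "mock":
        return list(mock_hits or [])
    if backend == "precomputed":
        if precomputed is None:
            raise ValueError("backend='precomputed' needs a hit-file path")
        if mode == "protein":
            return parse_blast_tabular(precomputed, db)
        return parse_hmmer_tblout(precomputed, db)
    if backend != "external":
        raise ValueError(f"unknown backend {backend!r}")

    if mode == "protein":
        exe = shutil.which("mmseqs") or shutil.which("blastp")
        if exe is None:
            raise SearchBackendError(
                "no protein-search binary (mmseqs/blastp) on PATH; pass "
                "backend='precomputed' with a 12-column tabular hit file, or backend='mock'"
            )
        raise SearchBackendError(
            "external protein search is not wired in this build; pass backend='precomputed' or 'mock'"
        )
    tool = "hmmsearch" if mode == "hmm" else "jackhmmer"
    exe = shutil.which(tool)
    if exe is None:
        raise SearchBackendError(
            f"{tool} not found on PATH; pass backend='precomputed' with a tblout file, or backend='mock'"
        )
    if proteins is None or db.path is None:
        raise ValueError("external search needs a protein FASTA and db.path")
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        tbl = Path(tmp) / "hits.tblout"
        cmd = [exe, "--tblout", str(tbl)]
        if mode == "iterative":
            cmd += ["-N", str(db.n_iterations)]
        if mode == "hmm":
            cmd += [str(db.path), str(proteins)]
        else:  # jackhmmer: query sequences, then target db
            cmd += [str(proteins), str(db.path)]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0:
            raise SearchBackendError(f"{tool} failed (exit {res.returncode}): {res.stderr[-500:]}")
        return parse_hmmer_tblout(tbl, db)


# ---------------------------------------------------------------------------
# Filtering and per-contig summaries


def filter_hits(hits: Sequence[HitRecord], thresholds: SearchThresholds | None = None) -> list[HitRecord]:
    """Keep hits strictly below their source-specific e-value ceiling.

    Order is preserved; the operation is idempotent and monotone in every
    threshold.
    """
    thresholds = thresholds or SearchThresholds()
    return [h for h in hits if h.evalue < thresholds.for_source(h.source_db)]


def _best_hit_key(h: HitRecord) -> tuple[float, float, str]:
    # max bitscore, then min evalue, then lexicographic target_id
    return (-h.bitscore, h.evalue, h.target_id)


def best_hits_per_orf(hits: Sequence[HitRecord]) -> dict[tuple[str, str], HitRecord]:
    """Best hit per (orf_id, source_db): max bitscore, tie -> min e-value, -> target_id."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.orf_id, h.source_db)
        cur = best.get(key)
        if cur is None or _best_hit_key(h) < _best_hit_key(cur):
            best[key] = h
    return best


@dataclass(frozen=True)
class DbSummary:
    n_hits: int
    n_orfs_with_hit: int
    fraction_orfs_annotated: float
    n_best_archaeal: int
    n_best_phage: int
    mean_best_bitscore: float


@dataclass(frozen=True)
class ContigHitSummary:
    """Aggregated, already-filtered homology evidence for one contig."""

    contig_id: str
    n_orfs: int
    per_db: Mapping[str, DbSummary]
    ocav_hit_count: int  # all filtered iterative-profile hits (not best-per-ORF)
    n_orfs_annotated_any: int
    archaeal_fraction_of_annotated: float


def summarize_hits(
    contig: Contig, orfs: Sequence[OrfRecord], hits: Sequence[HitRecord]
) -> ContigHitSummary:
    """Summarise filtered hits for one contig, per source database and class.

    An ORF's overall affiliation is decided by its single best hit across all
    databases (same bitscore/e-value/target tie-break); the archaeal fraction
    is computed over ORFs whose best hit resolves to an archaea- or
    phage-affiliated class.
    """
    orf_ids = {o.orf_id for o in orfs}
    if len(orf_ids) != len(orfs):
        raise ValueError(f"contig {contig.id}: duplicate orf ids")
    for h in hits:
        if h.orf_id not in orf_ids:
            raise ValueError(f"hit references unknown orf {h.orf_id!r} on contig {contig.id}")

    n_orfs = len(orfs)
    best = best_hits_per_orf(hits)
    by_db: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_db[h.source_db].append(h)

    per_db: dict[str, DbSummary] = {}
    for db in SOURCE_DBS:
        db_hits = by_db.get(db, [])
        db_best = [v for (oid, d), v in best.items() if d == db]
        n_arch = sum(1 for h in db_best if h.target_class in ARCHAEAL_CLASSES)
        n_phage = sum(1 for h in db_best if h.target_class in PHAGE_CLASSES)
        per_db[db] = DbSummary(
            n_hits=len(db_hits),
            n_orfs_with_hit=len(db_best),
            fraction_orfs_annotated=len(db_best) / n_orfs if n_orfs else 0.0,
            n_best_archaeal=n_arch,
            n_best_phage=n_phage,
            mean_best_bitscore=sum(h.bitscore for h in db_best) / len(db_best) if db_best else 0.0,
        )

    # overall best hit per ORF across dbs -> affiliation
    overall: dict[str, HitRecord] = {}
    for (oid, _db), h in best.items():
        cur = overall.get(oid)
        if cur is None or _best_hit_key(h) < _best_hit_key(cur):
            overall[oid] = h
    n_annot = len(overall)
    n_arch_overall = sum(1 for h in overall.values() if h.target_class in ARCHAEAL_CLASSES)
    return ContigHitSummary(
        contig_id=contig.id,
        n_orfs=n_orfs,
        per_db=per_db,
        ocav_hit_count=len(by_db.get("ocav_profile", [])),
        n_orfs_annotated_any=n_annot,
        archaeal_fraction_of_annotated=n_arch_overall / n_annot if n_annot else 0.0,
    )
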