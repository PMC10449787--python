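"""Sequence I/O, protein-coding gene calls, and per-contig genomic attributes.

Contigs are plain nucleotide records; gene calls come either from an external
caller (Prodigal, run in metagenome mode as a subprocess) or from a built-in
naive six-frame scanner that needs no binary.  All coordinates are 1-based
inclusive, matching the text output of common gene callers; conversion to
Python slices happens only inside this module.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NAIVE_MIN_ORF_NT = 90  # approximates the external caller for fixtures


class FastaError(ValueError):
    """Malformed FASTA input."""


class GeneCallerError(RuntimeError):
    """The external gene caller is unavailable or failed."""


@dataclass(frozen=True)
class Contig:
    """A nucleotide contig (A/C/G/T/N, uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """One predicted protein-coding gene, 1-based inclusive coordinates."""

    contig_id: str
    orf_id: str
    start: int
    end: int
    strand: int  # +1 or -1
    partial_left: bool = False
    partial_right: bool = False
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError(f"orf {self.orf_id}: bad coordinates {self.start}..{self.end}")
        if self.strand not in (1, -1):
            raise ValueError(f"orf {self.orf_id}: strand must be +1/-1")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AttributeVector:
    """Per-contig genomic attributes feeding the feature table.

    Zero-ORF contigs get conventional values (densities and lengths 0,
    strand_bias 1.0) together with ``no_genes=True`` so downstream code can
    flag rather than drop them.
    """

    mean_gene_length: float
    median_gene_length: float
    gene_density: float  # genes per kb
    coding_fraction: float
    strand_bias: float
    strand_switch_rate: float
    contig_length: int
    gc_content: float
    mean_intergenic_gap: float
    no_genes: bool = False


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[Contig]:
    """Read nucleotide FASTA into Contigs (sequences uppercased, order kept).

    Raises :class:`FastaError` on a malformed leading record or duplicate ids.
    An empty file yields an empty list.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                text_head = line
                break
        else:
            return []
    if not text_head.startswith(">"):
        raise FastaError(f"{path}: line {lineno}: expected '>' header, got {text_head[:30]!r}")

    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        contigs.append(Contig(id=rec.id, sequence=seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene calling


def call_genes(contig: Contig, backend: str = "prodigal", min_orf_nt: int = NAIVE_MIN_ORF_NT) -> list[OrfRecord]:
    """Predict protein-coding genes on one contig.

    ``backend="prodigal"`` shells out to the external caller in metagenome
    mode and parses its protein-FASTA headers verbatim; ``backend="naive"``
    uses the built-in scanner (complete ORFs >= ``min_orf_nt`` nt between a
    start codon in {ATG, GTG, TTG} and the next in-frame stop, both strands;
    ambiguous bases terminate extension).  Zero ORFs is a valid result.
    """
    if backend == "naive":
        return naive_orf_scan(contig, min_orf_nt=min_orf_nt)
    if backend == "prodigal":
        return _prodigal_call(contig)
    raise ValueError(f"unknown gene-caller backend {backend!r}")


def _prodigal_call(contig: Contig) -> list[OrfRecord]:
    exe = shutil.which("prodigal")
    if exe is None:
        raise GeneCallerError(
            "external gene caller 'prodigal' not found on PATH; "
            "use backend='naive' for the built-in scanner"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fna"
        faa = Path(tmp) / "out.faa"
        write_fasta([contig], fa)
        res = subprocess.run(
            [exe, "-i", str(fa), "-a", str(faa), "-p", "meta", "-q", "-o", str(Path(tmp) / "genes.out")],
            capture_output=True,
            text=True,
        )
        if res.returncode != 0:
            raise GeneCallerError(f"prodigal failed (exit {res.returncode}): {res.stderr[-500:]}")
        return parse_prodigal_proteins(faa, contig.id)


def parse_prodigal_proteins(faa_path: str | Path, contig_id: str) -> list[OrfRecord]:
    """Parse Prodigal's protein FASTA (``>id # start # end # strand # ...``)."""
    orfs: list[OrfRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(faa_path), "fasta"), 1):
        parts = rec.description.split(" # ")
        if len(parts) < 5:
            raise GeneCallerError(f"unparseable gene-caller header: {rec.description!r}")
        start, end, strand = int(parts[1]), int(parts[2]), int(parts[3])
        attrs = dict(kv.split("=", 1) for kv in parts[4].split(";") if "=" in kv)
        partial = attrs.get("partial", "00")
        aa = str(rec.seq).rstrip("*")
        orfs.append(
            OrfRecord(
                contig_id=contig_id,
                orf_id=f"{contig_id}_{i}",
                start=start,
                end=end,
                strand=1 if strand >= 0 else -1,
                partial_left=partial[0] == "1",
                partial_right=partial[-1] == "1",
                aa_seq=aa,
            )
        )
    return orfs


def _scan_frames(seq: str, min_orf_nt: int) -> list[tuple[int, int]]:
    """Complete ORFs on the forward strand of ``seq``; 0-based [start, end) nt."""
    found: list[tuple[int, int]] = []
    n = len(seq)
    for frame in range(3):
        start_at: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start_at = None  # ambiguity terminates extension
                continue
            if codon in STOP_CODONS:
                if start_at is not None and (i + 3 - start_at) >= min_orf_nt:
                    found.append((start_at, i + 3))
                start_at = None
            elif start_at is None and codon in START_CODONS:
                start_at = i
    return found


def naive_orf_scan(contig: Contig, min_orf_nt: int = NAIVE_MIN_ORF_NT) -> list[OrfRecord]:
    """Built-in fallback scanner: maximal complete ORFs on both strands.

    Within each frame, an ORF runs from the first start codon after the
    previous stop to the next in-frame stop (stop included in the span).
    """
    seq = contig.sequence
    n = len(seq)
    spans: list[tuple[int, int, int]] = []  # (start0, end0_excl, strand)
    for s0, e0 in _scan_frames(seq, min_orf_nt):
        spans.append((s0, e0, 1))
    rc = str(Seq(seq).reverse_complement())
    for s0, e0 in _scan_frames(rc, min_orf_nt):
        spans.append((n - e0, n - s0, -1))
    spans.sort(key=lambda t: (t[0], t[1], -t[2]))
    orfs = []
    for k, (s0, e0, strand) in enumerate(spans, 1):
        sub = seq[s0:e0] if strand == 1 else rc[n - e0 : n - s0]
        aa = str(Seq(sub[:-3]).translate(table=11))
        orfs.append(
            OrfRecord(
                contig_id=contig.id,
                orf_id=f"{contig.id}_{k}",
                start=s0 + 1,
                end=e0,
                strand=strand,
                aa_seq=aa,
            )
        )
    return orfs


# ---------------------------------------------------------------------------
# Gene-call cache (TSV)

_GENE_TABLE_COLS = ["contig_id", "orf_id", "start", "end", "strand", "partial_left", "partial_right", "aa_seq"]


def write_gene_table(orfs: Iterable[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TABLE_COLS) + "\n")
        for o in orfs:
            fh.write(
                f"{o.contig_id}\t{o.orf_id}\t{o.start}\t{o.end}\t"
                f"{'+' if o.strand == 1 else '-'}\t{int(o.partial_left)}\t{int(o.partial_right)}\t{o.aa_seq}\n"
            )


def read_gene_table(path: str | Path) -> list[OrfRecord]:
    orfs: list[OrfRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_GENE_TABLE_COLS) - 1] != _GENE_TABLE_COLS[:-1]:
            raise ValueError(f"{path}: unexpected gene-table header {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            orfs.append(
                OrfRecord(
                    contig_id=f[0],
                    orf_id=f[1],
                    start=int(f[2]),
                    end=int(f[3]),
                    strand=1 if f[4] == "+" else -1,
                    partial_left=f[5] == "1",
                    partial_right=f[6] == "1",
                    aa_seq=f[7] if len(f) > 7 else "",
                )
            )
    return orfs


# ---------------------------------------------------------------------------
# Genomic attributes


def _merged_coverage(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bp covered by possibly overlapping 1-based inclusive intervals."""
    if not intervals:
        return 0
    ivs = sorted(intervals)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def genomic_attributes(contig: Contig, orfs: Sequence[OrfRecord]) -> AttributeVector:
    """Deterministic per-contig attributes from a contig and its gene calls.

    gene_density is genes/kb; strand_bias = max(n+, n-)/n; switch rate is the
    fraction of adjacent gene pairs (by start coordinate) on opposite strands;
    intergenic gaps are clamped at zero for overlapping genes.  Lengths are in
    nucleotides.
    """
    for o in orfs:
        if o.contig_id != contig.id:
            raise ValueError(f"orf {o.orf_id} belongs to {o.contig_id}, not {contig.id}")
        if o.end > contig.length:
            raise ValueError(f"orf {o.orf_id} extends past contig end ({o.end} > {contig.length})")
    seq = contig.sequence
    acgt = sum(seq.count(b) for b in "ACGT")
    gc = (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0

    if not orfs:
        return AttributeVector(
            mean_gene_length=0.0,
            median_gene_length=0.0,
            gene_density=0.0,
            coding_fraction=0.0,
            strand_bias=1.0,
            strand_switch_rate=0.0,
            contig_length=contig.length,
            gc_content=gc,
            mean_intergenic_gap=0.0,
            no_genes=True,
        )

    lengths = sorted(o.nt_length for o in orfs)
    n = len(lengths)
    mid = n // 2
    median = float(lengths[mid]) if n % 2 else (lengths[mid - 1] + lengths[mid]) / 2.0
    n_fwd = sum(1 for o in orfs if o.strand == 1)
    by_start = sorted(orfs, key=lambda o: (o.start, o.end))
    switches = sum(1 for a, b in zip(by_start, by_start[1:]) if a.strand != b.strand)
    gaps = [max(0, b.start - a.end - 1) for a, b in zip(by_start, by_start[1:])]
    return AttributeVector(
        mean_gene_length=sum(lengths) / n,
        median_gene_length=median,
        gene_density=1000.0 * n / contig.length,
        coding_fraction=_merged_coverage([(o.start, o.end) for o in orfs]) / contig.length,
        strand_bias=max(n_fwd, n - n_fwd) / n,
        strand_switch_rate=switches / (n - 1) if n > 1 else 0.0,
        contig_length=contig.length,
        gc_content=gc,
        mean_intergenic_gap=sum(gaps) / len(gaps) if gaps else 0.0,
    )
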