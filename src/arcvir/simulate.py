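"""Synthetic labeled contigs, hit tables, and microbial contaminant pools.

The generator plants the class-conditional structure the classifier relies
on, so every module is testable offline without reference databases:

* archaeal-virus contigs — a modest fraction of ORFs carries an annotation
  (mean 0.27, sd 0.23) but among annotated ORFs most affiliate with archaea
  or archaeal viruses (mean 0.71, sd 0.21), and iterative-profile hit counts
  are high (Poisson mean 18);
* phage contigs — most ORFs are annotated (mean 0.70, sd 0.33) yet almost
  none affiliate archaeally (mean 0.02, sd 0.06), and iterative-profile hits
  are rare (Poisson mean 0.5);
* microbial contaminants — 10-200 kb cellular fragments, half archaea and
  half bacteria, with sparse gene layouts and near-zero viral-database hit
  rates (archaeal fragments affiliate archaeally when annotated).

Hit tables are generated directly with e-values/bitscores that pass the
pipeline filters; the unit under test is the pipeline, not an aligner.
Regenerating from the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import seqio
from .homology import HitRecord, read_hits_tsv, write_hits_tsv
from .seqio import Contig, OrfRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}
# sense codons only: planted genes must not contain in-frame stops
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional homology structure for one contig class."""

    annotated_fraction_mean: float
    annotated_fraction_sd: float
    archaeal_fraction_mean: float
    archaeal_fraction_sd: float
    ocav_hit_rate: float  # Poisson mean of iterative-profile hits per contig

    def __post_init__(self) -> None:
        for v in (self.annotated_fraction_mean, self.archaeal_fraction_mean):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fraction means must be in [0, 1]")
        if self.ocav_hit_rate < 0:
            raise ValueError("ocav_hit_rate must be >= 0")


ARCHAEAL_PROFILE = ClassProfile(0.27, 0.23, 0.71, 0.21, 18.0)
PHAGE_PROFILE = ClassProfile(0.70, 0.33, 0.02, 0.06, 0.5)


@dataclass(frozen=True)
class SimulationConfig:
    n_per_class: int = 400
    seed: int = 0
    archaeal: ClassProfile = ARCHAEAL_PROFILE
    phage: ClassProfile = PHAGE_PROFILE
    contig_length_range: tuple[int, int] = (10_000, 50_000)
    orf_length_mean: int = 900  # nt, multiple-of-3 after clipping
    orf_length_sd: int = 300
    min_orf_nt: int = 150
    intergenic_gap_range: tuple[int, int] = (5, 200)
    strand_persistence: float = 0.75  # chance the next gene keeps the strand
    pvog_hit_prob: float = 0.6  # annotated ORFs also hit the profile-HMM db

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    contigs: list[Contig]
    orfs_by_contig: dict[str, list[OrfRecord]]
    hits: list[HitRecord]
    labels: dict[str, str]
    manifest: dict

    def subset(self, ids: Sequence[str]) -> "SyntheticDataset":
        keep = set(ids)
        return SyntheticDataset(
            contigs=[c for c in self.contigs if c.id in keep],
            orfs_by_contig={k: v for k, v in self.orfs_by_contig.items() if k in keep},
            hits=[h for h in self.hits if h.contig_id in keep],
            labels={k: v for k, v in self.labels.items() if k in keep},
            manifest=dict(self.manifest),
        )

    def fragment(self, target_size: int | None, seed: int = 0, subsample_to: int | None = None) -> "SyntheticDataset":
        """Size-fraction the dataset, carrying gene calls and hits along.

        Windows are 5'-anchored and exact; an ORF survives only when it lies
        entirely inside one window (coordinates are shifted), and a hit
        survives with its ORF — homology evidence on genes broken by the cut
        is lost, which is precisely the degradation fragmentation causes.
        """
        if target_size is None:
            return self
        frags: list[Contig] = []
        orfs_by: dict[str, list[OrfRecord]] = {}
        labels: dict[str, str] = {}
        orf_owner: dict[str, str] = {}
        for c in self.contigs:
            for k in range(c.length // target_size):
                lo, hi = k * target_size + 1, (k + 1) * target_size  # 1-based inclusive
                fid = f"{c.id}|frag{k + 1}"
                frags.append(Contig(id=fid, sequence=c.sequence[lo - 1 : hi]))
                labels[fid] = self.labels[c.id]
                kept: list[OrfRecord] = []
                for o in self.orfs_by_contig[c.id]:
                    if o.start >= lo and o.end <= hi:
                        kept.append(
                            dataclasses.replace(
                                o, contig_id=fid, start=o.start - lo + 1, end=o.end - lo + 1
                            )
                        )
                        orf_owner[o.orf_id] = fid
                orfs_by[fid] = kept
        n_out = subsample_to if subsample_to is not None else len(self.contigs)
        if len(frags) > n_out:
            rng = np.random.default_rng(seed)
            idx = sorted(rng.choice(len(frags), size=n_out, replace=False))
            frags = [frags[i] for i in idx]
        kept_ids = {f.id for f in frags}
        hits = [
            dataclasses.replace(h, contig_id=orf_owner[h.orf_id])
            for h in self.hits
            if orf_owner.get(h.orf_id) in kept_ids
        ]
        return SyntheticDataset(
            contigs=frags,
            orfs_by_contig={k: v for k, v in orfs_by.items() if k in kept_ids},
            hits=hits,
            labels={k: v for k, v in labels.items() if k in kept_ids},
            manifest={**self.manifest, "fragmented_to": target_size},
        )

    def merged_with(self, other: "SyntheticDataset") -> "SyntheticDataset":
        return SyntheticDataset(
            contigs=self.contigs + other.contigs,
            orfs_by_contig={**self.orfs_by_contig, **other.orfs_by_contig},
            hits=self.hits + other.hits,
            labels={**self.labels, **other.labels},
            manifest={"merged": [self.manifest, other.manifest]},
        )

    # -- on-disk layout shared with the CLI --------------------------------
    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(self.contigs, outdir / "contigs.fasta")
        all_orfs = [o for c in self.contigs for o in self.orfs_by_contig[c.id]]
        seqio.write_gene_table(all_orfs, outdir / "orfs.tsv")
        write_hits_tsv(self.hits, outdir / "hits.tsv")
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("contig_id\tlabel\n")
            for c in self.contigs:
                fh.write(f"{c.id}\t{self.labels[c.id]}\n")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticDataset":
        indir = Path(indir)
        contigs = seqio.read_fasta(indir / "contigs.fasta")
        orfs_by: dict[str, list[OrfRecord]] = {c.id: [] for c in contigs}
        for o in seqio.read_gene_table(indir / "orfs.tsv"):
            orfs_by[o.contig_id].append(o)
        labels: dict[str, str] = {}
        with open(indir / "labels.tsv") as fh:
            fh.readline()
            for line in fh:
                cid, lab = line.rstrip("\n").split("\t")
                labels[cid] = lab
        manifest = json.loads((indir / "manifest.json").read_text())
        return cls(contigs, orfs_by, read_hits_tsv(indir / "hits.tsv"), labels, manifest)


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _plant_contig(
    rng: np.random.Generator,
    contig_id: str,
    length: int,
    cfg: SimulationConfig,
    gap_scale: float = 1.0,
) -> tuple[Contig, list[OrfRecord]]:
    """Random background sequence with planted complete ORFs on both strands."""
    arr = _random_bases(rng, length)
    orfs: list[OrfRecord] = []
    lo_gap, hi_gap = cfg.intergenic_gap_range
    pos = int(rng.integers(int(lo_gap * gap_scale), int(hi_gap * gap_scale) + 1))
    strand = 1 if rng.random() < 0.5 else -1
    k = 0
    while True:
        nt = int(np.clip(rng.normal(cfg.orf_length_mean, cfg.orf_length_sd), cfg.min_orf_nt, 4500))
        nt -= nt % 3
        if pos + nt > length:
            break
        n_codons = nt // 3
        body = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)]
        gene = "ATG" + "".join(body) + "TAA"
        if strand == -1:
            gene = str(Seq(gene).reverse_complement())
        arr[pos : pos + nt] = np.frombuffer(gene.encode(), dtype="S1")
        k += 1
        start, end = pos + 1, pos + nt  # 1-based inclusive
        aa = str(Seq(gene if strand == 1 else str(Seq(gene).reverse_complement())).translate(table=11)).rstrip("*")
        orfs.append(
            OrfRecord(contig_id=contig_id, orf_id=f"{contig_id}_{k}", start=start, end=end, strand=strand, aa_seq=aa)
        )
        if rng.random() >= cfg.strand_persistence:
            strand = -strand
        pos = end + int(rng.integers(int(lo_gap * gap_scale), int(hi_gap * gap_scale) + 1))
    return Contig(id=contig_id, sequence=arr.tobytes().decode()), orfs


def _hits_for_contig(
    rng: np.random.Generator,
    orfs: Sequence[OrfRecord],
    profile: ClassProfile,
    cfg: SimulationConfig,
    viral: bool = True,
) -> list[HitRecord]:
    """Plant class-conditional hits that all pass the pipeline filters."""
    hits: list[HitRecord] = []
    n_orfs = len(orfs)
    if n_orfs == 0:
        return hits
    frac_annot = _truncnorm01(rng, profile.annotated_fraction_mean, profile.annotated_fraction_sd)
    n_annot = int(round(frac_annot * n_orfs))
    annotated = list(rng.choice(n_orfs, size=n_annot, replace=False)) if n_annot else []
    frac_arch = _truncnorm01(rng, profile.archaeal_fraction_mean, profile.archaeal_fraction_sd)
    n_arch = int(round(frac_arch * n_annot))
    arch_set = set(annotated[:n_arch])
    for idx in annotated:
        o = orfs[int(idx)]
        if int(idx) in arch_set:
            cls = "archaeal_virus" if rng.random() < 0.6 else "archaea"
        else:
            cls = "phage" if rng.random() < 0.7 else "bacteria"
        hits.append(
            HitRecord(
                orf_id=o.orf_id,
                contig_id=o.contig_id,
                target_id=f"nr|{cls}|{int(rng.integers(1, 10_000)):05d}",
                evalue=float(10.0 ** rng.uniform(-20, -6)),
                bitscore=float(rng.uniform(60, 300)),
                target_class=cls,
                source_db="protein_nr",
            )
        )
        pvog_prob = cfg.pvog_hit_prob if viral else 0.05
        if rng.random() < pvog_prob:
            vcls = "archaeal_virus" if int(idx) in arch_set else "phage"
            hits.append(
                HitRecord(
                    orf_id=o.orf_id,
                    contig_id=o.contig_id,
                    target_id=f"VOG{int(rng.integers(1, 30_000)):05d}",
                    evalue=float(10.0 ** rng.uniform(-25, -11)),
                    bitscore=float(rng.uniform(40, 250)),
                    target_class=vcls,
                    source_db="pvog_hmm",
                )
            )
    n_ocav = int(rng.poisson(profile.ocav_hit_rate))
    for _ in range(n_ocav):
        o = orfs[int(rng.integers(0, n_orfs))]
        hits.append(
            HitRecord(
                orf_id=o.orf_id,
                contig_id=o.contig_id,
                target_id=f"ocav|ref{int(rng.integers(1, 206)):03d}",
                evalue=float(10.0 ** rng.uniform(-20, -6)),
                bitscore=float(rng.uniform(60, 200)),
                target_class="archaeal_virus",
                source_db="ocav_profile",
            )
        )
    return hits


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate a labeled two-class contig set with planted homology structure."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    contigs: list[Contig] = []
    orfs_by: dict[str, list[OrfRecord]] = {}
    hits: list[HitRecord] = []
    labels: dict[str, str] = {}
    lo, hi = cfg.contig_length_range
    for label, prefix, profile in (
        ("archaeal_virus", "arcv", cfg.archaeal),
        ("phage", "phage", cfg.phage),
    ):
        for i in range(1, cfg.n_per_class + 1):
            cid = f"{prefix}{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            contig, orfs = _plant_contig(rng, cid, length, cfg)
            contigs.append(contig)
            orfs_by[cid] = orfs
            labels[cid] = label
            hits.extend(_hits_for_contig(rng, orfs, profile, cfg, viral=True))
    manifest = {"kind": "two_class_viral", "config": json.loads(cfg.to_json())}
    return SyntheticDataset(contigs, orfs_by, hits, labels, manifest)


#: annotation structure of cellular contaminant fragments
CONTAMINANT_PROFILES = {
    "archaea": ClassProfile(0.30, 0.15, 0.80, 0.15, 0.05),
    "bacteria": ClassProfile(0.30, 0.15, 0.02, 0.05, 0.0),
}


def simulate_contaminants(
    n: int,
    seed: int = 0,
    length_range: tuple[int, int] = (10_000, 200_000),
    config: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Microbial contaminant fragments: 10-200 kb, half archaea / half bacteria.

    Gene layouts are sparse (intergenic gaps an order of magnitude wider than
    the viral layout) and viral-database hit rates near zero; archaeal
    fragments mostly affiliate with archaea when annotated, mimicking the
    cellular fragments that drive false positives at high contamination.
    """
    if n < 2:
        raise ValueError("need at least 2 contaminant fragments")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    orfs_by: dict[str, list[OrfRecord]] = {}
    hits: list[HitRecord] = []
    labels: dict[str, str] = {}
    n_arch = n // 2
    for i in range(1, n + 1):
        cls = "archaea" if i <= n_arch else "bacteria"
        cid = f"mic{i:05d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        contig, orfs = _plant_contig(rng, cid, length, cfg, gap_scale=12.0)
        contigs.append(contig)
        orfs_by[cid] = orfs
        labels[cid] = cls
        hits.extend(_hits_for_contig(rng, orfs, CONTAMINANT_PROFILES[cls], cfg, viral=False))
    manifest = {"kind": "microbial_contaminants", "n": n, "seed": seed, "length_range": list(length_range)}
    return SyntheticDataset(contigs, orfs_by, hits, labels, manifest)
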