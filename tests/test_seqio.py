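"""Sequence I/O, the naive ORF scanner against a brute-force oracle, and
per-contig genomic attributes."""

import numpy as np
import pytest

from arcvir.seqio import (
    Contig,
    FastaError,
    OrfRecord,
    START_CODONS,
    STOP_CODONS,
    call_genes,
    genomic_attributes,
    naive_orf_scan,
    parse_prodigal_proteins,
    read_fasta,
    read_gene_table,
    write_fasta,
    write_gene_table,
)

RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s):
    return "".join(RC[b] for b in reversed(s))


def oracle_orfs(seq, min_nt=90):
    """Independent six-frame brute force: maximal (start..stop] spans.

    Returns a set of (start_1based, end_1based, strand).
    """
    found = set()
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        n = len(s)
        for frame in range(3):
            start = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if "N" in codon:
                    start = None
                    continue
                if codon in STOP_CODONS:
                    if start is not None and i + 3 - start >= min_nt:
                        if strand == 1:
                            found.add((start + 1, i + 3, 1))
                        else:
                            found.add((n - (i + 3) + 1, n - start, -1))
                    start = None
                elif start is None and codon in START_CODONS:
                    start = i
    return found


# ---------------------------------------------------------------------- FASTA


def test_read_fasta_roundtrip(tmp_path):
    contigs = [Contig("a", "ACGTACGTAA"), Contig("b", "GGGCCCATG")]
    p = tmp_path / "x.fasta"
    write_fasta(contigs, p)
    back = read_fasta(p)
    assert [(c.id, c.sequence) for c in back] == [(c.id, c.sequence) for c in contigs]


def test_read_fasta_uppercases_and_preserves_order(tmp_path):
    p = tmp_path / "x.fasta"
    p.write_text(">one\nacgt\n>two\nTTaa\n")
    contigs = read_fasta(p)
    assert [c.id for c in contigs] == ["one", "two"]
    assert [c.sequence for c in contigs] == ["ACGT", "TTAA"]
    assert [c.length for c in contigs] == [4, 4]


def test_read_fasta_empty_file_gives_empty_list(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert read_fasta(p) == []


@pytest.mark.parametrize(
    "text,msg",
    [("ACGT\n", "line 1"), (">a\nACGT\n>a\nTTTT\n", "duplicate")],
)
def test_read_fasta_rejects_malformed_input(tmp_path, text, msg):
    p = tmp_path / "bad.fasta"
    p.write_text(text)
    with pytest.raises(FastaError, match=msg):
        read_fasta(p)


# ------------------------------------------------------------------ ORF calls


def test_naive_scanner_finds_planted_orf_at_exact_coordinates():
    rng = np.random.default_rng(5)
    # background free of start codons in any frame: poly-C pads
    pad5, pad3 = "C" * 151, "C" * 100
    body = "".join(
        np.random.default_rng(1).choice(
            [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in STOP_CODONS | START_CODONS]
        , size=98)
    )
    gene = "ATG" + body + "TAA"  # 300 nt
    contig = Contig("p", pad5 + gene + pad3)
    orfs = naive_orf_scan(contig)
    fwd = [(o.start, o.end, o.strand) for o in orfs if o.strand == 1]
    assert (152, 451, 1) in fwd
    planted = next(o for o in orfs if (o.start, o.end) == (152, 451))
    assert planted.nt_length == 300
    assert len(planted.aa_seq) == 99  # stop excluded


def test_all_n_contig_yields_no_orfs():
    assert naive_orf_scan(Contig("n", "N" * 500)) == []


@pytest.mark.parametrize("seed", range(8))
def test_naive_scanner_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=900))
    got = {(o.start, o.end, o.strand) for o in naive_orf_scan(Contig("r", seq))}
    assert got == oracle_orfs(seq)


def test_prodigal_header_parse_two_genes(tmp_path):
    faa = tmp_path / "g.faa"
    faa.write_text(
        ">c1_1 # 337 # 2799 # 1 # ID=1_1;partial=00;start_type=ATG\nMKL\n"
        ">c1_2 # 3000 # 4000 # -1 # ID=1_2;partial=01;start_type=GTG\nMAA*\n"
    )
    orfs = parse_prodigal_proteins(faa, "c1")
    assert [(o.start, o.end, o.strand) for o in orfs] == [(337, 2799, 1), (3000, 4000, -1)]
    assert orfs[1].partial_left is False and orfs[1].partial_right is True
    assert orfs[1].aa_seq == "MAA"  # trailing stop stripped


def test_prodigal_backend_runs_on_synthetic_contig():
    from arcvir.simulate import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(n_per_class=1, seed=3, contig_length_range=(12000, 12000)))
    contig = ds.contigs[0]
    orfs = call_genes(contig, backend="prodigal")
    assert all(1 <= o.start < o.end <= contig.length for o in orfs)
    assert len(orfs) > 0  # planted genes are dense enough to be found


def test_gene_table_roundtrip(tmp_path):
    orfs = [
        OrfRecord("c", "c_1", 10, 309, 1, aa_seq="MKL"),
        OrfRecord("c", "c_2", 400, 999, -1, partial_right=True),
    ]
    p = tmp_path / "orfs.tsv"
    write_gene_table(orfs, p)
    assert read_gene_table(p) == orfs


# ------------------------------------------------------------------ attributes


def _orf(cid, start, end, strand=1):
    return OrfRecord(cid, f"{cid}_{start}", start, end, strand)


def test_attribute_formulas_density_and_coding_fraction():
    contig = Contig("c", "A" * 10_000)
    orfs = [_orf("c", 1 + i * 1000, 900 + i * 1000) for i in range(10)]  # 10 x 900 bp
    a = genomic_attributes(contig, orfs)
    assert a.gene_density == pytest.approx(1.0)
    assert a.coding_fraction == pytest.approx(0.9)


def test_strand_bias_and_mean_length():
    contig = Contig("c", "A" * 6000)
    orfs = [_orf("c", 1, 300), _orf("c", 400, 999, -1), _orf("c", 1200, 2099)]
    a = genomic_attributes(contig, orfs)
    assert a.mean_gene_length == pytest.approx(600)  # {300, 600, 900}
    assert a.strand_bias == pytest.approx(2 / 3)
    balanced = [_orf("c", 1 + i * 500, 300 + i * 500, 1 if i < 5 else -1) for i in range(10)]
    assert genomic_attributes(contig, balanced).strand_bias == pytest.approx(0.5)
    allfwd = [_orf("c", 1 + i * 500, 300 + i * 500, 1) for i in range(10)]
    assert genomic_attributes(contig, allfwd).strand_bias == pytest.approx(1.0)


def test_zero_orf_convention_flags_no_genes():
    a = genomic_attributes(Contig("c", "ACGT" * 100), [])
    assert a.no_genes and a.gene_density == 0 and a.strand_bias == 1.0
    assert a.mean_gene_length == 0 and a.coding_fraction == 0


def test_gc_content_ignores_ambiguous_bases():
    a = genomic_attributes(Contig("c", "GGCCAANN"), [])
    assert a.gc_content == pytest.approx(4 / 6)


def test_attributes_scale_consistent_under_self_concatenation():
    contig = Contig("c", "A" * 10_000)
    orfs = [_orf("c", 1 + i * 1000, 900 + i * 1000) for i in range(10)]
    doubled = Contig("c", contig.sequence * 2)
    orfs2 = orfs + [_orf("c", o.start + 10_000, o.end + 10_000) for o in orfs]
    a1, a2 = genomic_attributes(contig, orfs), genomic_attributes(doubled, orfs2)
    assert a2.gene_density == pytest.approx(a1.gene_density)
    assert a2.coding_fraction == pytest.approx(a1.coding_fraction)


def test_orf_outside_contig_rejected():
    with pytest.raises(ValueError, match="extends past"):
        genomic_attributes(Contig("c", "A" * 100), [_orf("c", 50, 200)])
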