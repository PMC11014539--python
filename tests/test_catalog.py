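"""Catalog parsing, pyrimidine-frame context annotation, and motif counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobec_smoke.catalog import (
    CatalogError,
    MotifCounts,
    Mutation,
    MutationCatalog,
    ReferenceMismatchError,
    annotate_context,
    count_motifs,
    genome_length,
    read_mutations,
)
from apobec_smoke.simulate import (
    SimulationConfig,
    SiteInventory,
    simulate_sample,
    write_vcf,
)

# test-local complement table, independent of the package helper
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s):
    return "".join(_COMP[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=10000>\n"
    '##INFO=<ID=CCF,Number=1,Type=Float,Description="ccf">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def test_vcf_snv_filter_drops_indels(tmp_path):
    """Indel and MNV rows are excluded; only true SNVs survive."""
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        VCF_HEADER
        + "chr1\t100\t.\tC\tT\t.\tPASS\tCCF=1.0\n"
        + "chr1\t200\t.\tG\tA\t.\tPASS\tCCF=0.3\n"
        + "chr1\t300\t.\tCA\tC\t.\tPASS\t.\n"        # deletion
        + "chr1\t400\t.\tT\tG\t.\tPASS\t.\n"
    )
    cat = read_mutations(vcf, "vcf", "s1")
    assert len(cat) == 3
    assert [m.pos for m in cat] == [100, 200, 400]
    assert cat.mutations[0].ccf == 1.0
    assert cat.mutations[2].ccf is None


def test_maf_dedup_and_required_columns(tmp_path):
    maf = tmp_path / "t.maf"
    header = "Chromosome\tStart_Position\tReference_Allele\tTumor_Seq_Allele2\tTumor_Sample_Barcode\n"
    maf.write_text(header + "chr1\t100\tC\tT\ts1\n" * 2 + "chr1\t200\tCA\tC\ts1\n")
    cat = read_mutations(maf, "maf", "s1")
    assert len(cat) == 1  # identical rows deduplicated, indel dropped

    bad = tmp_path / "bad.maf"
    bad.write_text("Chromosome\tStart_Position\n1\t2\n")
    with pytest.raises(CatalogError):
        read_mutations(bad, "maf", "s1")


def test_vcf_roundtrip_with_simulator_truth(tmp_path, refseq, sites):
    """Write-then-read round trip preserves (chrom, pos, ref, alt) exactly."""
    cfg = SimulationConfig(total_mutations=300, kataegis_lambda=1.0)
    rng = np.random.default_rng(7)
    records, _ = simulate_sample(refseq, sites, cfg, rng, age=60, ploidy=2.0, latency=5.0)
    path = tmp_path / "sim.vcf"
    write_vcf(records, path, "chr1", len(refseq))
    cat = read_mutations(path, "vcf", "sim")
    assert [(m.chrom, m.pos, m.ref, m.alt) for m in cat] == [
        (r["chrom"], r["pos"], r["ref"], r["alt"]) for r in records
    ]
    assert all(m.ccf is not None for m in cat)


def test_catalog_sorted_and_deduplicated():
    cat = MutationCatalog("s", [
        Mutation("chr2", 5, "C", "T"),
        Mutation("chr1", 9, "G", "A"),
        Mutation("chr1", 2, "C", "G"),
        Mutation("chr1", 9, "G", "A"),
    ])
    assert [(m.chrom, m.pos) for m in cat] == [("chr1", 2), ("chr1", 9), ("chr2", 5)]


# ---------------------------------------------------------------------------
# context annotation
# ---------------------------------------------------------------------------

def test_plus_strand_c_context(catalog_factory):
    cat = catalog_factory([("c", 4, "C", "T")])
    annotate_context(cat, {"c": "AATCAGG"})
    m = cat.mutations[0]
    assert (m.context5, m.pyr_ref, m.pyr_alt) == ("ATCAG", "C", "T")


def test_purine_strand_flip(catalog_factory):
    cat = catalog_factory([("c", 4, "G", "A")])
    annotate_context(cat, {"c": "AATGAGG"})
    m = cat.mutations[0]
    assert (m.context5, m.pyr_ref, m.pyr_alt) == ("CTCAT", "C", "T")


def test_context_matches_string_oracle(refseq, ref_handle):
    """Annotation equals brute-force substring extraction + conditional revcomp."""
    rng = np.random.default_rng(11)
    positions = rng.choice(np.arange(10, len(refseq) - 10), size=100, replace=False)
    muts = []
    for p in positions:
        ref = refseq[p - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        muts.append(Mutation("chr1", int(p), ref, alt))
    cat = MutationCatalog("s", muts)
    annotate_context(cat, ref_handle)
    for m in cat:
        window = refseq[m.pos - 3:m.pos + 2]
        expect = rc(window) if refseq[m.pos - 1] in "GA" else window
        assert m.context5 == expect
        assert m.context5[2] == m.pyr_ref
        assert m.pyr_ref in "CT"


def test_annotate_is_idempotent(refseq, ref_handle):
    cat = MutationCatalog("s", [Mutation("chr1", 1000, refseq[999],
                                         "A" if refseq[999] != "A" else "C")])
    annotate_context(cat, ref_handle)
    first = (cat.mutations[0].context5, cat.mutations[0].pyr_ref, cat.mutations[0].pyr_alt)
    annotate_context(cat, ref_handle)
    assert (cat.mutations[0].context5, cat.mutations[0].pyr_ref,
            cat.mutations[0].pyr_alt) == first


def test_annotation_errors(catalog_factory):
    with pytest.raises(ReferenceMismatchError):
        annotate_context(catalog_factory([("c", 4, "G", "A")]), {"c": "AATCAGG"})
    with pytest.raises(CatalogError):
        annotate_context(catalog_factory([("c", 999, "C", "T")]), {"c": "AATCAGG"})
    with pytest.raises(CatalogError):  # < 2 flanking bases
        annotate_context(catalog_factory([("c", 2, "A", "T")]), {"c": "AATCAGG"})


def test_n_in_window_flagged(catalog_factory):
    cat = catalog_factory([("c", 4, "C", "T")])
    annotate_context(cat, {"c": "ANTCAGG"})
    assert cat.mutations[0].context_ok is False


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------

def brute_motif_counts(seq):
    """Independent oracle: scan every offset of seq and its reverse complement."""
    seqs = (seq, rc(seq))

    def occ(pats):
        return sum(
            1 for s in seqs for i in range(len(s)) for p in pats
            if s[i:i + len(p)] == p
        )

    return MotifCounts(
        n_C=sum(s.count("C") for s in seqs),
        n_TCW=occ(["TCA", "TCT"]),
        n_TCA=occ(["TCA"]),
        n_YTCA=occ(["CTCA", "TTCA"]),
        n_RTCA=occ(["ATCA", "GTCA"]),
    )


def test_hand_countable_string():
    counts = count_motifs({"c": "TCATCA"}, scope="genome")
    assert (counts.n_TCA, counts.n_C, counts.n_TCW) == (2, 2, 2)


def test_strand_symmetry_hand_case():
    a = count_motifs({"c": "TCATCA"}, scope="genome")
    b = count_motifs({"c": "TGATGA"}, scope="genome")
    assert (a.n_C, a.n_TCW, a.n_TCA, a.n_YTCA, a.n_RTCA) == \
           (b.n_C, b.n_TCW, b.n_TCA, b.n_YTCA, b.n_RTCA)


def test_exhaustive_scan_oracle(refseq):
    """Genome-scope counts equal a brute-force scan over both strands (10 kb)."""
    sub = refseq[:10_000]
    got = count_motifs({"c": sub}, scope="genome")
    exp = brute_motif_counts(sub)
    assert (got.n_C, got.n_TCW, got.n_TCA, got.n_YTCA, got.n_RTCA) == \
           (exp.n_C, exp.n_TCW, exp.n_TCA, exp.n_YTCA, exp.n_RTCA)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=4, max_size=60))
def test_strand_symmetry_property(s):
    a = count_motifs({"c": s}, scope="genome")
    b = count_motifs({"c": rc(s)}, scope="genome")
    assert (a.n_C, a.n_TCW, a.n_TCA, a.n_YTCA, a.n_RTCA) == \
           (b.n_C, b.n_TCW, b.n_TCA, b.n_YTCA, b.n_RTCA)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=4, max_size=80))
def test_tetranucleotide_partition_property(s):
    """Every TCA occurrence with a defined 5' flank is exactly one of YTCA/RTCA."""
    got = count_motifs({"c": s}, scope="genome")
    flanked = sum(
        1 for strand in (s, rc(s)) for i in range(1, len(strand))
        if strand[i:i + 3] == "TCA"
    )
    assert got.n_YTCA + got.n_RTCA == flanked
    assert got.n_TCA >= flanked
    assert got.n_TCW <= got.n_C


def test_window_scope_merges_overlaps(refseq, ref_handle, catalog_factory):
    """Window counts equal a genome-scope count of the merged union sequence."""
    cat = catalog_factory([("chr1", 1000, refseq[999], "T" if refseq[999] != "T" else "A"),
                           ("chr1", 1015, refseq[1014], "T" if refseq[1014] != "T" else "A"),
                           ("chr1", 3000, refseq[2999], "T" if refseq[2999] != "T" else "A")])
    got = count_motifs(ref_handle, cat, window=20, scope="windows")
    # mutations 1 and 2 are 15 bp apart: one merged window [979, 1035), plus [2979, 3020)
    union = {"a": refseq[979:1035], "b": refseq[2979:3020]}
    exp = count_motifs(union, scope="genome")
    assert (got.n_C, got.n_TCW, got.n_TCA) == (exp.n_C, exp.n_TCW, exp.n_TCA)


def test_window_scope_empty_catalog_warns(ref_handle, catalog_factory):
    counts = count_motifs(ref_handle, catalog_factory([]), scope="windows")
    assert counts.n_C == 0 and counts.n_TCW == 0


def test_genome_length_excludes_n():
    assert genome_length({"c": "ACGTNNACGT"}) == 8
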