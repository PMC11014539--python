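"""LAS/HAS decision rule, YTCA/RTCA phenotype, and subtype association tests."""

import itertools
import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apobec_smoke.catalog import (
    MotifCounts,
    Mutation,
    MutationCatalog,
    annotate_context,
    count_motifs,
)
from apobec_smoke.enrichment import EnrichmentResult
from apobec_smoke.subtypes import (
    SignatureAttribution,
    assign_subtype,
    classify_phenotypes,
    signature_presence,
    subtype_association,
    ytca_rtca_counts,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s):
    return "".join(_COMP[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# signature presence and the decision table
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sbs2_13,total,expected", [
    (400, 10_000, False),   # 4% < 5% fraction threshold
    (49, 500, False),       # 9.8% but below the 50-mutation minimum
    (600, 10_000, True),    # both criteria met
    (50, 1000, True),       # exactly at both boundaries (5%, 50)
])
def test_signature_presence_thresholds(sbs2_13, total, expected):
    attr = SignatureAttribution("s", {"SBS2": sbs2_13 // 2, "SBS13": sbs2_13 - sbs2_13 // 2},
                                total)
    assert signature_presence(attr) is expected


def test_signature_presence_zero_total_rejected():
    with pytest.raises(ValueError):
        signature_presence(SignatureAttribution("s", {"SBS2": 0, "SBS13": 0}, 0))


def test_subtype_decision_table_exhaustive():
    """All four evidence combinations map to the documented subtype."""
    expected = {(True, True): "HAS", (True, False): "LAS",
                (False, True): "LAS", (False, False): "no_APOBEC"}
    for sig, enr in itertools.product([True, False], repeat=2):
        assert assign_subtype(sig, enr) == expected[(sig, enr)]


# ---------------------------------------------------------------------------
# YTCA/RTCA chi-square phenotype
# ---------------------------------------------------------------------------

def _tca_catalog(n_ytca, n_rtca):
    """Catalog of C>T mutations at TCA with controlled 5' flanks (pyr frame)."""
    muts = []
    pos = 100
    for flank, n in (("T", n_ytca), ("A", n_rtca)):
        for _ in range(n):
            m = Mutation("chr1", pos, "C", "T")
            m.pyr_ref, m.pyr_alt = "C", "T"
            m.context5 = flank + "TCA" + "G"
            m.context_ok = True
            muts.append(m)
            pos += 1000
    return MutationCatalog("s", muts, genome_length=10**6)


BALANCED = MotifCounts(n_C=10_000, n_TCW=4000, n_TCA=2000, n_YTCA=1000, n_RTCA=1000)


def test_chi2_zero_under_perfect_null():
    call = ytca_rtca_counts(_tca_catalog(50, 50), BALANCED)
    assert call.chi2 == pytest.approx(0.0)
    assert (call.n_ytca, call.n_rtca) == (50, 50)
    assert call.exp_ytca == pytest.approx(50.0)


def test_chi2_hand_computation():
    """(75, 25) observed against a 50/50 expectation: chi2 = 25^2/50 + 25^2/50 = 25."""
    call = ytca_rtca_counts(_tca_catalog(75, 25), BALANCED)
    assert call.chi2 == pytest.approx(25.0)
    assert call.p_pheno == pytest.approx(float(stats.chi2.sf(25.0, 1)))


@pytest.mark.parametrize("n_y,n_r", [(3, 7), (10, 0), (0, 10), (25, 25), (40, 9)])
def test_chi2_matches_scipy_goodness_of_fit(n_y, n_r):
    """Exhaustive small-table agreement with an independent chi-square oracle."""
    call = ytca_rtca_counts(_tca_catalog(n_y, n_r), BALANCED)
    oracle = stats.chisquare([n_y, n_r], f_exp=[(n_y + n_r) / 2, (n_y + n_r) / 2])
    assert call.chi2 == pytest.approx(float(oracle.statistic), abs=1e-12)
    assert call.p_pheno == pytest.approx(float(oracle.pvalue), abs=1e-12)


def test_zero_tca_mutations_gives_na():
    call = ytca_rtca_counts(_tca_catalog(0, 0), BALANCED)
    assert call.phenotype == "NA"


def test_zero_motif_inventory_rejected():
    with pytest.raises(ValueError):
        ytca_rtca_counts(_tca_catalog(5, 5), MotifCounts(n_C=10, n_TCW=4, n_TCA=0))


def _enr(sample_id, tca_enriched=True):
    e = EnrichmentResult(sample_id)
    e.tca_enriched_flag = tca_enriched
    return e


def test_phenotype_assignment_with_gate():
    """Significant YTCA excess -> A3A-like; RTCA excess -> A3B-like; gated samples NA."""
    calls = [ytca_rtca_counts(_tca_catalog(90, 10), BALANCED),
             ytca_rtca_counts(_tca_catalog(10, 90), BALANCED),
             ytca_rtca_counts(_tca_catalog(51, 49), BALANCED),
             ytca_rtca_counts(_tca_catalog(90, 10), BALANCED)]
    for i, c in enumerate(calls):
        c.sample_id = f"s{i}"
    enrs = [_enr("s0"), _enr("s1"), _enr("s2"), _enr("s3", tca_enriched=False)]
    out = classify_phenotypes(calls, enrs)
    assert [c.phenotype for c in out] == ["A3A_like", "A3B_like", "NA", "NA"]


def test_phenotype_invariant_to_reverse_complement(refseq):
    """Mirroring the genome and every mutation leaves YTCA/RTCA counts unchanged."""
    rng = np.random.default_rng(5)
    from apobec_smoke.simulate import SiteInventory

    sites = SiteInventory(refseq)
    picks = rng.choice(sites.tca_plus, 40, replace=False)
    muts = [Mutation("chr1", int(p) + 1, "C", "T") for p in picks]
    cat = MutationCatalog("s", muts, genome_length=len(refseq))
    annotate_context(cat, {"chr1": refseq})
    motifs = count_motifs({"chr1": refseq}, scope="genome")
    call = ytca_rtca_counts(cat, motifs)

    mirror_seq = rc(refseq)
    L = len(refseq)
    mirror_muts = [Mutation("chr1", L - int(p), "G", "A") for p in picks]
    mcat = MutationCatalog("s", mirror_muts, genome_length=L)
    annotate_context(mcat, {"chr1": mirror_seq})
    mmotifs = count_motifs({"chr1": mirror_seq}, scope="genome")
    mcall = ytca_rtca_counts(mcat, mmotifs)
    assert (call.n_ytca, call.n_rtca) == (mcall.n_ytca, mcall.n_rtca)
    assert call.chi2 == pytest.approx(mcall.chi2)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Exact two-sided Fisher P: sum of hypergeometric masses <= observed mass."""
    (a, b), (c, d) = table
    r1, r2, col1 = a + b, c + d, a + c
    n = r1 + r2

    def mass(x):
        return comb(r1, x) * comb(r2, col1 - x) / comb(n, col1)

    m_obs = mass(a)
    return sum(mass(x) for x in range(max(0, col1 - r2), min(r1, col1) + 1)
               if mass(x) <= m_obs * (1 + 1e-12))


def test_identical_outcome_distribution_null():
    df = pd.DataFrame({
        "feature": [1, 0] * 20,
        "subtype": ["HAS"] * 20 + ["LAS"] * 20,
    })
    out = subtype_association(df, "feature")
    assert out["fisher_or"] == pytest.approx(1.0)
    assert out["fisher_p"] == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    df = pd.DataFrame({
        "feature": [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30,
        "subtype": ["HAS"] * 40 + ["LAS"] * 40,
    })
    out = subtype_association(df, "feature")
    assert out["table"] == [[30, 10], [10, 30]]
    assert out["fisher_p"] == pytest.approx(fisher_two_sided_oracle([[30, 10], [10, 30]]),
                                            rel=1e-9)


def test_association_power_with_covariates():
    """Feature prevalence 0.6 in HAS vs 0.2 in LAS (n=100 each) is detected."""
    rng = np.random.default_rng(2)
    hits = 0
    n_rep = 20
    for _ in range(n_rep):
        feat = np.concatenate([rng.random(100) < 0.6, rng.random(100) < 0.2])
        df = pd.DataFrame({
            "feature": feat.astype(int),
            "subtype": ["HAS"] * 100 + ["LAS"] * 100,
            "age": rng.integers(45, 80, 200),
            "sex": rng.choice(["M", "F"], 200),
            "tmb": rng.uniform(1, 30, 200),
        })
        out = subtype_association(df, "feature", covariates=["age", "sex", "tmb"])
        hits += out["converged"] and out["p_value"] < 0.05 and out["log_or"] > 0
    assert hits >= 0.9 * n_rep
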