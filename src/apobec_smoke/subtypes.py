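"""LAS/HAS subtype calls and A3A-like vs A3B-like phenotype classification.

Two orthogonal lines of evidence define the subtypes: (i) signature attribution —
at least 5% of a sample's mutations and at least 50 mutations assigned to the
APOBEC signatures SBS2+SBS13 — and (ii) motif evidence — significant TCW
enrichment after BH correction. Samples positive by both are High APOBEC Subtype
(HAS); samples positive by motif enrichment only, or by neither, are Low APOBEC
Subtype (no-APOBEC being the doubly negative corner of LAS kept distinct here).

The A3A-like vs A3B-like phenotype uses the tetranucleotide context of APOBEC-type
mutations at TCA: APOBEC3A prefers YTCA (Y = C/T), APOBEC3B prefers RTCA
(R = A/G). Under random mutagenesis the YTCA:RTCA split of mutations follows the
motif availability in the genome; a 1-df chi-square goodness-of-fit test against
that expectation, BH-corrected across the cohort, flags samples with a biased
ratio. Phenotypes are only evaluated for samples enriched for TCA mutations
(same one-sided Fisher machinery as TCW, with TCA in place of TCW).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .catalog import MotifCounts, MutationCatalog
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass
class SignatureAttribution:
    sample_id: str
    counts: Dict[str, float]
    total: int


@dataclass
class SubtypeCall:
    sample_id: str
    sig_present: bool = False
    enriched: bool = False
    subtype: str = "no_APOBEC"      # {HAS, LAS, no_APOBEC}
    phenotype: str = "NA"           # {A3A_like, A3B_like, NA}
    n_ytca: int = 0
    n_rtca: int = 0
    exp_ytca: float = math.nan
    exp_rtca: float = math.nan
    chi2: float = 0.0
    p_pheno: float = 1.0
    q_pheno: float = math.nan
    tca_enriched: bool = False


def signature_presence(attr: SignatureAttribution, frac_threshold: float = 0.05,
                       min_count: int = 50) -> bool:
    """APOBEC signature evidence: SBS2+SBS13 >= 5% of mutations AND >= 50 mutations."""
    if attr.total <= 0:
        raise ValueError(f"{attr.sample_id}: total mutation count must be positive")
    apo = attr.counts.get("SBS2", 0) + attr.counts.get("SBS13", 0)
    return (apo / attr.total >= frac_threshold) and (apo >= min_count)


def assign_subtype(sig_present: bool, enriched: bool) -> str:
    """Two-evidence decision table for the APOBEC subtype call.

    (sig, motif): (T,T)->HAS, (F,T)->LAS, (F,F)->no_APOBEC. The (T,F) corner is
    unobserved in practice (motif enrichment confirms every signature-positive
    sample); it maps conservatively to LAS with a logged discordance warning.
    """
    if sig_present and enriched:
        return "HAS"
    if sig_present and not enriched:
        logger.warning("discordant evidence: signature present without motif enrichment -> LAS")
        return "LAS"
    if enriched:
        return "LAS"
    return "no_APOBEC"


def ytca_rtca_counts(catalog: MutationCatalog, motifs: MotifCounts) -> SubtypeCall:
    """Observed/expected YTCA vs RTCA mutation counts and the chi-square statistic.

    Observed counts are APOBEC-type (C>T/C>G pyrimidine-frame) mutations at TCA,
    split by the 5' neighbor of the T in pyrimidine frame. Expected counts scale
    the total by the genomic motif fractions n_YTCA/(n_YTCA+n_RTCA). No Yates
    correction (large counts expected). q and phenotype are cohort-level.
    """
    if motifs.n_YTCA + motifs.n_RTCA == 0:
        raise ValueError("no YTCA/RTCA motifs in the evaluated sequence space")
    call = SubtypeCall(sample_id=catalog.sample_id)
    for m in catalog:
        if not (m.context_ok and m.is_apobec_type and m.at_tca):
            continue
        flank = m.context5[0]
        if flank in "CT":
            call.n_ytca += 1
        elif flank in "AG":
            call.n_rtca += 1
    n_obs = call.n_ytca + call.n_rtca
    if n_obs == 0:
        call.phenotype = "NA"
        call.p_pheno = 1.0
        return call
    f_y = motifs.n_YTCA / (motifs.n_YTCA + motifs.n_RTCA)
    call.exp_ytca = n_obs * f_y
    call.exp_rtca = n_obs * (1 - f_y)
    chi2 = 0.0
    for obs, exp in ((call.n_ytca, call.exp_ytca), (call.n_rtca, call.exp_rtca)):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    call.chi2 = chi2
    call.p_pheno = float(stats.chi2.sf(chi2, df=1))
    return call


def classify_phenotypes(calls: List[SubtypeCall],
                        enrichments: List[EnrichmentResult],
                        alpha: float = 0.05) -> List[SubtypeCall]:
    """Cohort-level phenotype assignment with BH correction and the TCA gate.

    A sample is A3A-like when its YTCA:RTCA ratio deviates significantly (Q<alpha)
    with YTCA excess, A3B-like with RTCA excess; samples not enriched for TCA
    mutations, or without a significant deviation, are NA.
    """
    by_id = {e.sample_id: e for e in enrichments}
    q = multipletests([c.p_pheno for c in calls], method="fdr_bh")[1]
    for c, qi in zip(calls, q):
        c.q_pheno = float(qi)
        enr = by_id.get(c.sample_id)
        c.tca_enriched = bool(enr.tca_enriched_flag) if enr is not None else False
        c.phenotype = "NA"
        if not c.tca_enriched or qi >= alpha or (c.n_ytca + c.n_rtca) == 0:
            continue
        if c.exp_ytca > 0 and c.n_ytca / c.exp_ytca > 1:
            c.phenotype = "A3A_like"
        elif c.exp_rtca > 0 and c.n_rtca / c.exp_rtca > 1:
            c.phenotype = "A3B_like"
    return calls


def call_subtypes(attributions: List[SignatureAttribution],
                  enrichments: List[EnrichmentResult],
                  phenotype_calls: Optional[List[SubtypeCall]] = None,
                  frac_threshold: float = 0.05, min_count: int = 50) -> List[SubtypeCall]:
    """Combine signature and enrichment evidence into per-sample subtype calls."""
    by_id = {e.sample_id: e for e in enrichments}
    pheno_by_id = {c.sample_id: c for c in (phenotype_calls or [])}
    out = []
    for attr in attributions:
        enr = by_id[attr.sample_id]
        call = pheno_by_id.get(attr.sample_id, SubtypeCall(sample_id=attr.sample_id))
        call.sig_present = signature_presence(attr, frac_threshold, min_count)
        call.enriched = bool(enr.enriched_flag)
        call.subtype = assign_subtype(call.sig_present, call.enriched)
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# downstream association
# ---------------------------------------------------------------------------

def subtype_association(feature_table: pd.DataFrame, outcome: str,
                        subtype_col: str = "subtype",
                        covariates: Optional[List[str]] = None) -> dict:
    """Logistic regression of a binary feature on subtype, plus unadjusted Fisher.

    ``feature_table`` holds one row per sample with the binary ``outcome`` column,
    the subtype call, and covariate columns. Categorical covariates (sex,
    histology) are indicator-encoded; TMB is log10-transformed. The subtype term
    is coded HAS=1, LAS/other=0. Complete separation is flagged as non-converged
    rather than silently dropped.
    """
    df = feature_table.copy()
    y = df[outcome].astype(int)
    subtype_ind = (df[subtype_col] == "HAS").astype(int).rename("subtype_HAS")
    X = [subtype_ind]
    for cov in covariates or []:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            X.append(pd.get_dummies(col, prefix=cov, drop_first=True).astype(float))
        elif cov.lower() == "tmb":
            X.append(np.log10(col.astype(float) + 1).rename("log10_tmb"))
        else:
            X.append(col.astype(float))
    X = sm.add_constant(pd.concat(X, axis=1))

    out = {"outcome": outcome, "converged": False, "log_or": math.nan,
           "ci_low": math.nan, "ci_high": math.nan, "p_value": math.nan}
    try:
        fit = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=200)
        beta = fit.params["subtype_HAS"]
        se = fit.bse["subtype_HAS"]
        if np.isfinite(beta) and np.isfinite(se) and se < 50:
            out.update(converged=bool(fit.mle_retvals["converged"]), log_or=float(beta),
                       ci_low=float(beta - 1.96 * se), ci_high=float(beta + 1.96 * se),
                       p_value=float(fit.pvalues["subtype_HAS"]))
    except Exception as exc:  # perfect separation raises in statsmodels
        logger.warning("logistic regression failed for %s: %s", outcome, exc)

    # unadjusted two-sided Fisher on the 2x2 feature x subtype table
    has = df[subtype_col] == "HAS"
    table = [[int((y[has] == 1).sum()), int((y[has] == 0).sum())],
             [int((y[~has] == 1).sum()), int((y[~has] == 0).sum())]]
    odds, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    out["fisher_or"] = float(odds)
    out["fisher_p"] = float(p_fisher)
    out["table"] = table
    return out


def calls_to_frame(calls: List[SubtypeCall]) -> pd.DataFrame:
    cols = ["sample_id", "sig_present", "enriched", "subtype", "phenotype",
            "n_ytca", "n_rtca", "exp_ytca", "exp_rtca", "chi2", "p_pheno",
            "q_pheno", "tca_enriched"]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in calls], columns=cols)
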