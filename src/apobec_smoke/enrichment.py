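"""Per-sample TCW enrichment, Fisher test, BH correction, minimum APOBEC load.

The enrichment statistic compares the fraction of APOBEC-type mutations (C>T and
C>G in pyrimidine frame) falling at TCW motifs with the fraction of evaluated
cytosines that sit in a TCW context:

    E_TCW = (mut_TCW / ctx_TCW) / (mut_C / ctx_C)

A one-sided (greater) Fisher exact test on the 2x2 table
[[mut_TCW, mut_C - mut_TCW], [ctx_TCW, ctx_C - ctx_TCW]] gives the sample-specific
P-value; Benjamini-Hochberg correction across the cohort flags enriched samples at
Q < alpha. The minimum APOBEC load is mut_TCW x (E-1)/E for E > 1 — the excess of
TCW mutations over the random expectation, a lower bound on the APOBEC-attributable
burden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import MotifCounts, MutationCatalog


@dataclass
class EnrichmentResult:
    sample_id: str
    mut_tcw: int = 0
    mut_c: int = 0
    ctx_tcw: int = 0
    ctx_c: int = 0
    e_tcw: float = 0.0
    p_fisher: float = 1.0
    q_bh: float = math.nan
    apobec_load_min: float = 0.0
    apobec_load_min_rounded: int = 0
    enriched_flag: bool = False
    # TCA-restricted analogues used by the A3A/A3B phenotype gate
    mut_tca: int = 0
    ctx_tca: int = 0
    p_fisher_tca: float = 1.0
    q_bh_tca: float = math.nan
    tca_enriched_flag: bool = False


def tcw_enrichment(catalog: MutationCatalog, motifs: MotifCounts,
                   alpha: float = 0.05) -> EnrichmentResult:
    """Compute E_TCW, the one-sided Fisher P and the minimum load for one sample.

    Only pyrimidine-frame C>T/C>G mutations with a clean (N-free) context enter the
    counts. ``q_bh`` stays NaN until :func:`cohort_adjust` fills it.
    """
    apo = [m for m in catalog if m.context_ok and m.is_apobec_type]
    return enrichment_from_counts(
        catalog.sample_id,
        mut_tcw=sum(1 for m in apo if m.at_tcw),
        mut_c=len(apo),
        motifs=motifs,
        mut_tca=sum(1 for m in apo if m.at_tca),
    )


def enrichment_from_counts(sample_id: str, mut_tcw: int, mut_c: int,
                           motifs: MotifCounts, mut_tca: int = 0) -> EnrichmentResult:
    """Enrichment statistic from pre-tabulated mutation counts."""
    if motifs.n_TCW == 0 or motifs.n_C == 0:
        raise ValueError("undefined enrichment statistic: zero TCW or C motif count")
    if mut_tcw > mut_c:
        raise ValueError("mut_tcw cannot exceed mut_c")
    res = EnrichmentResult(
        sample_id=sample_id, mut_tcw=mut_tcw, mut_c=mut_c, mut_tca=mut_tca,
        ctx_tcw=motifs.n_TCW, ctx_c=motifs.n_C, ctx_tca=motifs.n_TCA,
    )
    if res.mut_c > 0:
        res.e_tcw = (res.mut_tcw / res.ctx_tcw) / (res.mut_c / res.ctx_c)
    res.p_fisher = _fisher_greater(res.mut_tcw, res.mut_c - res.mut_tcw,
                                   res.ctx_tcw, res.ctx_c - res.ctx_tcw)
    if motifs.n_TCA > 0:
        res.p_fisher_tca = _fisher_greater(res.mut_tca, res.mut_c - res.mut_tca,
                                           res.ctx_tca, res.ctx_c - res.ctx_tca)
    return min_apobec_load(res)


def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def min_apobec_load(result: EnrichmentResult) -> EnrichmentResult:
    """Fill APOBEC_MutLoad_MinEstimate: mut_TCW x (E-1)/E for E > 1, else 0.

    Stored unrounded plus a half-even-rounded integer companion.
    """
    if result.e_tcw > 1:
        result.apobec_load_min = result.mut_tcw * (result.e_tcw - 1) / result.e_tcw
    else:
        result.apobec_load_min = 0.0
    # Python round() is banker's (half-even) rounding
    result.apobec_load_min_rounded = int(round(result.apobec_load_min))
    return result


def cohort_adjust(results: List[EnrichmentResult], alpha: float = 0.05) -> List[EnrichmentResult]:
    """Benjamini-Hochberg step-up across the cohort; sets q_bh and enriched_flag.

    The TCA-restricted Fisher P-values (phenotype gate) are adjusted in the same
    pass. Input order is preserved.
    """
    if not results:
        raise ValueError("cohort_adjust requires at least one result")
    q = multipletests([r.p_fisher for r in results], method="fdr_bh")[1]
    q_tca = multipletests([r.p_fisher_tca for r in results], method="fdr_bh")[1]
    for r, qi, qt in zip(results, q, q_tca):
        r.q_bh = float(qi)
        r.enriched_flag = bool(qi < alpha)
        r.q_bh_tca = float(qt)
        r.tca_enriched_flag = bool(qt < alpha)
    return results


def results_to_frame(results: List[EnrichmentResult]) -> pd.DataFrame:
    cols = ["sample_id", "mut_tcw", "mut_c", "ctx_tcw", "ctx_c", "e_tcw",
            "p_fisher", "q_bh", "apobec_load_min", "apobec_load_min_rounded",
            "enriched_flag", "mut_tca", "ctx_tca", "p_fisher_tca", "q_bh_tca",
            "tca_enriched_flag"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
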