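"""Cell-of-origin inference by Gamma-Poisson regression of binned mutation density.

Somatic mutation density is depleted in regions that were highly expressed and
open in the tumor's cell of origin (transcription-coupled repair, early
replication, active chromatin). Regressing per-bin SNV counts on a cell type's
expression centroid — with replication timing, GC fraction, mean expression
across centroids and log intronic/exonic fractions as covariates — therefore
yields a relative risk (RR) per unit centroid expression below 1 for the true
cell of origin; the inferred COO is the cell type with the smallest RR. Counts
are overdispersed, so a Gamma-Poisson (negative binomial, variance mu + phi*mu^2)
likelihood is used, one separate fit per cell type.

Default centroid schema: the seven benign lung cell types (basal,
neuroendocrine, goblet, ciliated, club, AT1, AT2); proximal airway types are
basal/neuroendocrine/goblet/ciliated/club, distal alveolar types AT1/AT2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .catalog import MutationCatalog

logger = logging.getLogger(__name__)

PROXIMAL_TYPES = frozenset({"basal", "neuroendocrine", "goblet", "ciliated", "club"})
DISTAL_TYPES = frozenset({"AT1", "AT2"})

COVARIATE_COLUMNS = ["replication_timing", "gc_fraction", "mean_expression",
                     "log_intronic_fraction", "log_exonic_fraction"]


@dataclass
class BinMatrix:
    """Per-sample binned mutation counts with bin covariates and centroids."""

    sample_id: str
    bins: pd.DataFrame          # chrom, start, end (0-based half-open)
    counts: np.ndarray          # per-bin mutation count
    covariates: pd.DataFrame    # COVARIATE_COLUMNS, row per bin
    centroids: pd.DataFrame     # cell type columns, row per bin (log scale)


@dataclass
class COOFit:
    cell_type: str
    rr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    phi: float
    converged: bool


@dataclass
class COOResult:
    sample_id: str
    fits: Dict[str, COOFit]
    coo_call: Optional[str] = None
    class_call: Optional[str] = None   # {proximal, distal}

    @property
    def rr(self) -> Dict[str, float]:
        return {k: f.rr for k, f in self.fits.items()}


def _validate_bins(bins: pd.DataFrame) -> None:
    for chrom, grp in bins.groupby("chrom"):
        grp = grp.sort_values("start")
        if (grp["end"].values[:-1] > grp["start"].values[1:]).any():
            raise ValueError(f"overlapping bins on {chrom}")


def build_bin_matrix(catalog: MutationCatalog, bins: pd.DataFrame,
                     covariate_table: pd.DataFrame,
                     centroid_table: pd.DataFrame) -> BinMatrix:
    """Count catalog mutations into half-open bins and attach covariates/centroids.

    A mutation at 1-based position p falls in bin [start, end) iff start <= p-1 < end.
    Bins with any missing covariate or centroid value are dropped with a log line.
    """
    _validate_bins(bins)
    bins = bins.reset_index(drop=True)
    counts = np.zeros(len(bins), dtype=int)
    for chrom, grp in bins.groupby("chrom"):
        starts = grp["start"].values
        ends = grp["end"].values
        idx = grp.index.values
        pos0 = np.array([m.pos - 1 for m in catalog if m.chrom == chrom])
        if pos0.size == 0:
            continue
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        for jj in j[ok]:
            counts[idx[jj]] += 1
    cov = covariate_table.reset_index(drop=True)
    cen = centroid_table.reset_index(drop=True)
    keep = ~(cov.isna().any(axis=1) | cen.isna().any(axis=1))
    if (~keep).any():
        logger.info("%s: dropped %d bins with missing covariates", catalog.sample_id,
                    int((~keep).sum()))
    return BinMatrix(sample_id=catalog.sample_id, bins=bins[keep],
                     counts=counts[keep.values], covariates=cov[keep], centroids=cen[keep])


def gamma_poisson_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood (variance mu + phi mu^2); Poisson limit as phi -> 0."""
    if phi <= 0:
        return float(np.sum(stats.poisson.logpmf(y, mu)))
    r = 1.0 / phi
    p = r / (r + mu)
    return float(np.sum(stats.nbinom.logpmf(y, r, p)))


def fit_coo_regression(matrix: BinMatrix, cell_type: str, min_bins: int = 50) -> COOFit:
    """ML Gamma-Poisson fit of counts on one cell type's centroid plus covariates.

    Returns the relative risk exp(beta_centroid) with its Wald 95% CI (log scale)
    and the jointly estimated dispersion phi. A constant centroid or a failed
    optimization yields a flagged non-converged fit.
    """
    y = matrix.counts
    if len(y) < min_bins:
        raise ValueError(f"need >= {min_bins} bins, got {len(y)}")
    if y.sum() == 0:
        raise ValueError("response has zero total count")
    centroid = matrix.centroids[cell_type].values.astype(float)
    bad = COOFit(cell_type=cell_type, rr=math.nan, ci_low=math.nan, ci_high=math.nan,
                 beta=math.nan, se=math.nan, phi=math.nan, converged=False)
    if np.ptp(centroid) == 0:
        logger.warning("%s: centroid constant across bins, slope unidentifiable", cell_type)
        return bad
    X = sm.add_constant(
        pd.DataFrame({"centroid": centroid, **{c: matrix.covariates[c].values
                                               for c in matrix.covariates.columns}})
    ).astype(float)
    try:
        fit = NegativeBinomial(y, X, loglike_method="nb2").fit(
            disp=0, maxiter=200, method="bfgs", gtol=1e-6)
    except Exception as exc:
        logger.warning("%s: NB fit failed: %s", cell_type, exc)
        return bad
    beta = float(fit.params["centroid"])
    se = float(fit.bse["centroid"])
    converged = bool(fit.mle_retvals.get("converged", False)) and np.isfinite(se)
    if not np.isfinite(beta) or not np.isfinite(se):
        return bad
    return COOFit(cell_type=cell_type, rr=math.exp(beta),
                  ci_low=math.exp(beta - 1.96 * se), ci_high=math.exp(beta + 1.96 * se),
                  beta=beta, se=se, phi=float(fit.params.get("alpha", math.nan)),
                  converged=converged)


def assign_coo(matrix: BinMatrix, cell_types: Optional[List[str]] = None,
               depletion: bool = True) -> COOResult:
    """Fit every cell type and call the COO as the argmin-RR (depletion convention).

    Ties are broken by the narrower Wald CI. ``depletion=False`` inverts the
    convention (argmax RR) for sensitivity analyses. Non-converged fits are
    excluded from the call with a warning; fewer than 2 converged fits -> no call.
    """
    cell_types = cell_types or list(matrix.centroids.columns)
    fits = {ct: fit_coo_regression(matrix, ct) for ct in cell_types}
    ok = {ct: f for ct, f in fits.items() if f.converged}
    result = COOResult(sample_id=matrix.sample_id, fits=fits)
    if len(ok) < 2:
        logger.warning("%s: fewer than 2 converged cell-type fits; no COO call",
                       matrix.sample_id)
        return result
    key = (lambda ct: (ok[ct].rr, ok[ct].ci_high - ok[ct].ci_low)) if depletion else \
          (lambda ct: (-ok[ct].rr, ok[ct].ci_high - ok[ct].ci_low))
    result.coo_call = min(ok, key=key)
    result.class_call = ("proximal" if result.coo_call in PROXIMAL_TYPES
                         else "distal" if result.coo_call in DISTAL_TYPES else None)
    return result


def cohort_comparison(results: List[COOResult], subtype_calls: pd.DataFrame) -> dict:
    """Proximal/distal x LAS/HAS 2x2 Fisher test and per-cell-type median RR by subtype.

    ``subtype_calls`` needs columns sample_id and subtype; LAS and no_APOBEC are
    pooled as the low-APOBEC arm.
    """
    sub = subtype_calls.set_index("sample_id")["subtype"]
    rows = []
    for r in results:
        if r.class_call is None or r.sample_id not in sub.index:
            continue
        rows.append({"sample_id": r.sample_id, "class_call": r.class_call,
                     "is_has": sub[r.sample_id] == "HAS",
                     **{f"rr_{ct}": f.rr for ct, f in r.fits.items() if f.converged}})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no callable samples overlap the subtype table")
    table = [[int(((df.is_has) & (df.class_call == "proximal")).sum()),
              int(((df.is_has) & (df.class_call == "distal")).sum())],
             [int(((~df.is_has) & (df.class_call == "proximal")).sum()),
              int(((~df.is_has) & (df.class_call == "distal")).sum())]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    rr_cols = [c for c in df.columns if c.startswith("rr_")]
    median_rr = df.groupby("is_has")[rr_cols].median()
    return {"table": table, "fisher_or": float(odds), "fisher_p": float(p),
            "median_rr_by_subtype": median_rr, "calls": df}


def results_to_frame(results: List[COOResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "coo_call": r.coo_call, "class_call": r.class_call}
        for ct, f in r.fits.items():
            row[f"rr_{ct}"] = f.rr
            row[f"ci_low_{ct}"] = f.ci_low
            row[f"ci_high_{ct}"] = f.ci_high
        rows.append(row)
    return pd.DataFrame(rows)
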