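"""Tumor chronology from clock-like CpG>TpG mutations.

Spontaneous deamination of methylated CpG produces C>T mutations in an NpCpG
context (signature SBS1) at a near-constant rate per year of life, which makes
their count a molecular clock. Clonal clock mutations (present in every tumor
cell, CCF near 1) accumulate over the patient's lifetime; subclonal clock
mutations arise after the most recent common ancestor (MRCA) of the tumor cell
population, during an expansion phase whose mutation rate is accelerated by a
factor A (default 5) relative to normal tissue.

The rate model: diploid-normalized clonal burden m_i = n_clonal_i / (ploidy_i/2)
is Poisson with mean r_i x age_i, with per-sample rates r_i partially pooled
around a cohort log-normal, log r_i ~ Normal(mu, sigma^2). The marginal
likelihood is maximized over (mu, sigma) by Gauss-Hermite quadrature; per-sample
posteriors come from the same quadrature. Latency (years between MRCA and
diagnosis) is the accelerated conversion of the subclonal burden:

    latency_i = [n_subclonal_i / (ploidy_i/2)] / (r_i x A)

and MRCA age = age at diagnosis - latency, floored at 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .catalog import MutationCatalog

logger = logging.getLogger(__name__)


@dataclass
class ClockCounts:
    sample_id: str
    n_clock_clonal: int
    n_clock_subclonal: int
    purity: float
    ploidy: float
    age_dx: float
    nrpcc: Optional[float] = None


@dataclass
class MRCAEstimate:
    sample_id: str
    rate_per_year: float
    rate_lo: float
    rate_hi: float
    acceleration: float
    latency_years: float
    latency_lo: float
    latency_hi: float
    mrca_age: float
    age_dx: float
    floored: bool = False


def count_clock_mutations(catalog: MutationCatalog) -> ClockCounts:
    """Count C>T mutations at NpCpG, split by clonal/subclonal flag.

    Requires annotated contexts and resolved clonality; unknown-clonality clock
    mutations are excluded with a logged count, and a catalog where every clock
    mutation has unknown clonality is refused.
    """
    n_clonal = n_sub = n_unknown = 0
    for m in catalog:
        if not (m.context_ok and m.pyr_ref == "C" and m.pyr_alt == "T"
                and m.context5 and m.context5[3] == "G"):
            continue
        if m.clonal_flag == "clonal":
            n_clonal += 1
        elif m.clonal_flag == "subclonal":
            n_sub += 1
        else:
            n_unknown += 1
    if n_unknown and n_clonal + n_sub == 0:
        raise ValueError(
            f"{catalog.sample_id}: all {n_unknown} clock mutations have unknown "
            "clonality; resolve CCF (resolve_clonality) before timing analysis"
        )
    if n_unknown:
        logger.info("%s: %d clock mutations with unknown clonality excluded",
                    catalog.sample_id, n_unknown)
    meta = catalog.metadata
    return ClockCounts(
        sample_id=catalog.sample_id,
        n_clock_clonal=n_clonal,
        n_clock_subclonal=n_sub,
        purity=float(meta.get("purity", math.nan)),
        ploidy=float(meta.get("ploidy", 2.0)),
        age_dx=float(meta.get("age", math.nan)),
        nrpcc=float(meta["nrpcc"]) if meta.get("nrpcc") is not None else None,
    )


class ClockRateModel:
    """Partially pooled Poisson clock-rate model fit by marginal maximum likelihood.

    Parameters
    ----------
    purity_min, nrpcc_min : quality gates; samples at or below them are excluded.
    n_quad : Gauss-Hermite nodes for the marginal likelihood.
    interval : central posterior mass for per-sample rate intervals (default 0.90).

    Fitted attributes (trailing underscore) follow the scikit-learn convention:
    ``mu_``/``sigma_`` are the log-rate hyperparameters, ``cohort_rate_`` is
    exp(mu) (the cohort median rate, per diploid-normalized mutation per year),
    ``cohort_mean_rate_`` is the log-normal mean, and ``sample_rates_`` holds the
    per-sample posterior mean rate and central interval.
    """

    def __init__(self, purity_min: float = 0.3, nrpcc_min: float = 10.0,
                 min_samples: int = 10, n_quad: int = 40, interval: float = 0.90):
        self.purity_min = purity_min
        self.nrpcc_min = nrpcc_min
        self.min_samples = min_samples
        self.n_quad = n_quad
        self.interval = interval

    def _usable(self, cohort: List[ClockCounts]) -> List[ClockCounts]:
        out = []
        for c in cohort:
            if not np.isfinite(c.age_dx) or c.age_dx <= 0:
                continue
            if not np.isfinite(c.purity) or c.purity <= self.purity_min:
                continue
            if c.nrpcc is not None and c.nrpcc <= self.nrpcc_min:
                continue
            out.append(c)
        return out

    @staticmethod
    def _offsets(cohort) -> np.ndarray:
        return np.array([c.age_dx * c.ploidy / 2.0 for c in cohort])

    def fit(self, cohort: List[ClockCounts]) -> "ClockRateModel":
        usable = self._usable(cohort)
        if len(usable) < self.min_samples:
            raise ValueError(
                f"only {len(usable)} samples pass quality gates "
                f"(purity>{self.purity_min}, NRPCC>{self.nrpcc_min}); "
                f"need >= {self.min_samples}"
            )
        y = np.array([c.n_clock_clonal for c in usable], dtype=float)
        off = self._offsets(usable)
        nodes, weights = np.polynomial.hermite_e.hermegauss(self.n_quad)
        logw = np.log(weights / math.sqrt(2 * math.pi))

        def nll(theta):
            mu, log_sigma = theta
            sigma = math.exp(log_sigma)
            t = mu + sigma * nodes                       # (q,)
            lam = np.exp(t)[None, :] * off[:, None]      # (n, q)
            loglik = y[:, None] * np.log(lam) - lam - special.gammaln(y + 1)[:, None]
            return -float(special.logsumexp(loglik + logw[None, :], axis=1).sum())

        mu0 = math.log(max(np.mean(y / off), 1e-8))
        res = optimize.minimize(nll, x0=[mu0, math.log(0.3)], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        if not res.success:
            logger.warning("clock model optimizer did not report convergence: %s", res.message)
        self.converged_ = bool(res.success)
        self.mu_, self.sigma_ = float(res.x[0]), float(math.exp(res.x[1]))
        self.cohort_rate_ = math.exp(self.mu_)
        self.cohort_mean_rate_ = math.exp(self.mu_ + self.sigma_ ** 2 / 2)
        self.hyper_cov_ = self._hessian_cov(nll, res.x)
        self.hyper_grid_ = self._hyper_grid(nll, res.x)
        self.samples_ = usable
        self.sample_rates_ = self._posteriors(usable, y, off)
        return self

    def _hyper_grid(self, nll, xopt, half_width: float = 3.5, n_grid: int = 7):
        """Likelihood-weighted (mu, sigma) nodes around the optimum.

        The grid spans +-half_width standard errors (from the Laplace covariance)
        in each hyperparameter; node weights use the exact marginal likelihood,
        which keeps the right-skew of the sigma posterior that a Gaussian
        approximation would clip.
        """
        # clamp: a near-degenerate sigma (noiseless cohorts) makes the log-sigma
        # curvature vanish and would send grid nodes to +-inf
        se = np.clip(np.sqrt(np.maximum(np.diag(self.hyper_cov_), 1e-8)), 0.0, 2.0)
        mus = xopt[0] + np.linspace(-half_width, half_width, n_grid) * se[0]
        logsigs = np.clip(
            xopt[1] + np.linspace(-half_width, half_width, n_grid) * se[1], -12.0, 2.0)
        nodes = []
        nlls = []
        for mu in mus:
            for ls in logsigs:
                nodes.append((float(mu), float(math.exp(ls))))
                nlls.append(nll([mu, ls]))
        w = np.exp(np.min(nlls) - np.array(nlls))
        return [(mu, s, float(wi)) for (mu, s), wi in zip(nodes, w / w.sum())]

    @staticmethod
    def _hessian_cov(nll, xopt, h: float = 1e-3) -> np.ndarray:
        """Laplace covariance of (mu, log sigma) from a finite-difference Hessian."""
        x = np.asarray(xopt, dtype=float)
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                e_i = np.eye(2)[i] * h
                e_j = np.eye(2)[j] * h
                H[i, j] = (nll(x + e_i + e_j) - nll(x + e_i - e_j)
                           - nll(x - e_i + e_j) + nll(x - e_i - e_j)) / (4 * h * h)
        try:
            cov = np.linalg.inv(H)
            if not np.all(np.linalg.eigvalsh(cov) > 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            logger.warning("non-positive-definite hyperparameter Hessian; "
                           "intervals ignore hyperparameter uncertainty")
            cov = np.zeros((2, 2))
        return cov

    def _posteriors(self, usable, y, off) -> pd.DataFrame:
        """Per-sample rate posteriors marginalized over hyperparameter uncertainty.

        Per-sample posteriors on a fine log-rate grid are mixed across the
        likelihood-weighted hyperparameter nodes of ``hyper_grid_``.
        """
        hyper = [h for h in self.hyper_grid_ if h[2] > 1e-6]
        wsum = sum(h[2] for h in hyper)
        s_max = max(h[1] for h in hyper)
        t = np.linspace(self.mu_ - 7 * max(s_max, 1e-3), self.mu_ + 7 * max(s_max, 1e-3), 1201)
        rate = np.exp(t)
        lo_q, hi_q = (1 - self.interval) / 2, 1 - (1 - self.interval) / 2
        rows = []
        for c, yi, oi in zip(usable, y, off):
            lam = rate * oi
            loglik = yi * np.log(lam) - lam
            mix = np.zeros_like(t)
            for mu_h, s_h, w_h in hyper:
                logp = loglik + stats.norm.logpdf(t, mu_h, s_h)
                p = np.exp(logp - logp.max())
                mix += (w_h / wsum) * (p / p.sum())
            mix /= mix.sum()
            cdf = np.cumsum(mix)
            rows.append({
                "sample_id": c.sample_id,
                "rate_mean": float(np.sum(mix * rate)),
                "rate_lo": float(np.interp(lo_q, cdf, rate)),
                "rate_hi": float(np.interp(hi_q, cdf, rate)),
            })
        return pd.DataFrame(rows).set_index("sample_id")


def fit_clock_model(cohort: List[ClockCounts], purity_min: float = 0.3,
                    nrpcc_min: float = 10.0, **kwargs) -> ClockRateModel:
    """Convenience wrapper: fit a :class:`ClockRateModel` on the cohort."""
    return ClockRateModel(purity_min=purity_min, nrpcc_min=nrpcc_min, **kwargs).fit(cohort)


def estimate_mrca(clock: ClockCounts, rate: float, acceleration: float = 5.0,
                  rate_lo: Optional[float] = None, rate_hi: Optional[float] = None,
                  age_dx: Optional[float] = None) -> MRCAEstimate:
    """Convert subclonal clock burden into latency and MRCA age.

    latency = diploid-normalized subclonal burden / (rate x A); the MRCA age is
    the age at diagnosis minus latency, floored at 0 with a flag. The rate
    posterior interval propagates inversely into the latency interval.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if acceleration < 1:
        raise ValueError("acceleration factor must be >= 1")
    age = clock.age_dx if age_dx is None else age_dx
    burden = clock.n_clock_subclonal / (clock.ploidy / 2.0)
    latency = burden / (rate * acceleration)
    lat_lo = burden / (rate_hi * acceleration) if rate_hi else latency
    lat_hi = burden / (rate_lo * acceleration) if rate_lo else latency
    mrca = age - latency
    floored = mrca < 0
    return MRCAEstimate(
        sample_id=clock.sample_id, rate_per_year=rate,
        rate_lo=rate_lo if rate_lo is not None else rate,
        rate_hi=rate_hi if rate_hi is not None else rate,
        acceleration=acceleration, latency_years=latency,
        latency_lo=lat_lo, latency_hi=lat_hi,
        mrca_age=max(mrca, 0.0), age_dx=age, floored=bool(floored),
    )


def estimates_to_frame(estimates: List[MRCAEstimate]) -> pd.DataFrame:
    cols = ["sample_id", "rate_per_year", "rate_lo", "rate_hi", "acceleration",
            "latency_years", "latency_lo", "latency_hi", "mrca_age", "age_dx", "floored"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in estimates], columns=cols)
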