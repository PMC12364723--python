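"""Two-sample MR estimators on harmonized summary statistics.

Given per-SNP exposure effects ``gamma_x`` (SE ``se_x``) and outcome effects
``gamma_y`` (SE ``se_y``) on a shared effect allele, the per-SNP Wald ratio
is ``r_j = gamma_y_j / gamma_x_j`` with first-order delta-method SE
``se_y_j / |gamma_x_j|``.  The module provides:

* IVW with multiplicative random effects (the primary estimator): the
  precision-weighted mean of the ratios, with SE inflated by
  ``sqrt(max(1, Q/(J-1)))`` where Q is Cochran's heterogeneity statistic;
* MR-Egger regression (free intercept; the intercept tests directional
  pleiotropy);
* the weighted median (consistent when >= 50% of instrument weight is
  valid), with a seeded parametric-bootstrap SE;
* multivariable IVW for joint direct effects of several exposures;
* odds-ratio / confidence-interval / p-value conversion utilities for
  binary outcomes on the log-odds scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "Z95",
    "MREstimate",
    "EstimatorError",
    "wald_ratios",
    "wald",
    "ivw_mre",
    "cochran_q",
    "egger",
    "weighted_median",
    "mvmr_ivw",
    "p_from_or_ci",
    "p_from_z",
]

#: two-sided 95% normal quantile used for all confidence intervals
Z95 = 1.959964

_P_FLOOR = float(np.finfo(float).tiny)


class EstimatorError(ValueError):
    """Estimator preconditions violated (too few SNPs, rank deficiency...)."""


def p_from_z(z) -> np.ndarray | float:
    """Two-sided normal p-value, floored at the smallest positive float."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, _P_FLOOR) if np.ndim(p) else max(float(p), _P_FLOOR)


@dataclasses.dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty and heterogeneity block.

    ``or_point`` and the CI are the exponentiated (odds-ratio) scale of
    ``beta`` for binary outcomes; for continuous outcomes they are simply
    ``exp(beta)`` and should be ignored.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    exposure: str = ""
    outcome: str = ""
    note: str = ""

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_lo(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def or_hi(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))

    def as_row(self) -> dict:
        return {
            "exposure": self.exposure, "outcome": self.outcome,
            "method": self.method, "n_snp": self.n_snp,
            "beta": self.beta, "se": self.se, "pval": self.pval,
            "or": self.or_point, "ci_lo": self.or_lo, "ci_hi": self.or_hi,
            "q_stat": self.q_stat, "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "intercept_pval": self.intercept_pval,
            "note": self.note,
        }


def _estimate(method: str, beta: float, se: float, n_snp: int, **kw) -> MREstimate:
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      pval=float(p_from_z(beta / se)) if se > 0 else 1.0,
                      n_snp=int(n_snp), **kw)


def wald_ratios(gamma_x, se_x, gamma_y, se_y) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their first-order delta-method SEs."""
    gx = np.asarray(gamma_x, dtype=float)
    gy = np.asarray(gamma_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    if np.any(gx == 0):
        raise EstimatorError("zero exposure effect; enforce the F filter upstream")
    return gy / gx, sy / np.abs(gx)


def wald(gamma_x, se_x, gamma_y, se_y, **kw) -> MREstimate:
    """Single-SNP Wald ratio estimate."""
    r, se_r = wald_ratios([gamma_x], [se_x], [gamma_y], [se_y])
    return _estimate("wald", r[0], se_r[0], 1, **kw)


def cochran_q(ratio, se_ratio) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratio estimates: (Q, df, upper-tail chi2 p)."""
    r = np.asarray(ratio, dtype=float)
    w = 1.0 / np.asarray(se_ratio, dtype=float) ** 2
    if len(r) < 2:
        raise EstimatorError("Cochran's Q needs >= 2 ratios")
    beta = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - beta) ** 2))
    df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw_mre(ratio, se_ratio, **kw) -> MREstimate:
    """IVW with multiplicative random effects.

    ``beta`` is the precision-weighted mean of the ratios; the fixed-effect
    SE ``1/sqrt(sum w)`` is inflated by ``sqrt(phi)`` with dispersion
    ``phi = max(1, Q/(J-1))`` (never deflated below the fixed-effect SE).
    A single ratio degrades to the Wald estimate, flagged in ``note``.
    """
    r = np.asarray(ratio, dtype=float)
    s = np.asarray(se_ratio, dtype=float)
    if len(r) == 0:
        raise EstimatorError("no ratios supplied")
    w = 1.0 / s**2
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    if len(r) == 1:
        return _estimate("ivw_mre", beta, se_fixed, 1,
                         note="single_snp_wald_fallback", **kw)
    q = float(np.sum(w * (r - beta) ** 2))
    df = len(r) - 1
    phi = max(1.0, q / df)
    return _estimate("ivw_mre", beta, se_fixed * np.sqrt(phi), len(r),
                     q_stat=q, q_pval=float(stats.chi2.sf(q, df)), **kw)


def ivw_from_hset(gamma_x, se_x, gamma_y, se_y, **kw) -> MREstimate:
    r, s = wald_ratios(gamma_x, se_x, gamma_y, se_y)
    return ivw_mre(r, s, **kw)


def egger(gamma_x, se_x, gamma_y, se_y, **kw) -> MREstimate:
    """MR-Egger regression with multiplicative random-effects SE inflation.

    Effects are first oriented so every exposure effect is non-negative
    (both signs of a SNP's pair flip together); then outcome effects are
    regressed on exposure effects with a free intercept and weights
    ``1/se_y^2``.  The slope is the causal estimate; the intercept and its
    p-value form the directional-pleiotropy test.  Both SEs are inflated by
    ``sqrt(max(1, RSS/(J-2)))``; inference uses normal quantiles.
    """
    gx = np.asarray(gamma_x, dtype=float)
    gy = np.asarray(gamma_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    J = len(gx)
    if J < 3:
        raise EstimatorError("MR-Egger needs >= 3 SNPs")
    orient = np.where(gx < 0, -1.0, 1.0)
    gx, gy = gx * orient, gy * orient
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(J), gx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * gy)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = gy - X @ coef
    rss = float(np.sum(w * resid**2))
    phi = max(1.0, rss / (J - 2))
    cov = phi * np.linalg.inv(xtwx)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    return _estimate(
        "egger", slope, se_slope, J,
        q_stat=rss, q_pval=float(stats.chi2.sf(rss, J - 2)),
        egger_intercept=float(intercept), intercept_se=float(se_int),
        intercept_pval=float(p_from_z(intercept / se_int)), **kw)


def weighted_median(ratio, se_ratio, n_boot: int = 1000,
                    seed: int | None = None, **kw) -> MREstimate:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Ratios are ordered ascending; with standardized cumulative weights
    ``p_i = (S_i - w_i/2) / S_total`` the estimate is the linear
    interpolation of ratio against p at p = 0.5.  The SE is the standard
    deviation of the estimate over ``n_boot`` resamples in which each ratio
    is redrawn from Normal(r_i, se_ratio_i^2) with weights held fixed.
    """
    r = np.asarray(ratio, dtype=float)
    s = np.asarray(se_ratio, dtype=float)
    if len(r) < 3:
        raise EstimatorError("weighted median needs >= 3 ratios")
    w = 1.0 / s**2
    est = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(r, s, size=(n_boot, len(r)))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", est, se, len(r), **kw)


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r, kind="mergesort")
    r = r[order]
    w = w[order]
    cum = np.cumsum(w)
    p = (cum - w / 2.0) / cum[-1]
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def mvmr_ivw(exposure_betas, gamma_y, se_y, names=None,
             random_effects: bool = False, outcome: str = "", **kw) -> list[MREstimate]:
    """Multivariable IVW: joint direct effects of K exposures.

    Weighted least squares of the outcome effects on the K columns of
    ``exposure_betas`` without intercept, weights ``1/se_y^2``.  Fixed-effect
    SEs by default; ``random_effects`` applies the multiplicative
    ``sqrt(max(1, RSS/(J-K)))`` inflation.  With K = 1 this reduces exactly
    to the fixed-effect part of univariable IVW.
    """
    X = np.asarray(exposure_betas, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    gy = np.asarray(gamma_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    J, K = X.shape
    if J < K + 2:
        raise EstimatorError(f"MVMR needs >= K+2 SNPs (got J={J}, K={K})")
    w = 1.0 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    if np.linalg.matrix_rank(xtwx) < K:
        cols = names or [f"x{k}" for k in range(K)]
        raise EstimatorError(f"rank-deficient exposure design among {cols}")
    coef = np.linalg.solve(xtwx, X.T @ (w * gy))
    cov = np.linalg.inv(xtwx)
    if random_effects:
        rss = float(np.sum(w * (gy - X @ coef) ** 2))
        cov = cov * max(1.0, rss / (J - K))
    ses = np.sqrt(np.diag(cov))
    names = names or [f"x{k}" for k in range(K)]
    return [
        _estimate("mvmr_ivw", coef[k], ses[k], J, exposure=str(names[k]),
                  outcome=outcome, **kw)
        for k in range(K)
    ]


def p_from_or_ci(or_point: float, ci_lo: float, ci_hi: float) -> float:
    """Two-sided Wald p-value recovered from an OR and its 95% CI.

    Inverts the standard reporting convention: ``se = (ln hi - ln lo) /
    (2 * 1.959964)``, ``z = ln(OR)/se``, ``p = 2 (1 - Phi(|z|))``.
    """
    if not (0 < ci_lo < or_point < ci_hi):
        raise ValueError("require 0 < ci_lo < OR < ci_hi")
    se = (np.log(ci_hi) - np.log(ci_lo)) / (2.0 * Z95)
    return float(p_from_z(np.log(or_point) / se))
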