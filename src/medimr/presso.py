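"""MR-PRESSO: residual-sum-of-squares pleiotropy testing on summary data.

Three stages over a harmonized exposure/outcome set:

* **global test** — the observed residual sum of squares
  ``RSS = sum_j w_j (gamma_y_j - beta_(-j) gamma_x_j)^2`` with leave-one-out
  fixed-effect IVW slopes and weights ``w_j = 1/se_y_j^2``, referred to a
  simulated null in which each SNP's effects are redrawn around their
  expected values;
* **outlier test** — each SNP's observed residual contribution against its
  own simulated distribution, Bonferroni-corrected at 0.05/J;
* **distortion test** — the relative change of the IVW estimate after
  removing flagged outliers, referred to random pseudo-outlier sets of the
  same size.

All p-values use the add-one permutation estimator (1 + #exceed)/(n_sim + 1)
and therefore lie in (0, 1]; all simulation is seeded.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .estimators import MREstimate, ivw_from_hset

__all__ = ["PressoResult", "run_presso", "presso_global", "presso_outlier",
           "presso_distortion", "pleiotropy_report"]


@dataclasses.dataclass
class PressoResult:
    rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray
    outlier_ids: list[str]
    snps: list[str]
    distortion_pval: float | None
    estimate_before: MREstimate
    estimate_after: MREstimate | None
    n_sim: int
    seed: int | None
    distortion_applicable: bool = True


def _loo_ivw_beta(gx: np.ndarray, gy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slope for every SNP, vectorised.

    The fixed-effect IVW slope equals zero-intercept WLS of gamma_y on
    gamma_x with weights 1/se_y^2.
    """
    sxy = np.sum(w * gx * gy)
    sxx = np.sum(w * gx * gx)
    return (sxy - w * gx * gy) / (sxx - w * gx * gx)


def _loo_ivw_beta_sims(GX: np.ndarray, GY: np.ndarray, w: np.ndarray) -> np.ndarray:
    sxy = (w * GX * GY).sum(axis=1, keepdims=True)
    sxx = (w * GX * GX).sum(axis=1, keepdims=True)
    return (sxy - w * GX * GY) / (sxx - w * GX * GX)


def _rss_core(gx, sx, gy, sy, n_sim, rng):
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_beta(gx, gy, w)
    rss_j = w * (gy - beta_loo * gx) ** 2

    GX = gx + sx * rng.normal(size=(n_sim, len(gx)))
    GY = beta_loo * gx + sy * rng.normal(size=(n_sim, len(gx)))
    beta_loo_sim = _loo_ivw_beta_sims(GX, GY, w)
    rss_sim_j = w * (GY - beta_loo_sim * GX) ** 2
    return rss_j, rss_sim_j


def run_presso(
    gamma_x, se_x, gamma_y, se_y,
    snps=None,
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Full MR-PRESSO: global, outlier, and distortion tests.

    Requires >= 4 SNPs.  Outliers are SNPs whose add-one residual p-value
    falls below ``outlier_alpha / J`` (Bonferroni); the distortion test is
    marked not applicable when no outlier is flagged or fewer than 3 SNPs
    would remain.
    """
    gx = np.asarray(gamma_x, dtype=float)
    sx = np.asarray(se_x, dtype=float)
    gy = np.asarray(gamma_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    J = len(gx)
    if J < 4:
        raise ValueError("MR-PRESSO needs >= 4 SNPs")
    snps = [str(s) for s in (snps if snps is not None else range(J))]
    rng = np.random.default_rng(seed)

    rss_j, rss_sim_j = _rss_core(gx, sx, gy, sy, n_sim, rng)
    rss_obs = float(np.sum(rss_j))
    rss_sim = rss_sim_j.sum(axis=1)
    global_pval = (1.0 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1.0)

    outlier_pvals = (1.0 + (rss_sim_j >= rss_j).sum(axis=0)) / (n_sim + 1.0)
    flagged = outlier_pvals < outlier_alpha / J
    outlier_ids = [snps[j] for j in np.flatnonzero(flagged)]

    before = ivw_from_hset(gx, sx, gy, sy)
    after = None
    distortion_pval = None
    applicable = False
    keep = ~flagged
    if flagged.any() and keep.sum() >= 3:
        applicable = True
        after = ivw_from_hset(gx[keep], sx[keep], gy[keep], sy[keep])
        distortion_pval = _distortion_pval(
            gx, sx, gy, sy, int(flagged.sum()), before.beta, after.beta,
            n_sim, rng)

    return PressoResult(
        rss_obs=rss_obs, global_pval=float(global_pval),
        outlier_pvals=outlier_pvals, outlier_ids=outlier_ids, snps=snps,
        distortion_pval=distortion_pval, estimate_before=before,
        estimate_after=after, n_sim=n_sim, seed=seed,
        distortion_applicable=applicable)


def _fixed_ivw(gx, gy, w, mask) -> float:
    return float(np.sum((w * gx * gy)[mask]) / np.sum((w * gx * gx)[mask]))


def _distortion_pval(gx, sx, gy, sy, n_out, beta_all, beta_wo, n_sim, rng) -> float:
    """Two-sided add-one p for the distortion statistic
    (beta_all - beta_without)/|beta_without| against random pseudo-outlier
    sets of the same size (fixed-effect IVW inside the resampling loop)."""
    J = len(gx)
    w = 1.0 / sy**2
    d_obs = (beta_all - beta_wo) / abs(beta_wo)
    d_null = np.empty(n_sim)
    for k in range(n_sim):
        drop = rng.choice(J, size=n_out, replace=False)
        mask = np.ones(J, dtype=bool)
        mask[drop] = False
        b_wo = _fixed_ivw(gx, gy, w, mask)
        b_all = _fixed_ivw(gx, gy, w, np.ones(J, dtype=bool))
        d_null[k] = (b_all - b_wo) / abs(b_wo)
    return float((1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1.0))


def presso_global(gamma_x, se_x, gamma_y, se_y, n_sim: int = 1000,
                  seed: int | None = None, **kw) -> PressoResult:
    """Global pleiotropy test (the full result's global block)."""
    return run_presso(gamma_x, se_x, gamma_y, se_y, n_sim=n_sim, seed=seed, **kw)


def presso_outlier(gamma_x, se_x, gamma_y, se_y, n_sim: int = 1000,
                   seed: int | None = None, **kw) -> PressoResult:
    """Per-SNP outlier test (runs the global simulation internally)."""
    return run_presso(gamma_x, se_x, gamma_y, se_y, n_sim=n_sim, seed=seed, **kw)


def presso_distortion(gamma_x, se_x, gamma_y, se_y, outlier_ids, snps,
                      n_sim: int = 1000, seed: int | None = None):
    """Distortion test for a given outlier set.

    Returns ``(distortion_pval, estimate_before, estimate_after)``; when the
    outlier set is empty the result is marked not applicable
    (``(None, before, None)``), not an error.
    """
    gx = np.asarray(gamma_x, dtype=float)
    sx = np.asarray(se_x, dtype=float)
    gy = np.asarray(gamma_y, dtype=float)
    sy = np.asarray(se_y, dtype=float)
    snps = [str(s) for s in snps]
    before = ivw_from_hset(gx, sx, gy, sy)
    outlier_ids = [str(s) for s in outlier_ids]
    if not outlier_ids:
        return None, before, None
    keep = np.array([s not in outlier_ids for s in snps])
    if keep.sum() < 3:
        return None, before, None
    after = ivw_from_hset(gx[keep], sx[keep], gy[keep], sy[keep])
    rng = np.random.default_rng(seed)
    p = _distortion_pval(gx, sx, gy, sy, len(outlier_ids), before.beta,
                         after.beta, n_sim, rng)
    return p, before, after


def pleiotropy_report(entries, alpha: float = 0.05):
    """Combine Egger-intercept, Cochran-Q, and PRESSO-global p-values.

    ``entries`` is an iterable of dicts with keys ``exposure, outcome,
    egger_intercept_pval, q_pval, presso_global_pval``.  Each row gets
    pass/fail flags at ``alpha`` and an ``all_pass`` column: a trait pair
    counts as consistent in the sensitivity analyses only when every test
    passes.
    """
    import pandas as pd

    rows = []
    for e in entries:
        row = dict(e)
        row["egger_pass"] = e["egger_intercept_pval"] >= alpha
        row["q_pass"] = e["q_pval"] >= alpha
        row["presso_pass"] = e["presso_global_pval"] >= alpha
        row["heterogeneity_flag"] = not row["q_pass"]
        row["all_pass"] = row["egger_pass"] and row["q_pass"] and row["presso_pass"]
        rows.append(row)
    return pd.DataFrame(rows)
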