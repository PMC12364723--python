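"""Monte-Carlo calibration studies of the estimators on synthetic data.

These routines quantify, under the generator's study conditions, the
statistical guarantees the pipeline relies on: IVW bias / CI coverage /
type-I error, Egger intercept recovery under directional pleiotropy,
mediation-proportion recovery, MR-PRESSO outlier power and null
calibration, and SMR/HEIDI operating characteristics.  Each returns a
plain dict of summary numbers; everything is seeded through a single
:class:`numpy.random.SeedSequence` so results are reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .estimators import Z95, egger, ivw_from_hset
from .instruments import IVConfig
from .mediation import StepFailure, two_step_mediation
from .presso import run_presso
from .simulate import SimulationConfig, simulate_cis_locus, simulate_two_sample
from .smr import heidi_test, smr_screen, smr_test

__all__ = [
    "ivw_recovery", "ivw_type1_error", "egger_intercept_recovery",
    "mediation_recovery", "presso_outlier_power", "presso_null_ks",
    "smr_null_rejection", "heidi_rejection_rate", "smr_panel_recovery",
]


def _child_seeds(seed: int | None, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _fit_ivw(cfg: SimulationConfig, seed: int):
    study = simulate_two_sample(dataclasses.replace(cfg, seed=seed))
    from .sumstats import harmonize

    ivs = IVConfig().select(study.exposure, study.ld())
    h = harmonize(ivs.records, study.outcome)
    if h.n_snp < 2:
        return None
    return ivw_from_hset(*h.arrays()), study.truth


def ivw_recovery(n_rep: int = 500, seed: int | None = 0,
                 **cfg_overrides) -> dict:
    """Bias and empirical 95% CI coverage of IVW-MRE under the defaults.

    Per replicate a study is simulated, instruments selected by the full IV
    chain, and the IVW estimate compared with the true total effect.
    Reports the mean estimate, Monte-Carlo SE of that mean, the bias in MC
    SE units, and the coverage of the nominal 95% CI in percent.
    """
    cfg = SimulationConfig(n_snp=50, **cfg_overrides)
    betas, covered = [], []
    for s in _child_seeds(seed, n_rep):
        fit = _fit_ivw(cfg, s)
        if fit is None:
            continue
        est, truth = fit
        betas.append(est.beta)
        lo, hi = est.beta - Z95 * est.se, est.beta + Z95 * est.se
        covered.append(lo <= truth.theta_total <= hi)
    betas = np.array(betas)
    mc_se = betas.std(ddof=1) / np.sqrt(len(betas))
    return {
        "n_rep": len(betas), "truth": cfg.theta_total,
        "mean_beta": float(betas.mean()), "mc_se": float(mc_se),
        "bias": float(betas.mean() - cfg.theta_total),
        "bias_in_mc_se": float((betas.mean() - cfg.theta_total) / mc_se),
        "coverage_pct": float(100.0 * np.mean(covered)),
    }


def ivw_type1_error(n_rep: int = 500, seed: int | None = 0,
                    alpha: float = 0.05, **cfg_overrides) -> dict:
    """Rejection rate of IVW at level alpha when the true effect is zero."""
    cfg_overrides.setdefault("theta", 0.0)
    cfg = SimulationConfig(n_snp=50, **cfg_overrides)
    rejections = []
    for s in _child_seeds(seed, n_rep):
        fit = _fit_ivw(cfg, s)
        if fit is not None:
            rejections.append(fit[0].pval < alpha)
    return {"n_rep": len(rejections),
            "rejection_pct": float(100.0 * np.mean(rejections))}


def egger_intercept_recovery(n_rep: int = 200, seed: int | None = 0,
                             mu_alpha: float = 0.05, n_snp: int = 10,
                             **cfg_overrides) -> dict:
    """Mean Egger intercept under directional pleiotropy of size mu_alpha."""
    cfg = SimulationConfig(n_snp=n_snp, pi_pleio=1.0, mu_alpha=mu_alpha,
                           sigma_alpha=0.02, **cfg_overrides)
    intercepts = []
    for s in _child_seeds(seed, n_rep):
        study = simulate_two_sample(dataclasses.replace(cfg, seed=s))
        from .sumstats import harmonize

        h = harmonize(study.exposure, study.outcome)
        est = egger(*h.arrays())
        intercepts.append(est.egger_intercept)
    arr = np.array(intercepts)
    mc_se = arr.std(ddof=1) / np.sqrt(len(arr))
    return {"n_rep": len(arr), "truth": mu_alpha,
            "mean_intercept": float(arr.mean()), "mc_se": float(mc_se),
            "bias_in_mc_se": float((arr.mean() - mu_alpha) / mc_se)}


def mediation_recovery(n_rep: int = 200, seed: int | None = 0,
                       delta: float = 0.5, theta_m: float = 0.3,
                       theta: float = 0.1, **cfg_overrides) -> dict:
    """Recovery of the true proportion mediated by two-step MR.

    The default scenario has truth delta*theta_m/(theta + delta*theta_m)
    = 0.15/0.25 = 60%.
    """
    cfg = SimulationConfig(n_snp=100, delta=delta, theta_m=theta_m,
                           theta=theta, **cfg_overrides)
    props, ses_emp = [], []
    for s in _child_seeds(seed, n_rep):
        study = simulate_two_sample(dataclasses.replace(cfg, seed=s))
        try:
            res = two_step_mediation(study.exposure, study.mediator,
                                     study.outcome, study.ld())
        except StepFailure:
            continue
        props.append(res.proportion_pct)
        ses_emp.append((res.indirect, res.se_indirect))
    arr = np.array(props)
    mc_se = arr.std(ddof=1) / np.sqrt(len(arr))
    indirect = np.array([x[0] for x in ses_emp])
    se_delta = np.array([x[1] for x in ses_emp])
    truth_pct = 100.0 * cfg.proportion_mediated
    return {
        "n_rep": len(arr), "truth_pct": truth_pct,
        "mean_proportion_pct": float(arr.mean()), "mc_se_pct": float(mc_se),
        "bias_in_mc_se": float((arr.mean() - truth_pct) / mc_se),
        "indirect_empirical_sd": float(indirect.std(ddof=1)),
        "indirect_delta_se_mean": float(se_delta.mean()),
    }


def presso_outlier_power(n_rep: int = 100, seed: int | None = 0,
                         n_clean: int = 20, alpha_scale: float = 10.0,
                         n_sim: int = 1000) -> dict:
    """Detection rate of a single implanted pleiotropic outlier.

    One SNP's outcome effect is shifted by ``alpha_scale * se_y``; the SNP
    counts as detected when it is Bonferroni-flagged, and as the top signal
    when it also has the minimum outlier p-value.
    """
    from .sumstats import harmonize

    cfg = SimulationConfig(n_snp=n_clean + 1)
    detected, top_signal = [], []
    for s in _child_seeds(seed, n_rep):
        study = simulate_two_sample(dataclasses.replace(cfg, seed=s))
        h = harmonize(study.exposure, study.outcome)
        gx, sx, gy, sy = h.arrays()
        gy = gy.copy()
        gy[0] += alpha_scale * sy[0]
        res = run_presso(gx, sx, gy, sy, snps=h.df["snp"], n_sim=n_sim, seed=s)
        target = h.df["snp"].iloc[0]
        detected.append(target in res.outlier_ids)
        top_signal.append(res.snps[int(np.argmin(res.outlier_pvals))] == target)
    return {"n_rep": n_rep, "detection_pct": float(100.0 * np.mean(detected)),
            "min_p_is_outlier_pct": float(100.0 * np.mean(top_signal))}


def presso_null_ks(n_rep: int = 200, seed: int | None = 0,
                   n_snp: int = 20, n_sim: int = 1000) -> dict:
    """KS distance of the null global p-value distribution from Uniform(0,1)."""
    from .sumstats import harmonize

    cfg = SimulationConfig(n_snp=n_snp)
    pvals = []
    for s in _child_seeds(seed, n_rep):
        study = simulate_two_sample(dataclasses.replace(cfg, seed=s))
        h = harmonize(study.exposure, study.outcome)
        gx, sx, gy, sy = h.arrays()
        pvals.append(run_presso(gx, sx, gy, sy, n_sim=n_sim, seed=s).global_pval)
    ks = stats.kstest(pvals, "uniform").statistic
    return {"n_rep": n_rep, "ks_statistic": float(ks)}


def smr_null_rejection(n_rep: int = 500, seed: int | None = 0,
                       alpha: float = 0.05, m: int = 20, rho: float = 0.9) -> dict:
    """Rejection rate of the SMR test at the top eQTL SNP under no GWAS signal."""
    rejections = []
    for s in _child_seeds(seed, n_rep):
        locus = simulate_cis_locus(m=m, rho=rho, mode="null", seed=s)
        res = smr_test(locus)
        if res.skipped_reason is None:
            rejections.append(res.p_smr < alpha)
    return {"n_rep": len(rejections),
            "rejection_pct": float(100.0 * np.mean(rejections))}


def heidi_rejection_rate(mode: str, n_rep: int = 500, seed: int | None = 0,
                         threshold: float = 0.01, m: int = 20,
                         rho: float = 0.9, beta_smr: float = 0.3,
                         n_draws: int = 20_000) -> dict:
    """Fraction of loci of a given generating mode with HEIDI p < threshold.

    Under ``pleiotropy`` (a shared causal variant) this is the false-linkage
    rate and should sit near the threshold; under ``linkage`` it is the
    power to detect distinct causal variants.
    """
    rejections = []
    for s in _child_seeds(seed, n_rep):
        locus = simulate_cis_locus(m=m, rho=rho, mode=mode,
                                   beta_smr=beta_smr, seed=s)
        h = heidi_test(locus, seed=s, n_draws=n_draws)
        if h.pval is not None:
            rejections.append(h.pval < threshold)
    return {"n_rep": len(rejections), "mode": mode,
            "rejection_pct": float(100.0 * np.mean(rejections))}


def smr_panel_recovery(n_rep: int = 11, seed: int | None = 0,
                       n_true: int = 10, n_null: int = 10,
                       beta_smr: float = 0.3, n_draws: int = 20_000) -> dict:
    """Gene-screen operating characteristics on a labelled panel.

    Each replicate screens ``n_true`` pleiotropy-mode loci with a real
    expression->outcome effect plus ``n_null`` loci without GWAS signal;
    reports the median number of true and false genes passing.
    """
    trues, falses = [], []
    for s in _child_seeds(seed, n_rep):
        rng_seeds = _child_seeds(s, n_true + n_null)
        loci = [simulate_cis_locus(mode="pleiotropy", beta_smr=beta_smr,
                                   seed=rng_seeds[i], gene_id=f"TRUE{i}")
                for i in range(n_true)]
        loci += [simulate_cis_locus(mode="null", seed=rng_seeds[n_true + i],
                                    gene_id=f"NULL{i}")
                 for i in range(n_null)]
        tab = smr_screen(loci, seed=s, n_draws=n_draws)
        passed = set(tab.loc[tab["pass"], "gene_id"])
        trues.append(len([g for g in passed if g.startswith("TRUE")]))
        falses.append(len([g for g in passed if g.startswith("NULL")]))
    return {"n_rep": n_rep, "median_true_recovered": float(np.median(trues)),
            "median_false_passed": float(np.median(falses)),
            "n_true": n_true, "n_null": n_null}
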