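"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the study conditions of a diet -> plasma-metabolite ->
urolithiasis MR design: a continuous exposure GWAS at biobank scale
(default n = 400,000), a binary outcome GWAS with 10,556 cases and 400,681
controls, an optional continuous mediator trait, per-SNP horizontal
pleiotropy drawn from a mixture, and LD-correlated cis loci for SMR/HEIDI.

For SNP j with minor-allele frequency ``maf_j ~ Uniform(maf_range)``:

* instrument effect      ``gamma_j ~ N(0, sigma_gamma^2)``
* pleiotropy             ``alpha_j ~ N(mu_alpha, sigma_alpha^2)`` with
  probability ``pi_pleio``, else 0; a directional component
  (``mu_alpha != 0``) acts on the exposure-increasing allele so that its
  direction is invariant to the arbitrary allele coding
* mediator effect        ``gamma_m_j = delta * gamma_j + N(0, sigma_m^2)``
  with ``sigma_m = sigma_gamma / 2`` by default
* outcome effect         ``Gamma_j = theta * gamma_j + theta_m * gamma_m_j
  + sign(gamma_j) * alpha_j``

Observed effects add independent sampling noise with
``se_x = 1/sqrt(2 n maf (1-maf))`` for continuous traits and
``se_y = sqrt((1/(2 maf (1-maf))) * (1/n_case + 1/n_control))`` for the
binary outcome (the standard log-odds variance approximation); p-values are
two-sided Wald.  The bundled truth record satisfies
``theta_total = theta + delta * theta_m`` and
``proportion_mediated = delta * theta_m / theta_total`` exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sumstats import COLUMNS, write_sumstats
from .instruments import LDMatrix

__all__ = [
    "SimulationConfig",
    "Truth",
    "SimulatedStudy",
    "CisLocus",
    "simulate_two_sample",
    "simulate_panel",
    "simulate_cis_locus",
    "write_study",
    "write_locus",
    "read_locus",
]

# non-palindromic allele pairs assigned cyclically to simulated SNPs
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated two-sample MR study.

    Sample sizes default to the source study design: a 400,000-participant
    continuous exposure GWAS and a binary outcome GWAS of 10,556 cases and
    400,681 controls.  ``theta`` is the direct exposure->outcome log-odds
    effect per SD of exposure; ``delta`` and ``theta_m`` parametrise the
    mediator pathway (both 0 by default, i.e. no mediation unless asked
    for); ``pi_pleio`` is the fraction of SNPs with horizontal pleiotropy.
    """

    n_snp: int = 100
    n_exposure: int = 400_000
    n_case: int = 10_556
    n_control: int = 400_681
    n_mediator: int | None = None  # defaults to n_exposure
    theta: float = 0.1
    delta: float = 0.0
    theta_m: float = 0.0
    pi_pleio: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.05
    maf_range: tuple[float, float] = (0.1, 0.5)
    sigma_gamma: float = 0.15
    sigma_gamma_m: float | None = None  # defaults to sigma_gamma / 2
    correlated_pleiotropy: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_snp, self.n_exposure, self.n_case, self.n_control) <= 0:
            raise ValueError("sample sizes and n_snp must be positive")
        if not 0.0 <= self.pi_pleio <= 1.0:
            raise ValueError("pi_pleio must lie in [0, 1]")
        if self.sigma_gamma <= 0:
            raise ValueError("sigma_gamma must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")

    @property
    def theta_total(self) -> float:
        return self.theta + self.delta * self.theta_m

    @property
    def proportion_mediated(self) -> float:
        if self.theta_total == 0:
            return float("nan")
        return self.delta * self.theta_m / self.theta_total


@dataclasses.dataclass
class Truth:
    """Ground truth of a simulated study; the identities
    ``theta_total = theta + delta*theta_m`` and
    ``proportion_mediated = delta*theta_m/theta_total`` hold exactly."""

    theta: float
    delta: float
    theta_m: float
    theta_total: float
    proportion_mediated: float
    gamma: np.ndarray
    gamma_m: np.ndarray
    alpha: np.ndarray

    def scalars(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("theta", "delta", "theta_m", "theta_total", "proportion_mediated")}


@dataclasses.dataclass
class SimulatedStudy:
    exposure: pd.DataFrame
    mediator: pd.DataFrame
    outcome: pd.DataFrame
    truth: Truth
    config: SimulationConfig

    def ld(self) -> LDMatrix:
        """Simulated panel SNPs are generated independent (identity LD)."""
        return LDMatrix.identity(self.exposure["snp"])


def _variant_scaffold(n_snp: int, rng: np.random.Generator,
                      maf_range: tuple[float, float]) -> pd.DataFrame:
    maf = rng.uniform(maf_range[0], maf_range[1], n_snp)
    # spread SNPs 25 Mb apart across autosomes so they are physically
    # unlinked at the default 10,000 kb clumping window
    chrom = (np.arange(n_snp) % 22 + 1).astype(str)
    pos = 10_000_000 + (np.arange(n_snp) // 22) * 25_000_000
    pairs = [_ALLELE_PAIRS[j % len(_ALLELE_PAIRS)] for j in range(n_snp)]
    return pd.DataFrame({
        "snp": [f"rs{j + 1}" for j in range(n_snp)],
        "chrom": chrom, "pos": pos.astype(np.int64),
        "ea": [p[0] for p in pairs], "oa": [p[1] for p in pairs],
        "eaf": maf,
    })


def _observe(scaffold: pd.DataFrame, true_beta: np.ndarray, se: np.ndarray,
             n: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    beta = true_beta + rng.normal(0.0, se)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)),
                      np.finfo(float).tiny)
    df = scaffold.copy()
    df["beta"] = beta
    df["se"] = se
    df["pval"] = pval
    df["n"] = np.asarray(n, dtype=float)
    return df[COLUMNS]


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Pleiotropy mixture; optionally correlated with gamma to break InSIDE."""
    has = rng.uniform(size=len(gamma)) < cfg.pi_pleio
    z = rng.normal(size=len(gamma))
    if cfg.correlated_pleiotropy:
        r = 0.5
        z = r * gamma / cfg.sigma_gamma + np.sqrt(1 - r**2) * z
    return has * (cfg.mu_alpha + cfg.sigma_alpha * z)


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Generate exposure, mediator, and outcome summary statistics.

    Reproducible: identical configs (including seed) give identical studies;
    different seeds redraw the noise and per-SNP truth but keep the same
    causal parameters.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scaffold = _variant_scaffold(cfg.n_snp, rng, cfg.maf_range)
    maf = scaffold["eaf"].to_numpy()

    sigma_m = cfg.sigma_gamma_m if cfg.sigma_gamma_m is not None else cfg.sigma_gamma / 2.0
    gamma = rng.normal(0.0, cfg.sigma_gamma, cfg.n_snp)
    gamma_m = cfg.delta * gamma + rng.normal(0.0, sigma_m, cfg.n_snp)
    alpha = _draw_alpha(cfg, gamma, rng)
    big_gamma = (cfg.theta * gamma + cfg.theta_m * gamma_m
                 + np.sign(gamma) * alpha)

    n_med = cfg.n_mediator if cfg.n_mediator is not None else cfg.n_exposure
    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(het * n_med)
    se_y = np.sqrt((1.0 / het) * (1.0 / cfg.n_case + 1.0 / cfg.n_control))

    n_y = np.full(cfg.n_snp, cfg.n_case + cfg.n_control)
    exposure = _observe(scaffold, gamma, se_x, np.full(cfg.n_snp, cfg.n_exposure), rng)
    mediator = _observe(scaffold, gamma_m, se_m, np.full(cfg.n_snp, n_med), rng)
    outcome = _observe(scaffold, big_gamma, se_y, n_y, rng)

    truth = Truth(theta=cfg.theta, delta=cfg.delta, theta_m=cfg.theta_m,
                  theta_total=cfg.theta_total,
                  proportion_mediated=cfg.proportion_mediated,
                  gamma=gamma, gamma_m=gamma_m, alpha=alpha)
    return SimulatedStudy(exposure=exposure, mediator=mediator,
                          outcome=outcome, truth=truth, config=cfg)


def simulate_panel(
    config: SimulationConfig,
    n_exposures: int = 3,
    n_mediators: int = 5,
) -> dict:
    """Multi-trait study over one shared variant panel (for pipeline runs).

    Every trait's summary file covers the full panel, as in a real biobank
    GWAS.  Exposure i has its own instrument effects; mediator k is driven
    by exposure ``k % n_exposures`` with strength ``config.delta``; the
    outcome sums direct effects ``config.theta`` from each exposure,
    ``config.theta_m`` from each mediator, and the pleiotropy mixture.

    Returns a dict with keys ``exposures`` (list of frames), ``mediators``
    (list of frames), ``outcome``, ``truth`` (scalar summary), ``ld``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    scaffold = _variant_scaffold(cfg.n_snp, rng, cfg.maf_range)
    maf = scaffold["eaf"].to_numpy()
    het = 2.0 * maf * (1.0 - maf)
    sigma_m = cfg.sigma_gamma_m if cfg.sigma_gamma_m is not None else cfg.sigma_gamma / 2.0
    n_med = cfg.n_mediator if cfg.n_mediator is not None else cfg.n_exposure

    gammas = [rng.normal(0.0, cfg.sigma_gamma, cfg.n_snp) for _ in range(n_exposures)]
    gamma_ms = [cfg.delta * gammas[k % n_exposures]
                + rng.normal(0.0, sigma_m, cfg.n_snp) for k in range(n_mediators)]
    alpha = _draw_alpha(cfg, gammas[0], rng)
    big_gamma = (cfg.theta * np.sum(gammas, axis=0)
                 + cfg.theta_m * np.sum(gamma_ms, axis=0)
                 + np.sign(gammas[0]) * alpha)

    se_x = 1.0 / np.sqrt(het * cfg.n_exposure)
    se_m = 1.0 / np.sqrt(het * n_med)
    se_y = np.sqrt((1.0 / het) * (1.0 / cfg.n_case + 1.0 / cfg.n_control))
    nx = np.full(cfg.n_snp, cfg.n_exposure)
    nm = np.full(cfg.n_snp, n_med)
    ny = np.full(cfg.n_snp, cfg.n_case + cfg.n_control)

    exposures = [_observe(scaffold, g, se_x, nx, rng) for g in gammas]
    mediators = [_observe(scaffold, gm, se_m, nm, rng) for gm in gamma_ms]
    outcome = _observe(scaffold, big_gamma, se_y, ny, rng)
    return {
        "exposures": exposures, "mediators": mediators, "outcome": outcome,
        "truth": {"theta": cfg.theta, "delta": cfg.delta, "theta_m": cfg.theta_m},
        "ld": LDMatrix.identity(scaffold["snp"]),
    }


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a study as tab-delimited files plus a YAML truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("exposure", study.exposure), ("mediator", study.mediator),
                     ("outcome", study.outcome)):
        p = outdir / f"{name}.tsv"
        write_sumstats(df, p)
        paths[name] = p
    truth_path = outdir / "truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(study.truth.scalars(), fh, sort_keys=True)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# cis loci for SMR / HEIDI
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CisLocus:
    """An eQTL/GWAS cis locus: marginal effects of m SNPs plus their LD.

    ``mode`` records the generating mechanism: ``pleiotropy`` (one shared
    causal variant, so all true per-SNP ratios equal ``beta_smr_true``),
    ``linkage`` (distinct eQTL and GWAS causal variants in partial LD, so
    ratios are heterogeneous), or ``null`` (no GWAS signal).
    """

    gene_id: str
    snps: list[str]
    ld: np.ndarray
    b_eqtl: np.ndarray
    se_eqtl: np.ndarray
    b_gwas: np.ndarray
    se_gwas: np.ndarray
    mode: str = "pleiotropy"
    beta_smr_true: float = 0.0

    @property
    def m(self) -> int:
        return len(self.snps)

    @property
    def z_eqtl(self) -> np.ndarray:
        return self.b_eqtl / self.se_eqtl

    @property
    def z_gwas(self) -> np.ndarray:
        return self.b_gwas / self.se_gwas


def _ar1(m: int, rho: float) -> np.ndarray:
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_cis_locus(
    m: int = 20,
    rho: float = 0.9,
    mode: str = "pleiotropy",
    beta_smr: float = 0.1,
    n_eqtl: int = 31_684,
    n_gwas: int = 411_237,
    seed: int | None = 0,
    eqtl_effect: float = 0.15,
    linkage_sep: int = 4,
    gene_id: str = "GENE",
) -> CisLocus:
    """Simulate one cis locus with AR(1) LD (parameter ``rho``).

    Marginal true effects propagate from the causal variant(s) through LD
    (``b_marginal = R[:, c] * b_causal`` under standardized genotypes).  In
    pleiotropy mode a single mid-locus causal variant drives both signals,
    so ``b_gwas(true) = beta_smr * b_eqtl(true)`` at every SNP; in linkage
    mode the GWAS causal variant sits ``linkage_sep`` SNPs away (pairwise
    LD r = rho^linkage_sep), making per-SNP ratios heterogeneous.  Observed
    effects add sampling noise with covariance ``se^2 * R`` (the LD-induced
    correlation of marginal-effect estimates) and ``se = 1/sqrt(n)`` per
    standardized trait.
    """
    if m < 3:
        raise ValueError("a cis locus needs m >= 3 SNPs")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    if mode not in ("pleiotropy", "linkage", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    R = _ar1(m, rho)
    c_e = m // 2
    b_eqtl_true = R[:, c_e] * eqtl_effect
    if mode == "pleiotropy":
        b_gwas_true = beta_smr * b_eqtl_true
    elif mode == "linkage":
        c_g = min(m - 1, c_e + linkage_sep)
        b_gwas_true = R[:, c_g] * (beta_smr * eqtl_effect)
    else:
        b_gwas_true = np.zeros(m)

    se_e = np.full(m, 1.0 / np.sqrt(n_eqtl))
    se_g = np.full(m, 1.0 / np.sqrt(n_gwas))
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    b_eqtl = b_eqtl_true + se_e * (L @ rng.normal(size=m))
    b_gwas = b_gwas_true + se_g * (L @ rng.normal(size=m))
    return CisLocus(
        gene_id=gene_id, snps=[f"{gene_id}_snp{i + 1}" for i in range(m)],
        ld=R, b_eqtl=b_eqtl, se_eqtl=se_e, b_gwas=b_gwas, se_gwas=se_g,
        mode=mode, beta_smr_true=float(beta_smr if mode != "null" else 0.0))


def write_locus(locus: CisLocus, outdir: str | Path) -> tuple[Path, Path]:
    """Write a locus as ``<gene>.eqtl.tsv`` plus ``<gene>.ld.txt``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tsv = outdir / f"{locus.gene_id}.eqtl.tsv"
    pd.DataFrame({
        "snp": locus.snps, "gene_id": locus.gene_id,
        "b_eqtl": locus.b_eqtl, "se_eqtl": locus.se_eqtl,
        "b_gwas": locus.b_gwas, "se_gwas": locus.se_gwas,
    }).to_csv(tsv, sep="\t", index=False)
    ldp = outdir / f"{locus.gene_id}.ld.txt"
    with open(ldp, "w") as fh:
        fh.write(" ".join(locus.snps) + "\n")
        np.savetxt(fh, locus.ld, fmt="%.10g")
    return tsv, ldp


def read_locus(tsv: str | Path, ld_path: str | Path) -> CisLocus:
    df = pd.read_csv(tsv, sep="\t")
    with open(ld_path) as fh:
        snps = fh.readline().split()
        R = np.atleast_2d(np.loadtxt(fh))
    df = df.set_index("snp").loc[snps].reset_index()
    return CisLocus(
        gene_id=str(df["gene_id"].iloc[0]), snps=snps, ld=R,
        b_eqtl=df["b_eqtl"].to_numpy(), se_eqtl=df["se_eqtl"].to_numpy(),
        b_gwas=df["b_gwas"].to_numpy(), se_gwas=df["se_gwas"].to_numpy(),
        mode="unknown")
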