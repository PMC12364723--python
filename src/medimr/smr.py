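"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR combines a cis-eQTL effect ``b_eqtl`` (z-score ``z_e``) and a GWAS
effect ``b_gwas`` (z-score ``z_g``) at the top cis-eQTL SNP into a test of
gene-expression -> outcome effect:

    beta_smr = b_gwas / b_eqtl
    T_smr    = z_g^2 z_e^2 / (z_g^2 + z_e^2)   ~  chi^2_1 under the null

with the delta-method SE ``|beta_smr| sqrt(se_g^2/b_g^2 + se_e^2/b_e^2)``.
A significant SMR signal can arise from a single shared causal variant
(pleiotropy/causality) or from two distinct variants in LD (linkage).  The
HEIDI test separates the two: under a shared variant every SNP in the cis
region estimates the same ratio, so the deviations
``d_i = b_smr(i) - b_smr(top)`` are jointly zero.  HEIDI forms the
statistic ``sum_i z_d(i)^2`` with the d-vector covariance obtained by the
delta method with LD correlations, and estimates its p-value by seeded
Monte Carlo from the implied weighted-chi-square null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95
from .simulate import CisLocus

__all__ = ["SMRResult", "HeidiResult", "smr_test", "heidi_test", "smr_screen"]

#: published HEIDI SNP-selection defaults (imported tool convention)
HEIDI_EQTL_P_MAX = 1.6e-3
HEIDI_R2_RANGE = (0.05, 0.9)
HEIDI_MAX_SNPS = 20


@dataclasses.dataclass
class SMRResult:
    gene_id: str
    top_snp: str | None
    beta_smr: float = float("nan")
    se_smr: float = float("nan")
    t_smr: float = float("nan")
    p_smr: float = 1.0
    heidi_pval: float | None = None
    n_heidi_snps: int | None = None
    skipped_reason: str | None = None

    @property
    def or_point(self) -> float:
        return float(np.exp(self.beta_smr))

    @property
    def or_lo(self) -> float:
        return float(np.exp(self.beta_smr - Z95 * self.se_smr))

    @property
    def or_hi(self) -> float:
        return float(np.exp(self.beta_smr + Z95 * self.se_smr))


@dataclasses.dataclass
class HeidiResult:
    pval: float | None
    n_snps: int
    stat: float | None = None
    reason: str | None = None


def smr_test(locus: CisLocus, strength_gate: float = 10.0) -> SMRResult:
    """SMR test at the locus's top cis-eQTL SNP.

    The top SNP is the one maximising |z_eqtl|; it must satisfy the
    instrument-strength gate ``z_eqtl^2 >= strength_gate`` (paralleling the
    F >= 10 rule for conventional instruments), otherwise the gene is
    skipped with a reason.
    """
    z_e = locus.z_eqtl
    top = int(np.argmax(np.abs(z_e)))
    if z_e[top] ** 2 < strength_gate:
        return SMRResult(gene_id=locus.gene_id, top_snp=None,
                         skipped_reason="weak_top_eqtl")
    b_e, se_e = locus.b_eqtl[top], locus.se_eqtl[top]
    b_g, se_g = locus.b_gwas[top], locus.se_gwas[top]
    z_g = b_g / se_g
    beta = b_g / b_e
    se = abs(beta) * np.sqrt(se_g**2 / b_g**2 + se_e**2 / b_e**2) if b_g != 0 \
        else se_g / abs(b_e)
    t = (z_g**2 * z_e[top]**2) / (z_g**2 + z_e[top]**2) if z_g != 0 else 0.0
    p = float(stats.chi2.sf(t, 1)) if t > 0 else 1.0
    return SMRResult(gene_id=locus.gene_id, top_snp=locus.snps[top],
                     beta_smr=float(beta), se_smr=float(se),
                     t_smr=float(t), p_smr=max(p, np.finfo(float).tiny))


def _heidi_selection(locus: CisLocus, top: int) -> np.ndarray:
    """Indices of non-top SNPs entering HEIDI under the tool's defaults:
    eQTL p < 1.6e-3, LD r^2 with the top SNP in [0.05, 0.9], capped at the
    20 largest |z_eqtl|."""
    z_e = locus.z_eqtl
    p_e = 2.0 * stats.norm.sf(np.abs(z_e))
    r2 = locus.ld[top] ** 2
    cand = np.flatnonzero(
        (np.arange(locus.m) != top)
        & (p_e < HEIDI_EQTL_P_MAX)
        & (r2 >= HEIDI_R2_RANGE[0]) & (r2 <= HEIDI_R2_RANGE[1]))
    if len(cand) > HEIDI_MAX_SNPS:
        cand = cand[np.argsort(-np.abs(z_e[cand]), kind="mergesort")[:HEIDI_MAX_SNPS]]
        cand = np.sort(cand)
    return cand


def heidi_test(locus: CisLocus, seed: int | None = None,
               n_draws: int = 50_000) -> HeidiResult:
    """HEIDI heterogeneity test for a cis locus.

    The statistic is ``sum_i z_d(i)^2`` over the selected non-top SNPs,
    where ``d_i = b_smr(i) - b_smr(top)`` and the joint covariance of the
    d-vector comes from the delta method with the locus LD correlations
    (eQTL and GWAS sampling errors independent between studies).  The
    p-value is the seeded add-one Monte-Carlo tail of the implied
    ``sum_k lambda_k chi^2_1`` null with lambda the eigenvalues of the
    correlation matrix of the z_d vector.  Requires >= 3 selected SNPs; a
    covariance that is not positive semi-definite after numerical jitter
    marks the gene's HEIDI unavailable rather than silently passing.
    """
    z_e = locus.z_eqtl
    top = int(np.argmax(np.abs(z_e)))
    sel = _heidi_selection(locus, top)
    if len(sel) < 3:
        return HeidiResult(pval=None, n_snps=len(sel), reason="too_few_snps")

    idx = np.concatenate([sel, [top]])
    b_e = locus.b_eqtl[idx]
    se_e = locus.se_eqtl[idx]
    b_g = locus.b_gwas[idx]
    se_g = locus.se_gwas[idx]
    R = locus.ld[np.ix_(idx, idx)]
    k = len(sel)  # non-top count; top sits at position k

    d = b_g[:k] / b_e[:k] - b_g[k] / b_e[k]

    # delta-method gradients of d wrt (b_gwas, b_eqtl) over the subset
    Gg = np.zeros((k, k + 1))
    Ge = np.zeros((k, k + 1))
    Gg[np.arange(k), np.arange(k)] = 1.0 / b_e[:k]
    Gg[:, k] = -1.0 / b_e[k]
    Ge[np.arange(k), np.arange(k)] = -b_g[:k] / b_e[:k] ** 2
    Ge[:, k] = b_g[k] / b_e[k] ** 2
    Vg = R * np.outer(se_g, se_g)
    Ve = R * np.outer(se_e, se_e)
    cov = Gg @ Vg @ Gg.T + Ge @ Ve @ Ge.T

    sd = np.sqrt(np.diag(cov))
    z_d = d / sd
    stat = float(np.sum(z_d**2))
    corr = cov / np.outer(sd, sd)
    lam = np.linalg.eigvalsh(corr)
    if lam.min() < -1e-6:
        return HeidiResult(pval=None, n_snps=k, stat=stat, reason="cov_not_psd")
    lam = np.clip(lam, 0.0, None)

    rng = np.random.default_rng(seed)
    chi = rng.chisquare(1.0, size=(n_draws, len(lam)))
    t_null = chi @ lam
    pval = float((1.0 + np.sum(t_null >= stat)) / (n_draws + 1.0))
    return HeidiResult(pval=pval, n_snps=k, stat=stat)


def smr_screen(
    loci,
    p_smr_threshold: float = 0.05,
    heidi_threshold: float = 0.01,
    seed: int | None = None,
    n_draws: int = 50_000,
) -> pd.DataFrame:
    """Gene prioritisation over a set of cis loci.

    Runs the SMR test per locus and, for genes with an SMR signal, the
    HEIDI test; a gene passes when ``p_smr < p_smr_threshold`` and
    ``heidi_pval >= heidi_threshold`` (a heterogeneous locus is interpreted
    as linkage, not a shared causal variant).  Genes whose HEIDI is
    unavailable never pass silently.  The result is ranked by p_smr and
    carries a ``pass`` column; the passing count is the screen's headline
    number.
    """
    loci = list(loci)
    children = np.random.SeedSequence(seed).spawn(len(loci))
    rows = []
    for locus, child in zip(loci, children):
        res = smr_test(locus)
        heidi_p = None
        n_heidi = None
        reason = res.skipped_reason
        if res.skipped_reason is None:
            h = heidi_test(locus, seed=int(child.generate_state(1)[0] % 2**31),
                          n_draws=n_draws)
            heidi_p = h.pval
            n_heidi = h.n_snps
            reason = h.reason
        passed = (res.skipped_reason is None and heidi_p is not None
                  and res.p_smr < p_smr_threshold and heidi_p >= heidi_threshold)
        rows.append({
            "gene_id": locus.gene_id, "top_snp": res.top_snp,
            "beta_smr": res.beta_smr, "se_smr": res.se_smr,
            "or": res.or_point, "ci_lo": res.or_lo, "ci_hi": res.or_hi,
            "p_smr": res.p_smr, "heidi_pval": heidi_p,
            "n_heidi_snps": n_heidi, "pass": bool(passed),
            "reason": reason,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("p_smr", kind="mergesort").reset_index(drop=True)
    return out
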