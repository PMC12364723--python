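# Methods

This note documents the statistical models implemented in `medimr`, the
assumptions they rest on, the synthetic-data generator that the test suite
and the acceptance script run against, and the numerical and design
choices that were genuinely open.

## Data model and harmonization

A summary-statistics set is a table of per-SNP associations (effect/other
allele, effect-allele frequency, beta, SE, two-sided p, sample size) with
1-based positions; betas are log-odds for binary traits and SD units for
continuous traits. Gene annotation is consumed as 0-based half-open BED;
all coordinate conversion happens at the I/O boundary so that each format
keeps its native dialect.

Harmonization aligns every trait to the exposure's effect allele. Swapped
allele pairs flip the beta sign and replace eaf by 1−eaf; complement-strand
representations (A/G vs T/C) are reconciled and flagged before a pair is
declared irreconcilable. Palindromic SNPs (A/T, C/G) are removed
unconditionally — no allele-frequency rescue is attempted, because strand
cannot be resolved from alleles alone and a frequency heuristic would trade
a known small loss of instruments for an unbounded misalignment risk. If a
file carries beta and p but no SE, the SE is imputed as |beta|/Φ⁻¹(1−p/2)
and the row flagged for audit.

Nearest-gene mapping returns an overlapping gene at distance 0, otherwise
the gene minimising the distance to its nearest edge; exact ties break by
smaller start coordinate, then gene id, so output is deterministic.
Distance is signed: negative upstream of the gene start, positive
downstream of the end.

## Instrument selection

Instruments pass three filters in order: association p strictly below
5×10⁻⁶ (5×10⁻⁸ available as a stringent sensitivity setting — both are
configuration, neither is hard-coded into any analysis), greedy LD
clumping, and an F ≥ 10 weak-instrument filter. Clumping repeatedly takes
the lowest-p unclumped SNP as index and removes same-chromosome SNPs
within ±10,000 kb whose r² with it is ≥ 0.001; p ties break by position
then SNP id, which makes the result independent of input order (verified
against an independently coded exhaustive reference). A missing LD value
for an in-window pair is treated as r² = 1 — conservative removal — and
logged. The F statistic is the squared Wald z, (β/se)²; under a
standardized trait this equals the regression F, and the
allele-frequency-based form R²(n−2)/(1−R²) with R² = 2·maf(1−maf)·β² is
available behind a flag for inputs where the equivalence matters.

## Estimators

**IVW with multiplicative random effects** is the primary estimator: the
precision-weighted mean of per-SNP Wald ratios with first-order SEs
se_y/|γ_x| (the dominant convention, consistent with the strong instruments
the F filter enforces; a second-order option exists). The dispersion
φ = max(1, Q/(J−1)) never deflates the SE below its fixed-effect value.
IVW equals zero-intercept WLS of Γ on γ with weights 1/se_y², which the
test suite exploits as an independent oracle.

**MR-Egger** first orients effects so all γ_x ≥ 0 (a per-SNP joint sign
flip, to which slope and intercept are invariant), then fits WLS with a
free intercept; the intercept tests directional pleiotropy. Both SEs are
inflated by √max(1, RSS/(J−2)). Inference uses normal rather than t
quantiles for consistency across the estimator suite; with the instrument
counts this pipeline targets (tens of SNPs) the difference is small, and
the choice is documented here as a deviation knob rather than hidden.

**Weighted median**: ratios ordered ascending, standardized cumulative
weights p_i = (S_i − w_i/2)/S_total, linear interpolation at p = 0.5. The
SE is a seeded parametric bootstrap (default 1000 resamples, each ratio
redrawn from N(r_i, se_i²) with weights fixed); the literature names the
estimator but no single SE convention, so the bootstrap is an explicit
artifact choice.

**Multivariable IVW** regresses outcome effects on K exposure-beta columns
without intercept, weights 1/se_y². Fixed-effect SEs are the default (the
multivariable analyses this mirrors do not state random-effects inflation);
the multiplicative inflation is behind a flag. K = 1 reduces exactly to
fixed-effect univariable IVW.

All p-values are two-sided normal, floored at the smallest positive
float — never reported as 0. OR and 95% CI come from exp(β ∓ 1.959964·se),
and the inverse conversion (OR + CI → p) inverts the same convention.

## MR-PRESSO

The global statistic is RSS = Σ w_j (Γ_j − β₍₋ⱼ₎γ_j)² with leave-one-out
fixed-effect IVW slopes and w_j = 1/se_y². Its null distribution is
simulated (default 1000 draws, seeded): each draw redraws γ* ~ N(γ̂, se_x²)
and Γ*_j ~ N(β₍₋ⱼ₎γ̂_j, se_y²) and recomputes the statistic including the
leave-one-out slopes. Per-SNP outlier p-values compare each SNP's observed
residual contribution with its simulated distribution; the outlier set is
Bonferroni-controlled at 0.05/J, matching the published convention. The
distortion test compares (β_all − β_without)/|β_without| against random
pseudo-outlier sets of the same size. Every p-value uses the add-one
estimator (1 + #exceed)/(n_sim + 1) and so lies in (0, 1]. A trait pair
counts as "consistent in the sensitivity analyses" only when Egger
intercept, Cochran's Q, and the PRESSO global test all pass at 0.05; this
any-fail exclusion policy is configurable because the source analyses name
the rule but not its exact parameters.

## Two-step mediation

beta_total is univariable IVW of exposure on outcome; beta_xm univariable
IVW of exposure on mediator (exposure instruments); beta_my is the
mediator→outcome effect using the mediator's own instruments. By default
beta_my comes from multivariable IVW adjusting for the exposure. This is a
deliberate design decision: whenever mediator instruments also perturb the
exposure pathway — which is guaranteed under this package's generator,
where the mediator inherits part of its genetic architecture from the
exposure — the univariable estimate is confounded by the direct path
(bias θ·cov(γ, γ_m)/var(γ_m)), and only the exposure-adjusted estimate
identifies θ_m. The univariable variant remains available via
`adjust_exposure=False` for data where mediator instruments are known to be
mediator-specific.

indirect = β_xm·β_my with delta-method SE √(β_xm²se_my² + β_my²se_xm²);
proportion mediated = indirect/β_total, reported in percent and unclipped.
The direction screen keeps a combination only when sign(indirect) =
sign(β_total); an exactly zero indirect effect passes with proportion 0
(avoiding spurious exclusion of exact nulls), and a zero total effect
fails with an annotation. Reported CIs for the indirect effect derive from
the delta SE — the source analyses print point proportions only, so the CI
convention is this package's own. Reverse MR reruns IVW with the trait
roles swapped (instruments selected for the original outcome) and passes
its screen when the reverse p ≥ 0.05.

## SMR and HEIDI

At the top cis-eQTL SNP (largest |z_e|, gated at z_e² ≥ 10 in parallel
with the F ≥ 10 rule), β_smr = b_gwas/b_eqtl, and
T_smr = z_g²z_e²/(z_g²+z_e²) is referred to χ²₁. HEIDI tests whether the
non-top SNPs estimate the same ratio: d_i = b_smr(i) − b_smr(top), with the
joint covariance of d from the delta method using the locus LD correlation
(eQTL and GWAS errors independent across studies), statistic Σ z_d².
Rather than a closed-form approximation, the null tail P(Σλ_k χ²₁ ≥ T) is
estimated by seeded Monte Carlo over the eigenvalues of the z_d correlation
matrix (default 50,000 draws in the library, 20,000 in the batched
calibration studies; add-one corrected) — simpler to verify by construction
and exact in the limit of draws. SNP selection follows the published tool
defaults (eQTL p < 1.6×10⁻³, r² with the top SNP in [0.05, 0.9], capped at
the 20 largest |z_e|); these are imported conventions, configurable. A
locus whose covariance is not PSD after jitter, or with fewer than 3
selected SNPs, reports HEIDI as unavailable and can never pass silently.
The gene screen passes genes with p_smr < 0.05 and HEIDI p ≥ 0.01 (both
thresholds configurable, since the source analyses do not print theirs).

## The synthetic-data generator

The generator emulates the study conditions end-to-end: a continuous
exposure GWAS of n = 400,000, a binary outcome GWAS of 10,556 cases and
400,681 controls, an optional mediator trait, and cis loci for SMR/HEIDI.
Per SNP: maf ~ U(0.1, 0.5); instrument effect γ ~ N(0, σ_γ²) with
σ_γ = 0.15; mediator effect γ_m = δγ + N(0, (σ_γ/2)²); outcome effect
Γ = θγ + θ_m γ_m + sign(γ)·α with pleiotropy α present with probability
π and drawn N(μ_α, σ_α²). Observed effects add independent noise with
se = 1/√(2n·maf(1−maf)) for continuous traits and the case/control
log-odds approximation √((1/(2maf(1−maf)))(1/n_case + 1/n_control)) for
the outcome. Defaults: θ = 0.1, no mediation (δ = θ_m = 0) and no
pleiotropy (π = 0) unless a scenario asks for them.

Choices worth recording:

* **σ_γ = 0.15** keeps simulated instruments clearly detectable at the
  5×10⁻⁶ threshold and, through the σ_γ/2 mediator-specific component,
  keeps mediator instruments strong — which is the generator's stated
  purpose. It is an effect scale for desk-size panels of ~100 SNPs, not an
  estimate of real per-variant food-liking effects (which are an order of
  magnitude smaller and spread over thousands of variants).
* **Directional pleiotropy acts on the exposure-increasing allele**
  (Γ gains sign(γ)·α). Allele coding is arbitrary in summary data, and
  Egger orients SNPs by sign(γ̂); a directional shift defined relative to
  raw allele coding would cancel to zero under that orientation, making
  "directional" meaningless. With μ_α = 0 the convention coincides with
  sign-free pleiotropy. An optional flag correlates α with γ to break the
  InSIDE assumption for stress tests.
* **The mediator GWAS sample size defaults to the exposure's** (400,000),
  overridable via `n_mediator`. Measurement noise in the mediator betas
  attenuates the exposure-adjusted β_my like any error-in-regressor; at
  biobank scale the attenuation is negligible, which keeps the
  mediation-recovery benchmark a test of the estimator rather than of a
  noise correction.
* **Simulated panel SNPs are physically unlinked** (25 Mb spacing,
  identity LD), so clumping is exercised by dedicated tests with explicit
  LD matrices rather than by the study generator.
* **All allele pairs are non-palindromic** by construction; palindromic
  handling is exercised by targeted harmonization tests.
* **Cis loci use AR(1) LD** (single parameter ρ, PSD by construction).
  Marginal effects propagate from the causal variant(s) as R[:,c]·b, and
  sampling noise is drawn with covariance se²R. Pleiotropy mode has one
  shared causal variant (all true ratios equal), linkage mode two causal
  variants `linkage_sep` SNPs apart (LD r = ρ^sep), null mode no GWAS
  signal. eQTL n defaults to 31,684 and the GWAS n to 411,237.

What the generator does **not** model: realistic human LD maps, sample
overlap between the two GWAS, individual-level genotypes, winner's-curse
effects of discovery in the same sample, multi-allelic sites, and
population stratification. Passing calibration on this generator therefore
shows the estimators are implemented correctly and behave as theory says
under their assumptions — not that real diet-GWAS inferences are free of
those additional complications.

## Calibration studies and problem sizes

`medimr.calibration` packages the Monte-Carlo studies that the acceptance
suite and `scripts/acceptance.py` run. Problem sizes are chosen so every
check completes on a single CPU in about a minute total: IVW bias/coverage
and type-I error at 500 replicates of 50-SNP studies; Egger intercept
recovery at 200 replicates of 10 SNPs with μ_α = 0.05; mediation recovery
at 200 replicates of 100-SNP studies (truth 60% mediated); MR-PRESSO
outlier power at 100 replicates of 21 SNPs (one implanted outlier of
10·se_y) and null calibration at 200 replicates; SMR/HEIDI at 500
replicates per mode (m = 20, ρ = 0.9) and an 11-replicate labelled panel
of 10 true + 10 null genes. All replicate seeds derive from one
`SeedSequence`.

## Known limitations

* Correlated-instrument IVW, mode-based estimators, and Steiger filtering
  are out of scope; clumping to near-independence is assumed sufficient.
* MR-PRESSO's null is the simulation scheme described above, not the
  original tool's analytic approximations; p-value resolution is bounded
  by 1/(n_sim+1).
* HEIDI's delta-method covariance treats the observed eQTL betas as the
  linearisation point; with very weak non-top eQTL signals the
  approximation degrades (mitigated by the eQTL-p selection rule).
* The pipeline screens at the nominal 0.05 by design (to surface as many
  candidate mediation signals as possible) and emits Benjamini-Hochberg
  adjusted columns alongside for transparency; the adjusted columns are
  informational, not the screen.
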