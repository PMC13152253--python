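# Methods

## Problem setting

Two-sample Mendelian randomisation (MR) estimates the causal effect of an
exposure on an outcome from two independent GWASs: per-SNP exposure
associations (β̂ˣⱼ, σˣⱼ) and outcome associations (β̂ʸⱼ, σʸⱼ) for a set of
instruments — approximately independent, genome-wide-significant SNPs for
the exposure. This package implements that workflow for maternal exposures
(BMI, blood counts) on pregnancy outcomes, where an extra complication
arises: the maternal and fetal genomes are correlated, so maternal-effect
GWASs must be partitioned before they can proxy the intrauterine
environment.

## Instrument preparation

* **Selection**: p < 5×10⁻⁸ (strict), configurable.
* **Clumping**: greedy by ascending p-value; a candidate is removed when an
  already-kept variant on the same chromosome lies within the window
  (default 10,000 kb, |Δpos| ≤ window) and has r² above the threshold
  (default 0.001) with it. LD is supplied as a sparse long-format table; a
  pair absent from the table within the window is treated as r² = 0, the
  natural reading of sparse tables that omit pairs below their reporting
  threshold.
* **Harmonization**: variants are intersected on id; outcome records whose
  alleles are swapped relative to the exposure (directly or after
  reverse-strand complement) have their betas sign-flipped and frequencies
  mirrored. Palindromic SNPs (A/T, G/C) carry no strand information in
  their labels, so they are resolved by allele frequency and dropped when
  the exposure frequency is missing or inside the ambiguity band
  (default [0.42, 0.58] — a conservative choice; no published rule is being
  matched here). Variants with incompatible alleles, or with β̂ˣ exactly 0
  (undefined Wald ratio), are dropped and counted. Instrument strength is
  reported as the mean F statistic, mean of (β̂ˣⱼ/σˣⱼ)².

## Estimators

All estimators consume the harmonized per-SNP quartet
(β̂ˣ, σˣ, β̂ʸ, σʸ) and are implemented as scikit-learn-style classes.

* **IVW, multiplicative random effects**: slope of the zero-intercept
  weighted regression of β̂ʸ on β̂ˣ with weights 1/σʸ². Fixed-effects SE
  1/√(Σwⱼ(β̂ˣⱼ)²), inflated by max(1, √(Q/(n−1))) where Q is Cochran's Q
  about the pooled slope. The floor at 1 means the random-effects SE never
  undercuts the fixed-effects SE. One instrument reduces exactly to the
  Wald ratio.
* **MR-Egger**: the same regression with a free intercept. Instruments are
  first recoded so every β̂ˣ is positive — Egger is not invariant to allele
  coding and a canonical orientation makes fits reproducible. Residual
  variance is floored at 1 (the same multiplicative convention); slope and
  intercept inference uses a t distribution with n−2 df. The intercept
  estimates the mean directional pleiotropic effect (InSIDE assumption for
  slope consistency).
* **Weighted median**: Wald ratios ordered ascending; with inverse-variance
  ratio weights wⱼ, standardised mid-cumulative weights
  sⱼ = (Σ_{k≤j}w_k − wⱼ/2)/Σw; the estimate linearly interpolates the
  ratios at s = 0.5. Consistent when <50% of weight is on invalid
  instruments.
* **Simple/weighted mode**: argmax of a normal-kernel density of the
  ratios, weights equal or inverse-variance. Bandwidth is a modified
  Silverman rule, 0.9·min(sd, MAD)·n^(−1/5), times a user factor (default
  1); when one spread measure degenerates to 0 (duplicated ratios) the
  other is used. The density is evaluated on a 2,048-point grid extended
  one bandwidth beyond the ratio range, so the estimate always lies within
  that extended range.
* **Bootstrap SEs** (median and modes): parametric — β̂ˣ and β̂ʸ are
  perturbed by their SEs, the estimator re-applied, and the SD over
  resamples taken (default 1,000 draws, seed 20240401, both recorded in
  output). p-values for IVW/median/mode are two-sided normal; Egger uses
  the t distribution. 95% CIs use ±1.96·SE throughout.

The Wald-ratio SE uses the first-order NOME approximation σʸ/|β̂ˣ|,
ignoring exposure-side uncertainty. This is the standard two-sample choice
and accurate for strong instruments; its residual consequence — an O(1/F̄)
attenuation of pooled estimates — is discussed under validation.

## Maternal-effect partitioning

For a trait measured on offspring, the unadjusted maternal-genotype GWAS
effect absorbs half the fetal effect and vice versa (allele-sharing ½), so
the weighted linear model inverts the mixture:

    β̂_MaternalAdj = (4/3)·β̂_Maternal − (2/3)·β̂_Fetal

This is exact: applied to (βm + βf/2, βf + βm/2) it returns βm identically,
and the transform is linear. The source formula is a point-estimate
transform only; for the SE this package propagates the quadratic form

    SE²_adj = (4/3)²SE²m + (2/3)²SE²f − 2(4/3)(2/3)·ρ·SEm·SEf

with ρ the between-GWAS sampling correlation from overlapping samples.
ρ defaults to 0 (independent samples) because the overlap between published
maternal and fetal GWASs is rarely known; users who know it can supply it.
Inputs already partitioned upstream (e.g. Z-score-scale maternal-specific
statistics) bypass the module via the run configuration — it never
re-partitions partitioned data. The symmetric fetal adjustment is provided
for completeness but is not used in the pipeline.

Derived blood counts follow count = percentage × total WBC / 100.

## Two-step mediation

Each step (exposure→outcome total, exposure→mediator a, mediator→outcome b)
is the IVW multiplicative-random-effects estimate; the robust panel is
reported alongside but does not feed the arithmetic. The mediator→outcome
step uses the mediator's own instruments. Gating: all three step p-values
must be < α (default 0.05) before the mediation quantities are computed; a
failed gate names the failing step(s). Indirect = a·b with delta-method SE
√(b²SE²ₐ + a²SE²ᵦ + SE²ₐSE²ᵦ) — for independent normal estimates this is
the exact SD of the product. Direct = total − indirect with SE
√(SE²ₜₒₜₐₗ + SE²ᵢₙ𝒹) (difference of two estimates); direct + indirect =
total holds identically. p-values are two-tailed normal. The proportion
mediated (indirect/total) is off by default and only reported when the
signs agree, since it is unstable near a null total effect.

A note on printed-precision inputs: recomputing the eosinophil worked
example's indirect-effect p-value from rounded published step estimates
gives ≈0.10 rather than the published 0.11; the package reports unrounded
values and does not attempt to reconcile rounding artefacts.

## Synthetic data

Summary statistics are simulated directly — the pipeline consumes only
summary data, so simulating individual-level genotypes would add cost
without adding truth. Structure:

* MAFs uniform on the configured range (default 0.05–0.45); per-SNP
  sampling SE 1/√(2p(1−p)N); binary outcomes on the log-odds scale with SE
  inflated by 1/√(v(1−v)) for case fraction v (default 0.117, matching a
  15,200/115,007 case–control mix). No liability-threshold conversion is
  applied; binary traits are treated as log-odds throughout.
* Two instrument blocks: exposure instruments γⱼ and mediator instruments
  δⱼ, each centred normal scaled so the block explains a stated
  heritability (defaults 0.04 for ~500 exposure SNPs at N ≈ 700,000 and
  0.15 for ~500 mediator SNPs at N ≈ 408,000, giving mean per-SNP F in the
  tens-to-hundreds range typical of published instruments). The mediator
  block exists because mediator→outcome estimation needs the mediator's own
  instruments; without it the step-b ratio identifies θ/a + b, not b.
* Causal structure: SNP-mediator effect a·γⱼ + δⱼ; SNP-outcome effect
  (θ + a·b)·γⱼ + b·δⱼ + αⱼ.
* Pleiotropy αⱼ: none; balanced (centred normal); or directional, drawn
  with the configured mean in the *trait-increasing-allele frame* — i.e.
  multiplied by the sign of the SNP's instrument effect. Applied in the raw
  (arbitrary) allele coding, a non-zero mean would cancel against the
  symmetric instrument-effect signs and be indistinguishable from balanced
  pleiotropy; orientation is what makes "directional" directional.
* Allele bookkeeping: exactly-counted configured fractions of palindromic
  variants and of swapped-coding records in the mediator/outcome sets, so
  harmonization is exercised (and its idempotence checkable) end to end.
* Duo studies: true maternal/fetal effects drawn independently; unadjusted
  estimates are the ½-allele-sharing mixtures plus bivariate-normal noise
  with the configured overlap correlation. A noise-free switch supports
  exact-recovery identities.
* The LD fixture is block-diagonal (blocks of adjacent SNPs 10 kb apart at
  r² = 0.95 by default, blocks 50,000 kb apart), so greedy clumping has a
  known correct answer: one survivor per block.

What the generator does **not** emulate: realistic LD from reference
panels, winner's-curse inflation of selected instruments, sample overlap
between exposure and outcome GWASs, INDELs, or multi-allelic sites. Passing
recovery tests therefore demonstrates correctness of the estimators and
plumbing under the stated generating model, not robustness to those
real-data phenomena.

## Validation design and problem sizes

* Estimator arithmetic is checked against independent oracles: weighted
  least squares (statsmodels) for IVW/Egger/Q to 1e-10, the interpolation
  formula by hand for the weighted median, and a fine-grid density argmax
  for the modes.
* Calibration: 500 replicates of a null study (θ = 0, no pleiotropy,
  100 instruments at paper-scale sample sizes) check IVW type-I error
  (nominal 0.05; band 0.03–0.07) and 95% CI coverage (band 0.93–0.97). The
  multiplicative-random-effects floor makes the test mildly conservative,
  which the bands accommodate.
* Mediation recovery: 300 replicates of a mediated study
  (θ_direct = 0.2, a = 0.3, b = 0.5) with 100 instruments per block at
  biobank-scale N = 2×10⁶ and block heritability 0.2 — a deliberately
  strong-instrument regime (per-SNP F ≈ 4000) chosen so the O(1/F̄)
  NOME/weak-instrument attenuation of the IVW product estimator sits below
  Monte-Carlo resolution. The mean recovered indirect effect must lie
  within 3 standard errors of a·b = 0.15, and the mean delta-method SE
  within 10% of the empirical SD. At paper-realistic instrument strength
  (F̄ ≈ 50–150) the same product estimator is attenuated by roughly 1–3% —
  a known property of ratio-based two-sample MR, not an implementation
  defect. Replicates use the truth-designated instrument lists rather than
  re-selection, consistent with the generator's stated scope (no
  winner's-curse modelling).
* Duo partitioning: noise-free recovery is exact to machine precision; with
  noise and a non-zero overlap correlation, the empirical SD of the
  adjusted effects over 1,000 SNPs matches the propagated SE within 10%.

## Defaults and tunables

| Parameter | Default | Meaning |
|---|---|---|
| instrument p threshold | 5×10⁻⁸ | genome-wide significance |
| clump r², window | 0.001, 10,000 kb | index-SNP independence |
| palindrome band | [0.42, 0.58] | ambiguous-strand drop zone |
| gate α | 0.05 | per-step mediation gate (deliberately liberal) |
| Bonferroni m | 7 | exposures corrected in outcome analyses (0.05/7 ≈ 0.007) |
| bootstrap | 1,000 draws, seed 20240401 | median/mode SEs |
| mode bandwidth factor | 1.0 | scales the modified Silverman rule |

## Known limitations

* No MR-PRESSO/contamination-mixture/RAPS, no multivariable MR, no Steiger
  filtering, no proxy-SNP lookup, no liftover, no INDEL support.
* The Egger fit requires a canonical orientation; with instruments near the
  significance boundary, observed-sign orientation can itself perturb the
  intercept — fit Egger on genome-wide-significant instruments.
* The Bonferroni correction is applied to the pregnancy-outcome analyses
  (m = 7 exposures) and not to exposure→mediator screens, mirroring common
  practice; both are configurable.
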