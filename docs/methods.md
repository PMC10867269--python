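# Methods

## Model and estimators

All analysis operates on GWAS summary statistics: per-SNP effect estimates
(beta), standard errors, effect/other alleles, effect-allele frequencies,
p-values and sample sizes, one table per trait. Continuous traits are
SD-scaled; binary outcomes are on the log-odds scale. The causal model is
linear and homogeneous: instruments affect the exposure, the exposure
affects mediators and outcome, mediators affect the outcome, and (except
where simulated otherwise) instruments have no other path to the outcome.

**Wald ratios.** For SNP j, the per-SNP causal estimate is
`ratio_j = betaY_j / betaX_j` with first-order SE `seY_j / |betaX_j|`.
Exposure-side uncertainty is neglected (the standard two-sample, strong-
instrument convention; with the instrument strengths used here the
neglected term is below 0.5% of the ratio variance).

**IVW.** Inverse-variance-weighted mean of Wald ratios with weights
`w_j = 1/ratio_se_j²`; algebraically identical to weighted least squares of
outcome betas on exposure betas through the origin with weights `1/seY²`.
Fixed-effect SE is `(Σw)^(-1/2)`; the default multiplicative random-effects
SE inflates it by `max(1, sqrt(Q/(n-1)))`, so heterogeneity can widen but
never narrow the interval. Both are exposed.

**MR-Egger.** Weighted regression with a free intercept after orienting
every SNP so its exposure beta is positive (Egger is not invariant to
allele coding; this is the fixed convention). The intercept estimates
average directional pleiotropy; the slope is the causal estimate under
InSIDE. SEs use the same multiplicative overdispersion scaling
(`max(1, sqrt(RSS_w/(n-2)))`). All p-values in the package use the normal
approximation and all 95% CIs are `estimate ± 1.96·SE` — a deliberate
uniformity across estimators (Egger with few SNPs is therefore slightly
anti-conservative relative to a t reference; with the instrument counts
this package targets, n ≥ 150, the difference is negligible).

**Weighted median.** Ratios are ordered and the estimate is the first
ratio at which the running sum of normalized inverse-variance weights
reaches 0.5; an exact 0.5 crossing averages the two bracketing ratios (so
two equally weighted SNPs give their midpoint, like a plain median, and a
SNP carrying more than half the weight is the estimate outright). This
"lower weighted median with tie-averaging" is deterministic and converges
to the usual interpolated weighted-median estimator as instruments grow.
The SE is a seeded parametric bootstrap (default 1000 resamples of both
exposure and outcome betas from their sampling distributions).

**Heterogeneity and outliers.** Cochran's Q of the ratios about the IVW
estimate, with a chi-square(n−1) p-value (plain Q, not the second-order-
weights modification). Outlier handling is a *report*, never a removal:
standardized residuals about the IVW fit are flagged beyond the two-sided
Bonferroni threshold at level 0.05.

**MVMR.** Weighted no-intercept multiple regression of outcome betas on
the matrix of exposure/mediator betas (weights `1/seY²`), coefficient
covariance scaled by `max(1, Q/(n-k))`. A trait whose instrument effects
are identically zero is excluded from the fit (its direct effect is 0 by
construction) so the remaining coefficients reduce to the nested model;
rank deficiency among non-null traits raises a collinearity error naming
the most correlated pair. Conditional instrument strength is reported as
the mean squared standardized residual of each trait's betas after
weighted projection on the others — a diagnostic only, never a filter.
The default mediation analysis fits one MVMR per mediator (exposure +
that mediator); a joint model over all mediators is available by passing
the full trait list.

**Mediation.** Indirect effect `β₁·β₂` with delta SE
`sqrt(β₂²se₁² + β₁²se₂²)`; proportion `indirect/total` with delta SE
`|p|·sqrt(se_ind²/ind² + se_tot²/tot²)` (or `se_ind/|total|` at an exactly
null indirect effect). Covariances are set to zero: β₁, β₂ and the total
derive from non-overlapping samples except that β₂ and the total share the
outcome GWAS through *disjoint* instrument sets, which makes their noise
approximately independent; this simplification is a documented limitation.
All arithmetic is on the log-odds scale; odds ratios appear only at
presentation. Proportions outside [0,1] (inconsistent mediation) are
reported with a warning, never truncated. The summed proportion across
mediators is attached with a caveat flag — mediators may be correlated, so
the sum is not a joint decomposition.

Delta-method accuracy: the proportion is a ratio, and the first-order SE
under-covers the Monte-Carlo SD as the total's relative SE grows — the
discrepancy grows roughly quadratically in `se_total/total` (≈2% at
|total|/se = 10, ≈8% at |total|/se = 5). Interpret `se_prop` cautiously
when the total effect is weakly determined; the published education→sepsis
total has |total|/se ≈ 2.4, where only the CI of the components, not the
delta CI of the ratio, should be taken literally.

## Harmonization conventions

The first set is the reference orientation. Swapped alleles flip the beta
and complement the frequency; strand flips are resolved by complementing
before declaring a mismatch. Palindromic SNPs (A/T, C/G) cannot be
strand-resolved from alleles: they are dropped as ambiguous when the
reference eaf lies within 0.08 of 0.5 (or is missing), otherwise oriented
so every trait's eaf falls on the same side of 0.5 as the reference's.
Frequency orientation assumes broadly comparable allele frequencies
across the contributing GWAS (same-ancestry panels); under that assumption
harmonization is idempotent. Every input SNP lands exactly once in the
panel or in the dropped list with a reason from a fixed enumeration.

## Instrument selection

Greedy clumping: sort candidates (p below threshold) by ascending p (ties
lexicographic by SNP id for determinism); accept the best, discard
unaccepted SNPs on the same chromosome within the window (inclusive,
basepair distance) with r² at or above the threshold; repeat. Cross-
chromosome pairs are never clumped. Defaults: p < 5×10⁻⁸, r² < 0.001,
10,000 kb. F-statistic filtering is not applied (no threshold is part of
the modelled procedure); conditional-strength diagnostics are available
from the MVMR fit.

## Synthetic-data generator

The generator emulates the *statistical shape* of consortium GWAS inputs,
not genotypes:

- Exposure instrument effects γ_j are drawn normal and rescaled so the
  allele-frequency-weighted sum `Σ 2p(1-p)γ²` equals `instrument_h2`
  exactly (default 0.1 over 371 SNPs). MAF ~ U(0.05, 0.5).
- Each mediator has its own instruments δ_m (default 150 per mediator,
  h² = 0.1) — without them β₂ is unidentified in MVMR, since exposure
  instruments hit mediator and outcome proportionally.
- True effects follow the diagram: exposure SNPs carry `β₁_k·γ_j` on
  mediator k and `θ_total·γ_j` on the outcome; mediator-k SNPs carry
  `β₂_k·δ_m` on the outcome (plus `reverse_k·δ_m` on the exposure when a
  reverse path is injected). The implied direct effect is
  `θ_total − Σ β₁_kβ₂_k`.
- Observed betas add Gaussian noise with `se = 1/sqrt(2p(1-p)·n)`; the
  binary outcome uses the effective size `n·cf·(1−cf)` (log-odds scale
  directly — no liability-threshold layer, since all downstream arithmetic
  is log-odds). P-values come from the normal approximation. The total
  IVW SE therefore has the closed form `1/sqrt(n_eff·h²)`, handy for
  sizing studies.
- Pleiotropy (optional) is added to outcome (and mediator) effects of
  exposure instruments *per exposure-increasing allele*: balanced mode is
  N(0, s²), directional mode N(s, s²) multiplied by sign(γ_j). Defining it
  relative to the exposure-increasing allele is what makes "directional"
  survive MR-Egger's orientation step; with allele-random pleiotropy the
  intercept would be 0 by symmetry regardless of s.
- LD blocks are simulated at the summary level only: satellite SNPs tag a
  lead with marginal effects `r·(lead effects)` and positions within a few
  kb, with pairwise r² entries emitted for the clumping reference.
- Seeding: one master seed spawns a child stream for the architecture and
  one per trait, so adding a trait never perturbs other traits' draws;
  fixtures are byte-reproducible.

What the generator does **not** emulate — and what passing recovery tests
therefore cannot certify about real data: sample overlap between GWAS,
population stratification, winner's-curse on externally selected
instruments, allele-frequency differences between cohorts, fine-scale LD
beyond block-uniform r², and non-collapsibility of odds ratios (effects
are generated directly on the log-odds scale).

## Default study conditions

The default `SimScenario` mirrors the education→sepsis analysis the
package was built around: 371 instruments, exposure n = 1,131,881; outcome
n = 486,484 with case fraction 10,154/462,918; total effect ln(0.83)
log-odds per SD (4.2 years) of schooling. `sepsis_mediation_scenario()`
adds the four mediators at their published effects (β₁ = −0.177, −0.334,
0.096, 0.104; β₂ = ln 1.51, ln 1.23, ln 0.93, ln 0.89; mediator GWAS
sample sizes 681,275 / 249,752 / 114,999 / 115,078), with the total
calibrated so the BMI pathway mediates 38.8% (OR 0.829 — consistent with
the published 0.83; the printed point estimates round-trip to 39.1%, so
one convention had to be fixed and the BMI-pathway calibration was chosen).
Mediator-side instrument counts and h² (150, 0.1) are stylized choices of
realistic magnitude; the published sources do not constrain them.

Known property of replicate averaging at these conditions: the mean of
per-replicate proportion estimates carries a small upward Jensen bias
(≈ +(se_tot/total)² ≈ +2–3% relative at the sepsis outcome's precision)
because the estimator is a ratio; replicate means of the *components*
(β₁, β₂, total) are unbiased. Similarly, the BMI-vs-smoking proportion
*ordering* is unstable replicate-to-replicate (their indirect effects
differ by ~0.004 against a per-replicate SD of ~0.012 pinned by the
outcome GWAS size), matching the published overlapping interval estimates.

## Numerical and design choices

- Tie-breaks and orderings are deterministic everywhere (mergesort,
  lexicographic SNP ids); result tables are written with fixed float
  formatting so identical config + seed gives byte-identical files.
- P-values are clipped to [5e-324, 1] to respect the (0, 1] contract.
- Reverse-causation screens flag |z| > 1.96 (flag only, no exclusion);
  Steiger filtering and MR-PRESSO-style outlier *removal* are deliberately
  out of scope.
- No multiple-testing correction is applied across mediators (noted in the
  run-report footer).
- Missing eaf is tolerated except for palindromic SNPs, which are then
  always dropped.
- The proportion-mediated CI is a normal-approximation interval; no
  bootstrap CI is provided for the proportion itself.

## Problem sizes used in the shipped studies

Recovery studies in the tests and the acceptance script use 500 replicates
at full published sample sizes but desk-scale SNP counts (371 exposure +
150 per-mediator instruments), which keeps a full four-mediator two-step
study around two minutes on one CPU while leaving every estimator's
sampling behaviour at realistic signal-to-noise.
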