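# Methods

## The design being emulated

A two-arm, 1:1, double-blind online trial of advice-taking in prognosis.
Each enrolled clinician reviews five advanced-cancer patient vignettes in
random order; for each vignette they (1) estimate the probability of
two-week survival (0–100%), (2) receive advice — a probability estimate of
50%, 75% or 90% (two vignettes at 90%, two at 75%, one at 50%) — and
(3) give a final estimate. The arms differ only in the advice's framing:
one arm is told it comes from a validated prognostic algorithm, the other
that it comes from a clinician of a different profession (doctors are told
a nurse; nurses and other professionals are told a doctor). Allocation
follows a blocked randomisation list with block sizes drawn uniformly with
replacement from {4, 6, 8}; the list is generated in whole blocks until it
covers the enrolment target, so every complete block is balanced and the
arm imbalance never exceeds half the largest block (4). The block-size
sequencing rule is this package's choice — standard practice for
mixed-block randomisation; the design being emulated specifies only the
set of sizes. Randomisation is unstratified.

## Weight of advice

`WOA = (f − i) / |a − i|`, capped at 1, undefined when `a = i` (the record
is excluded; exclusion is per record, not per participant). The absolute
value sits on the denominator only, so when the initial estimate lies
*above* the advice, movement toward the advice produces a negative raw
score. How negatives were handled in the original analyses is not
documented; consistent with the statistic's stated 0–1 range, the default
policy clamps them to 0, the raw value is always retained, and `keep` /
`drop` policies are provided for sensitivity work. Binning uses
left-closed, right-open intervals at 0.2/0.4/0.6/0.8 with the last bin
closed at 1. The per-protocol filter removes all records of any
participant who did not complete all five vignettes; it is idempotent.
Descriptive tables report n, mean, SD and a normal-approximation 95% CI of
the mean (explicitly descriptive; inferential CIs come from the models).

## Synthetic-data generator

No raw data from the emulated trial are deposited, so the pipeline is
validated by parameter recovery on synthetic cohorts. The generative model
is chosen so that the true advice weight is exactly the estimand of the
WOA statistic:

* **Covariates** are drawn independently per participant from marginal
  proportions defaulting to the published cohort's totals (49% doctors,
  41% nurses, 10% other; 65% with 15+ years' experience; etc.). The joint
  distribution is not published, so no dependence is modelled.
* **Initial estimates**: `i ~ round(TruncNormal(anchor_v, initial_sd²; 0, 100))`
  per vignette, with `initial_sd = 10` percent. With probability
  `tie_probability = 0.03` the draw is replaced by the advice value
  exactly, exercising the tie-exclusion rule.
* **Final estimates**: `f = round(clip(i + w·(a − i) + ε, 0, 100))`,
  `ε ~ N(0, response_sd²)` with `response_sd = 2.5` percent. The advice
  weight is `w = clip(w_arm + u_j, 0, 1)` with true arm means
  `w_ALGORITHM = 0.44`, `w_CLINICIAN = 0.31` and a participant-level shift
  `u_j ~ N(0, 0.10²)` giving the mixed model's random intercept a true
  variance component. A `true_weight` callable can replace the arm means
  with any function of arm, strength, profession and experience.
* **Dropout** is participant-level: with probability 0.124 a participant
  completes a uniformly chosen strict subset (0–4) of their five
  vignettes; with 323 enrolled this leaves ≈283 completers.
* Estimates are integers (the elicitation grid); a raw-real mode
  (`integer_estimates=False`) exists for exact identifiability checks.

**Anchor calibration.** The default anchors (68, 62, 52, 47, 28 for advice
90, 90, 75, 75, 50) all sit 22+ points *below* their advice values. This
is deliberate: under the literal WOA formula, records with `i > a` that
move toward the advice score negatively and are clamped to 0, which would
bias every arm mean downward and shrink the arm contrast. A direct
numerical integration of the capped-WOA estimand under these defaults puts
the residual bias of the arm difference below 0.01, so recovery
experiments test the estimator rather than the bias of the capping rule.
The trade-offs are documented limitations: the generator's mean initial
estimate (≈51%) is lower than the ≈65% a real cohort produced, and its
overall WOA dispersion (SD ≈ 0.18) is smaller than the ≈0.35 observed in
real data — matching that dispersion would reintroduce a capping bias of
up to −0.04 on the arm contrast, at which point a "recovery" experiment
would no longer have a well-defined truth to recover. Real elicitations
also show digit preference, vignette–participant interactions and
non-Gaussian heterogeneity that the generator does not emulate; passing
recovery tests therefore validates the estimators under this generative
model, not the clinical realism of the data.

## Linear mixed model

`y = Xβ + u_j + e`, one random intercept per participant. Fixed effects
use treatment contrasts with reference levels: algorithm arm, doctor,
≤14 years' total experience, ≤5 years' palliative experience, strength 50
(strength is categorical, allowing the non-monotone pattern in which
intermediate advice is weighted least). Fitting profiles the restricted
likelihood down to the variance ratio ψ = σ_u²/σ_e²: given ψ, β is the
GLS solution via the rank-one Woodbury identity and σ_e² has a closed
form, so REML reduces to a bounded one-dimensional search (ψ on the log
scale, tolerance 1e-12, the ψ = 0 boundary always evaluated and flagged
when selected). An interior optimum is certified by a numerical gradient
check; non-convergence is reported, never silenced. ML is available for
likelihood-ratio comparisons. The full Gaussian log-likelihood at
arbitrary parameters is exposed (`loglik_at`) and verified in the tests
against brute-force per-cluster multivariate-normal densities to 1e-10;
balanced designs are verified against the closed-form ANOVA/GLS estimator
to 1e-6, and whole fits against an independent mixed-model implementation.
Inference is by Wald tests on the GLS covariance (z for single
coefficients, joint χ² for interaction blocks, matching how moderation is
conventionally reported in this literature); moderators are fitted one
interaction model at a time. Rank-deficient designs raise an error naming
the collinear columns.

## Multilevel ordinal model

Proportional odds on the five WOA categories:
`P(Y_ij ≤ k | u_j) = logistic(κ_k − x_ij'β − u_j)`, `u_j ~ N(0, σ_u²)`.
Thresholds are parameterised as a first cutpoint plus log-increments
(monotonicity by construction); σ_u is optimised on the log scale with a
wide lower bound so the zero-variance boundary is reachable and flagged.
The random intercept is integrated by *adaptive* Gauss–Hermite quadrature
(default 15 nodes): the integrand is strictly log-concave, so each
cluster's mode and curvature are found by damped Newton steps and the
quadrature grid is centred and scaled there. On test fixtures the
log-likelihood moves by <1e-6 between 15 and 31 nodes. With σ_u fixed at 0
the fit collapses to an ordinary proportional-odds model and matches an
independent implementation to 1e-4. Categories absent from the data are
merged away with a warning (their thresholds are unidentifiable), and
standard errors come from a finite-difference observed-information matrix.

## Sample size

Two-sample normal approximation:
`n/arm = 2 (z_{1−α/2} + z_power)² (sd/Δ)²`, rounded up, doubled. The
planning convention (α = 0.05 two-sided, power 0.80) is exposed as
parameters rather than hard-coded, since design descriptions of this kind
often state only "95% confidence". Within the planning envelope
(sd 0.3–0.4, detectable difference 0.085–0.155) the smallest
configurations give totals of 118–210, consistent with a 100–200
recruitment target.

## Problem sizes and numerical choices

Test and acceptance runs use: 10,000 participants for marginal
calibration (3σ binomial bounds); 50 seeds × 284 participants for the
arm-difference recovery experiment (tolerance ±0.02 around the true
−0.13, which covers the ≤0.01 capping bias plus Monte-Carlo error);
500 replicates × 60 participants for type-I-error calibration (accepted
band 0.03–0.08 at the 5% level); 1,000 seeds for randomisation-invariant
checks; 300 participants × 5 records for ordinal self-recovery. These
sizes make the full suite run in well under a minute while keeping
Monte-Carlo error far inside each tolerance. Ties in `searchsorted`
binning resolve to the right (0.2 → category 2); empty summary groups
return n = 0 rows with undefined moments; degenerate generator settings
(zero SDs, point-mass proportions) are supported exactly.

## Known limitations

* The generator cannot reproduce the real trial's coefficients — raw data
  are unavailable — so all quantitative validation is against the
  generator's own ground truth plus in-design arithmetic.
* Only a participant random intercept is modelled (no vignette random
  effects, no crossed structures), matching the analysis being emulated.
* The advice-source labelling and the advice values themselves are taken
  as given; the prognostic algorithm that produced them is out of scope.
* Negative-WOA handling and the exact covariate adjustment of the primary
  arm contrast are undocumented in the emulated analysis; defaults are
  this package's documented choices, switchable for sensitivity analyses.
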