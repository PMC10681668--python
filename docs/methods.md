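# Methods

## Model and assumptions

`btrr` fits a longitudinal tensor response regression: each (subject,
visit) image is a 3-D tensor whose mean is a sum of coefficient tensors
loaded by scalar covariates, with i.i.d. Gaussian residuals over
observed voxels and a single residual variance σ² shared across voxels,
visits and subjects.  Key modelling assumptions:

* **Low rank.** Every coefficient is a rank-R CP tensor; all
  coefficients share one rank per fit.  This is the dimension-reduction
  device (R(p1+p2+p3) parameters instead of p1·p2·p3) and the mechanism
  by which information pools across voxels: a margin element is informed
  by the whole tensor slice it touches, so coefficients at voxels
  missing for some subjects are still estimable.
* **Spatial smoothing through the margin prior.** Margins are Gaussian
  with squared-exponential correlation along their own axis,
  `W = w·Λ(α)`, `Λ[k,k'] = exp(−α(k−k')²)`.  The induced prior
  covariance between coefficients at voxels displaced along one mode is
  `Σ_r w1 w2 w3 exp(−α₁ d²)` — verified against Monte-Carlo in the test
  suite.  Note `W` is `w·Λ`, not `diag(√w)Λdiag(√w)`; the elementwise
  form is the one under which that closed form holds exactly.
* **Exchangeable residuals, no spatial residual correlation.** All
  spatial structure lives in the coefficients.
* **Identifiability.** CP margins are identified only up to channel
  permutation and rescaling (irrelevant: only reconstructed tensors are
  reported).  The population intercept M and subject intercepts B_i, and
  likewise Γ and the Θ_i, are separated only by their shrinkage priors —
  no sum-to-zero constraint is imposed.  Time-invariant effects D_s are
  likewise partially confounded with subject intercepts; in practice the
  shared-across-subjects structure of D_s lets the prior allocate common
  signal correctly, as the selection results confirm.

## Posterior computation

Systematic-scan Gibbs, one sweep = margins (family by family in model
order, channels innermost, modes 1→3), then scale blocks, then σ² last:

* **Margins** — Gaussian full conditionals.  Conditional on the other
  two modes, a margin enters the mean linearly, and because different
  elements of a margin touch disjoint voxel sets the likelihood
  precision is diagonal; the update is a p_d-dimensional solve.
  Residual tensors are maintained incrementally (a channel's
  contribution is added back, the three margins updated, the new
  contribution subtracted) and refreshed from scratch every 200 sweeps
  to bound float drift.
* **Margin variances w** — generalized inverse Gaussian
  `GIG(1 − p_d/2, λ, q/τ)` with `q = uᵀΛ⁻¹u`.  Draws use a custom
  log-concave rejection sampler (uniform centre + exponential tails
  envelope on the log scale), batched across all blocks per sweep;
  SciPy's `geninvgauss` serves as the independent oracle in tests, not
  as the sampler (it is ~30× slower per draw).
* **Rates λ** — Gamma (exponential–Gamma conjugacy).
* **Global scales τ** — the Gamma(a_τ, b_τ) prior is interpreted as a
  prior on the precision 1/τ, which makes the update conjugate Gamma;
  this is the reading consistent with an all-Gibbs scale update, and it
  is flagged here because the scale-versus-precision convention is
  genuinely ambiguous in this model family.
* **Lengthscales α** — log-normal random-walk MH (proposal variance
  σ_α² = 0.1 by default) with the log-scale Jacobian in the acceptance
  ratio; Λ Cholesky factors, inverses and log-determinants are cached
  per (mode, channel) and refreshed on acceptance.
* **σ²** — inverse Gamma, updated from the residual sum of squares over
  observed voxels only.

Validation: every block passes a Geweke joint-distribution
("getting it right") test on a (3,3,3)/rank-1 configuration with a
missing-voxel pattern, using bounded indicator statistics and long-batch
standard errors.  Two practical notes from that exercise: (i) the
successive-conditional chain mixes extremely slowly along weakly
identified scale directions (τ versus w) when priors are vague, so the
test uses tight scale priors and a high-noise residual prior — this is a
property of the validation construction, not of posterior sampling on
real data, where the data identify the products that matter; (ii) an
isolated single-block check of the τ update against its prior marginal
agrees to z ≈ 0.3.

**Defaults.** `a = b = 1` for all Gamma/inverse-Gamma hyperparameters
(weakly informative at unit scale — appropriate because covariates are
z-scored and outcomes are standardized), σ_α² = 0.1, margins initialized
N(0, 0.1²) (a small random start avoids the saddle at zero where every
CP product has zero gradient), scales at prior-mean values, 5000
iterations with 2500 burn-in by default.  A fixed seed yields a bitwise
reproducible chain.

## Feature selection and derived maps

Simultaneous credible bands: per-voxel type-7 (linearly interpolated)
empirical quantiles at α/2 and 1−α/2, widened by the maximal deviation
of those quantiles from the posterior mean across the tensor's voxels;
a voxel is selected when its joint band strictly excludes zero (a band
touching zero at an endpoint is *not* selected).  One band is built per
coefficient tensor, and per derived map.  Neuroplasticity maps are
computed per MCMC draw as the model-implied difference of expected
images between consecutive visits (intercepts cancel; the identity with
the mean-difference computation is asserted numerically in tests);
group maps average member draws iteration by iteration.  Predictive
intervals for held-out voxels add a Gaussian noise draw to the fitted
mean per iteration and band the whole target set jointly.

## Rank selection

Gaussian deviance `−2 log L` over observed voxels; DIC with the
Spiegelhalter effective-parameter count `p_D = D̄ − D(θ̄)`, `θ̄` the
posterior mean of the dense coefficient tensors and of σ².  Candidate
ranks are fitted with identical settings and seeds; ties break toward
the smaller rank, and a numerically failed fit is excluded and logged.

## Synthetic data generator

The generator is the package's test bed and defines the study
conditions: 16×16×16 outcomes, 14 subjects, 3 visits at times 0, 1, 2,
four covariates (two time-varying `z`, and either two time-invariant
`x`, or one `x` plus one Bernoulli(0.5) covariate with time-varying
effects), no subject time slope in the truth, and Gaussian noise
calibrated so the mean voxel-wise SNR is 0.75.  The SNR of a voxel is
defined as the variance of its noise-free mean across (subject, visit)
observations divided by σ²; σ² is solved in closed form so the mean over
non-degenerate voxels hits the target, which the generator then reports
back as a check.

* **Scheme 1** — every coefficient (intercepts included) is a rank-2 CP
  tensor with binomially distributed 0/1 margin entries (zero with
  probability 0.55), so nonzero coefficient voxels take integer values
  ≥ 1.  The exact-zero fraction has the closed form
  `(1 − (1−p₀)³)^R ≈ 0.826` at the default p₀ = 0.55; a
  `target_zero_fraction` option solves for p₀ instead when a specific
  sparsity (e.g. 75%) is wanted, and realized sparsity is always
  reported.
* **Schemes 2a/2b** — coefficients supported on spherical / cubic
  volumes: the support is the set of exactly-k nearest voxels to a
  random center under the Euclidean / Chebyshev metric, with k chosen
  from the target zero fraction (75%).  Taking nearest voxels calibrates
  the volume exactly even when the shape clips the grid edge.  Magnitude
  is constant 1 inside the support with a random sign per coefficient —
  the simplest choice consistent with sharp-edged signals.
* **Schemes 3a/3b** — as Scheme 2 for three time-invariant effects,
  plus one time-varying effect whose per-visit supports share one center
  (hence are nested) and shrink on a linear zero-fraction schedule 50% →
  71.5% → 93% across the three visits.
* **Holdout** — a uniformly random voxel subset of the final visit is
  removed from every subject's mask (visits 0–1 stay fully observed);
  the noise-free truth at held-out voxels is retained for coverage
  scoring.

What the generator does **not** emulate: registration error, spatially
correlated or non-Gaussian noise, lesion-shaped missingness geometry,
subject dropout, or intensity nonstationarities.  Passing tests
therefore demonstrate correctness of the estimation and inference
machinery under the model's own assumptions plus sharp-edged
misspecified signals (Schemes 2–3), not robustness to real acquisition
artifacts.

## Problem sizes used in the shipped experiments

The validation experiment fits five Scheme-1-style replicates at
12×12×12 (other conditions unchanged: 14 subjects, 3 visits, SNR 0.75,
rank 2 truth and fit, 25% holdout) with 1500 iterations / 750 burn-in —
about 75 s per replicate — and smaller grids for the Geweke, DIC and
recovery suites.  These sizes were chosen so the full suite documents
the method's behaviour at interactive timescales; the defaults
(16×16×16, 5000 iterations) reproduce the full-size study conditions.

## Numerical choices and degenerate inputs

Λ carries a 1e-8 diagonal jitter (α → 0 makes it singular); a margin
posterior precision that fails Cholesky is jittered once and logged; GIG
rate parameters are floored at 1e-12 (an exactly zero margin has zero
quadratic form); extents of 1 make Λ the scalar 1 and the lengthscale
prior its own posterior; an all-zero generated signal (margin-zero
probability 1) falls back to unit noise variance since SNR calibration
is undefined.  Empty observed-voxel sets are allowed everywhere except
deviance computation, where they are an error.

## Known limitations

σ² is homoscedastic across voxels and visits; coefficient families
share a single rank; no trans-dimensional moves on the rank; the
cross-sectional configuration drops subject-level terms rather than
modelling exchangeable visits explicitly; voxel screening assumes
registration and masking were handled upstream.
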