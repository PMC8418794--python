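# Methods

This note documents the statistical machinery in `multidsm`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate.

## Two-stage structure

The package estimates abundance in two stages.  Stage one fits, per
platform, an observation model: a distance sampling detection function
(half-normal `g(x) = exp(−x²/2σ²)` or hazard-rate
`g(x) = 1 − exp(−(x/σ)^−b)`, `b > 1`), a strip/plot protocol (`p ≡ 1`), or
an independent-observer double-observer model (distance model × logistic
conditional-detection model for g(0)).  Stage two fits one penalized-spline
count model to the segment counts of *all* platforms, with each segment's
detectability entering through the log offset
`log(a · p · g(0) · u)`.  Stage-one uncertainty is then propagated into the
stage-two posterior covariance (below).

Units are the user's responsibility but only one convention is accepted:
distances, truncation and bin cutpoints in one length unit; areas in its
square.  When no area column is supplied the package derives
`a = sides · w · effort_length`, which is the covered-strip area; a supplied
column always wins.

## Detection functions

* Scale covariates enter by log link, `σ = exp(θ0 + Σ θ_q z_q)` (the
  multiple-covariate distance sampling convention).  Because the count
  model aggregates to segments, detection covariates must be constant within
  a segment; observation-level covariates are rejected at fit time (bin the
  covariate and duplicate segments if needed).
* The hazard-rate shape is parameterized `b = 1 + exp(φ)` so the optimizer
  is unconstrained while `b > 1` is guaranteed.
* Exact-distance likelihoods use the per-detection distance density
  `g(x)/∫g` (lines) or `r·g(r)/∫r·g` (points); binned likelihoods are
  multinomial over the cutpoints, conditional on detection.  Bins are
  half-open `[c_j, c_{j+1})` with the last closed at `w` — boundary ties have
  probability zero under the continuous model, so this convention is
  harmless and is applied uniformly.
* Average detectability integrals: half-normal has closed forms (erf for
  lines, exponential for points).  Hazard-rate integrals use a fixed
  100-point Gauss–Legendre rule, which agrees with adaptive Gauss–Kronrod
  quadrature (absolute tolerance 1e−10) to better than 1e−8 on the tested
  parameter ranges; the adaptive rule is kept as a cross-check path
  (`detection.average_p_quad`) and the agreement is asserted in the tests.
* Parameter covariance is the inverse observed information, with the Hessian
  by central finite differences (relative step `1e−5·(1+|θ|)`).  A
  non-positive-definite Hessian falls back to the pseudo-inverse with a
  warning flag on the fit.  Gradients of `log p` per segment use the same
  finite-difference scheme.
* No cosine/polynomial adjustment series are implemented: the intended use
  cases are plain key functions with covariates, and adjustment terms would
  complicate the offset gradient machinery for little benefit at segment
  scale.

## Double-observer g(0)

Only the full-independence independent-observer configuration is
implemented: each observer's detections are Bernoulli trials for the other,
a logistic model (distance plus optional covariates) is fitted per observer
via IRLS (statsmodels GLM), and
`g(0) = p1(0) + p2(0) − p1(0)p2(0)`.  Point independence is out of scope.
The distance model and the conditional model are estimated separately and
multiplied; the platform's joint parameter covariance is assembled
block-diagonally from the two parts, which treats the two likelihoods as
independent (they condition on disjoint information).  Complete separation
(e.g. every trial a success) triggers a weak ridge (1e−4) refit with a
warning rather than an error, since near-certain detection is a legitimate
regime.

Fixed external multipliers — an aerial g(0) from a prior study, an
availability probability from tag data — attach to segments as columns.
Their CVs never enter the propagation refit; they are combined into the
final abundance CV by squared-CV addition, on the stated assumption that
they are independent of the survey.

## The penalized-spline engine

No installed Python library fits penalized-spline GAMs by REML with the
pieces this model needs (offsets with derivative-column random effects,
factor-smooths, Tweedie), so the engine is implemented here.

* **Bases.**  One-dimensional terms use cubic B-splines with knots at
  covariate quantiles and the exact integrated-squared-second-derivative
  penalty (piecewise-polynomial Gram matrix by Gauss quadrature, exact for
  cubics).  Two-dimensional terms use a thin-plate-type radial basis
  `η(r) = r² log r` evaluated between data points, eigen-truncated to the
  leading `k` modes with the polynomial null space handled explicitly — the
  standard low-rank thin plate regression spline construction.  Every
  smooth block absorbs a sum-to-zero-over-data constraint (null-space
  reparameterization), losing one column; the model intercept (or platform
  factor) carries the level.
* **Shrinkage.**  The shrinkage variant adds `ε = 0.1 ×` (smallest nonzero
  penalty eigenvalue) on the penalty null space, so `λ → ∞` removes the
  whole term rather than leaving its linear part — the behaviour needed for
  smooth-term selection by the penalty alone.
* **Factor-smooths.**  A factor-smooth term is a reference-level smooth
  plus, per non-reference level, a deviation block (level indicator + the
  smooth's columns masked to that level).  The deviation penalty is the
  base wiggliness penalty normalized to unit spectral norm **plus the
  identity**: a single smoothing parameter per level then controls both the
  level and the wiggliness of that platform's deviation, the deviations are
  proper random effects that can borrow strength, and letting the deviation
  penalties go to infinity collapses the model onto the shared smooth
  (verified to a fitted-value gap below 1e−3).  Deviation penalties are
  separate per level by default; a `shared_lambda` option ties them.
* **Families.**  Poisson, quasi-Poisson (Pearson-estimated dispersion,
  covariance scaled, no AIC), negative binomial (size θ profiled in the
  outer optimization when not fixed) and Tweedie.  The Tweedie log-density
  is evaluated exactly by the compound Poisson–gamma series in the log
  domain (summation window around the dominant term); it was cross-checked
  against an independent implementation (mgcv's `ldTweedie`) to 1e−6.  Note
  the Tweedie density converges to the Poisson *law* only weakly as
  `p → 1`: probability mass near an integer matches the Poisson pmf, but
  the density at the integer does not converge pointwise — the tests check
  the integrated-mass statement.  The Tweedie index `p` is profiled over
  the fixed grid {1.1, …, 1.9} by REML rather than optimized continuously:
  the REML surface in `p` is flat near the optimum and the grid keeps the
  outer problem well-behaved and testable.
* **Fitting.**  Inner loop: penalized IRLS with step-halving on the
  penalized log-likelihood; convergence requires both a stationary
  objective and coefficient changes below 1e−9 (the latter matters — the
  factor score equations are only satisfied to the accuracy the
  coefficients themselves reach).  Outer loop: Nelder–Mead on the log
  smoothing parameters (plus log φ or log θ where applicable) maximizing
  the Laplace-approximate restricted marginal likelihood

      V(λ) = ℓ(β̂) − β̂ᵀS_λβ̂/2φ + ½log|S_λ/φ|₊ − ½log|(XᵀWX+S_λ)/φ|
             + (M_p/2) log 2π,

  with the penalty pseudo-determinant computed per block (blocks are
  disjoint by construction).  A coarse log-λ grid restart guards against a
  bad start; failure from all restarts is an error, not a silent fallback.
  Degenerate cases: `k` above the number of distinct covariate values is
  reduced with a warning; an exactly singular penalized information matrix
  raises.
* **Outputs.**  `V_β = φ(XᵀWX+S_λ)⁻¹` (the Bayesian posterior covariance),
  per-term effective degrees of freedom from `tr(F)`, AIC as
  `−2ℓ(β̂) + 2·EDF`.  In the unpenalized limit the fit, covariance and AIC
  reproduce a generic IRLS GLM to 1e−8 (asserted against statsmodels).

## Model variants and diagnostics

Variant A uses a global intercept; variant B replaces it with an
unpenalized one-hot platform factor (no reference level, no global
intercept); variant C keeps the global intercept and turns every smooth
into a factor-smooth over platform.  The three are nested by construction.
For simultaneous protocols the segment table is duplicated per platform
(ids suffixed `:platform`), each copy carrying its own count and covered
area; shared environmental covariates are identical across copies.

The observed-vs-expected diagnostic aggregates counts and fitted values by
any covariate (in the model or not) and reports plain Pearson
`χ² = Σ (O−E)²/E`.  Aggregation coarser than the segment is essential: the
smoother predicts small positive values where exact zeros were observed, so
segment-level comparisons are uninformative.  This definition reproduces the
reference worked-example value 38.26 exactly from its observed/expected
table (fulmar counts by behaviour), which is the anchored check in the
acceptance suite.

## Variance propagation

Stage one yields `V_θ = diag(V_θ1, …, V_θK)` (strip platforms contribute no
block).  The count model is refitted with additional columns `D_k` holding
`∂ log p_k(θ; z_jk)/∂θ_k` at `θ̂_k` (zero on other platforms' rows), with
coefficients treated as a random effect with mean zero and *fixed*
precision `V_θ⁻¹` — fixing the prior is what makes this propagation rather
than re-estimation.  Smoothing parameters are held at their estimates from
the original fit.  The joint posterior covariance `V_{β,θ}` of all
components, including β–θ cross-covariance, is
`φ([X D]ᵀW[X D] + blockdiag(S_λ, V_θ⁻¹))⁻¹`; its β block carries the
propagated uncertainty into any prediction.  With `V_θ = 0` the procedure
is exactly a no-op.  If the refit diverges, the package falls back to the
unpropagated covariance with a prominent warning so the user can combine
CVs by the delta method instead (`delta_method_total_cv`).

## Abundance and posterior sampling

`N̂ = a exp(X_p β̂)` over the prediction grid; variants B and C replicate
the grid per platform and sum the per-platform predictions (the platforms
index distinct density surfaces, e.g. swimming and flying birds).
Uncertainty comes from B coefficient draws:

* `mvn` — draws from N(β̂, V_{β,θ});
* `mh` — adaptive random-walk Metropolis–Hastings on the penalized
  posterior.  After propagation the target is the *augmented* posterior in
  (β, δ) with the fixed detection prior, so the draws reflect detection
  uncertainty; the proposal covariance is `c·V` with `c` adapted toward
  0.2–0.4 acceptance over a burn-in of B/5, thinning 1, and the β block is
  returned.  Acceptance outside [0.1, 0.6] warns.

Default B is 10 000 for reporting and a few hundred in tests.  Summaries:
posterior CV of N̂, percentile intervals, per-cell density and CV; fixed
multiplier CVs join by `sqrt(Σ cv²)`.  MH settings (burn-in, proposal
scheme) are this package's choices; nothing external prescribes them.

## Simulator

The simulator exists so that every stage is testable with known truth.
Animals arise from a named intensity surface (constant, log-linear, or a
fixed log-smooth `D0·exp(α sin(2πx/Lx)cos(πy/Ly))`) over a rectangle;
parallel vertical transects are cut into equal segments; available animal
counts per covered strip are drawn from the chosen count family around
`density × multiplier × area × availability` and thinned by the true
detection process.  Distances are uniform within the strip (triangular for
points), optionally binned.  Double-observer platforms use a two-part
process — a distance-driven cue following the platform's key function, then
independent per-observer logistic conditional detections — so the pooled
distances follow the key function and `g(0) = p1 + p2 − p1p2` exactly,
matching the two-part estimator.  One root seed spawns child streams (one
for shared covariates, then one per platform in list order), so runs are
reproducible at table level and ports can match distributionally.

Profile defaults mirror the two motivating designs: the seabird profile has
four distance bins (0, 50, 100, 200, 300 m expressed in km), a one-sided
300 m strip and duplicated segments; the cetacean profile has a 6 km
hazard-rate shipboard MRDS platform with a distance-only conditional model
and a 900 m aerial platform taking fixed multipliers g(0) = 0.67 and
availability u = 0.37.  The base densities and transect layouts are chosen
so fits are stable at desk scale (tens of segments, hundreds of
detections).  The simulator deliberately omits animal movement, responsive
movement, spatially correlated availability, and group-size biased
detection; passing tests therefore demonstrate correctness of the
estimation machinery under the stated model, not robustness to those
violations.

Thinned Poisson counts remain Poisson, and thinned negative binomial counts
remain negative binomial with the same size, so detection thinning preserves
those families exactly; Tweedie thinning is approximate (per-animal
thinning of a compound Poisson–gamma draw after rounding), which is
adequate for smoke-level fixtures but the precision tests all use Poisson.

## Problem sizes and numerical tolerances

Simulation tests use deliberately small designs — 20–130 segments, a few
hundred to ~1 500 detections, B between 300 and 20 000 draws, 100–400
replicates for Monte Carlo means, 200 surveys for interval coverage — sizes
at which every property under test is already sharply resolved.  Key
tolerances: quadrature cross-checks 1e−8; GLM equivalence 1e−8; propagation
no-op 1e−6; factor-smooth collapse 1e−3 on fitted values at deviation
λ = 1e8; recovery checks at 3 (Monte Carlo) standard errors; coverage in
[0.90, 0.98].

## Known limitations

* Detection parameters cannot be shared across platforms (each detection
  function is fitted separately); a joint model would need a different
  fitting framework.
* Detection covariates only at segment level (count-model restriction).
* Full-independence g(0) only; no point independence, no one-way trial
  configurations.
* No adjustment-series detection functions, left-truncation, or group-size
  bias modelling; the response is individuals per segment.
* No tensor-product anisotropic smooths or spatio-temporal terms.
* The CLI persists fitted-model state between stages via pickle inside the
  run directory; these files are run-local artifacts, not an interchange
  format.
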