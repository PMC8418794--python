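# multidsm

Density surface models (DSMs) that combine **multiple survey platforms** —
conventional and multiple-covariate distance sampling, double-observer
(mark–recapture) distance sampling, and strip/plot transects — in a single
spatially explicit model of animal density and abundance.

It is written for quantitative ecologists who have line/strip/point transect
survey data from more than one platform or protocol (aerial + shipboard
surveys of cetaceans; seabirds-at-sea protocols that record swimming birds by
distance sampling and flying birds by strip transect) and want one spatial
model, with detection uncertainty correctly carried into the final abundance
CV.

## The model

DSMs are a two-stage approach.  Stage one estimates each platform's
observation process; stage two models the per-segment counts with a
generalized additive model (GAM).  With platforms indexed `k = 1, …, K` and
segments `j_k`, the count model is

    E[n_jk] = a_jk · p_k(θ̂_k; z_jk) · exp( β0 + Σ_m f_m(x_m,jk) )

where `a_jk` is the segment's covered area, `p_k` the platform's average
detection probability given segment-level detection covariates `z`, and the
`f_m` are penalized regression splines of environmental covariates with
smoothing parameters chosen by REML.  The product `a·p` (possibly times a
trackline-detection probability g(0) and an availability probability `u`)
is the *offset* — an effective area.  Three variants express how density may
differ between platforms:

* **A** — common intercept `β0`: count differences are detectability alone;
* **B** — per-platform intercepts `β_k`;
* **C** — factor-smooth interactions `f(x, y, k)`: the smooths themselves
  vary by platform, as deviations from a reference-level smooth.

Detection probabilities come from half-normal or hazard-rate detection
functions (exact or binned distances, line or point transects, covariates on
the scale parameter); strip transects take `p ≡ 1`.  For double-observer
(independent observer) data, each observer's detections are
capture–recapture trials for the other; a logistic conditional-detection
model yields `g(0) = p1(0) + p2(0) − p1(0)·p2(0)`, which multiplies the
offset.

Detection uncertainty is propagated by refitting the count model with
per-platform columns holding `∂ log p_k / ∂θ_k`, treated as a zero-mean
random effect with fixed prior covariance `V_θ = diag(V_θ1, …, V_θK)`.
Abundance over a prediction grid is `N̂ = a exp(X_p β̂)`; its uncertainty
comes from posterior draws of the coefficients (multivariate normal or
Metropolis–Hastings), and independent external multipliers (a fixed aerial
g(0), an availability estimate) add their squared CVs.

## Worked example

The built-in simulator generates multi-platform surveys with known truth.
Below, a seabirds-at-sea style survey: swimming birds recorded in four
distance bins out to 300 m, flying birds by one-sided strip transect on the
same (duplicated) segments, with a true between-platform density difference.

```python
import multidsm as m

design = m.simulator._profile_design("fulmar_like", 7)
segments, observations, truth = m.simulate_survey(design)

fits = {}
for sp in design.platforms:
    pl = sp.platform
    sub = observations[observations.platform_id == pl.platform_id]
    fits[pl.platform_id] = m.fit_detection(sub.reset_index(drop=True), pl, segments)

spec = m.DsmSpec(variant="B_factor_intercept",
                 terms=[m.SmoothSpec(("x", "y"), k=20)], family="poisson")
fit = m.fit_dsm(spec, segments, fits)
print(m.dsm_report(fit))

V, order = m.assemble_v_theta(fits)
m.propagate_variance(fit, V, order)
est = m.abundance(fit, m.prediction_grid(design), B=2000, seed=1)
print(est.summary())
```

prints

```
Density surface model — variant B_factor_intercept, family poisson
  n segments: 128   platforms: flying, water
  REML score: -344.1727   AIC: 648.1118   total EDF: 16.601
  term factor(platform_id)          edf   2.000
  term s(x,y)                       edf  14.601
  lambda[s(x,y)] = 0.5884
  platform flying: observed 1053 fitted 1053.0
  platform water: observed 472 fitted 472.0
Abundance: N_hat = 22923.0
  posterior CV = 0.0323
  95% interval from draws: [21670.8, 24584.9]
  platform flying: N_hat = 13148.4
  platform water: N_hat = 9774.5
```

The binned half-normal detection function recovered a scale of
`exp(−1.887) ≈ 0.152` (truth 0.15), so average detectability of swimming
birds within the 300 m strip is 0.60 — which is why the per-platform
abundances (9 774 swimming, 13 148 flying; simulated truth 10 391 and
12 470) are roughly double the raw counts once effort and detectability are
accounted for.  The per-platform intercepts absorb the real density
difference between behaviours, and the fitted totals match the observed
totals exactly (the factor's score equation under a Poisson log link).

## Command line

A YAML config drives a five-stage pipeline:

```sh
multidsm simulate      --config config.yaml --outdir run/
multidsm fit-detection --config config.yaml --outdir run/
multidsm fit-dsm       --config config.yaml --outdir run/
multidsm predict       --config config.yaml --outdir run/
multidsm report        --config config.yaml --outdir run/   # variant comparison
```

All outputs (reports, per-cell predictions, model comparison tables) land in
the run directory with the config hash and seed recorded.

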