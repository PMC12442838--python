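# Methods

This note records the models, the numerical choices, and the limits of
what the test suite demonstrates.

## The measurement model

A response `x ∈ {0,1}` with time `t` on one item is modeled as a Wiener
diffusion with drift `μ`, boundary separation `α`, nondecision time `Ter`,
diffusion coefficient fixed at 1 and unbiased starting point `z = α/2`
(the symmetric ±(x−½) form of the density forces both conventions). The
joint defective density is the classical dual-series first-passage law;
the marginal probability of the upper boundary is `logistic(αμ)`, and the
mean decision time is `(α/2μ)·tanh(μα/2)` (limit `α²/4` at `μ = 0`).

The item-response layer decomposes `μ_ph = θ_p − v_h` and
`α_ph = γ_p / a_h`. `v_h` is item difficulty on the drift scale: responses
are fastest far from `v_h` and slowest near it (distance–difficulty;
expected RT is an inverted U in `θ` peaking at `v_h`, which the suite
checks on the fitted model). `a_h` scales how much of a person's caution
the item consumes.

### Estimation

Item parameters `(v_h, a_h)` and the population spreads are estimated by
marginal ML, treating every person–occasion row as an exchangeable unit:
`θ ~ N(0, ω_θ²)` and `log γ ~ N(0, ω_γ²)`, independent, integrated on a
15×15 tensor Gauss–Hermite grid. Fixing both population means at zero
anchors the translation/scale confounding in the decomposition; the
estimated `v_h` are therefore shifted by the (unidentified) mean person
drift and `a_h` scaled by the mean boundary, which is why recovery is
stated as a correlation, not an absolute error.

Nondecision time is profiled per row as `Ter_i = κ · min_h t_ih` with
`κ = 0.9` (configurable). With at most five RTs per row a free `Ter` is
weakly identified; the κ-profile is a declared stand-in rather than an
estimate, so κ-sensitivity is checked, not assumed: the suite rescores a
fitted model at κ = 0.8 and verifies that the drift-score ranking is
essentially unchanged (rank correlation > 0.9), since the profile mainly
reallocates a common offset between `Ter` and decision time.

Scores are EAPs of `θ` and `log γ` on the same grid. The derived speed
variable plugs the EAP into `mean_h |θ − v_h|` (the plug-in transformation
of the person drift, not the EAP of the distance). Log-boundary scores
more than 5 interquartile ranges below the median (a configurable rule)
are set missing, mirroring the removal of a handful of extreme negative
boundary outliers in practice.

### Numerics of the first-passage density

The large-time sine series converges poorly just above `Ter`; below scaled
time `s = (t−Ter)/α² < 0.35` the Gaussian-mirror (small-time) form is used
instead. Both are evaluated in log space with the leading term factored
out; truncation depths are chosen from the extreme `s` in each call so the
neglected term is below 1e−12 relative, with a hard cap of 500 terms
(exceeding it raises an error naming `t−Ter` and `α`). Total mass is 1
within 1e−6 across `(μ, α) ∈ [−2,2] × [0.5,3]`, which also settles the
reading of the density's normalizing constant as `π/α²`.

The sampler draws the boundary from the logistic law and the decision time
by inverse CDF on a per-parameter grid (768 points out to the conditional
mean plus 32 decay lengths of the slowest eigenmode). With an unbiased
start, the conditional time law is the same for both boundaries and
depends only on `|μα|`, which makes the per-draw grid cheap. A fine-step
random-walk sampler (1 ms Euler steps) exists purely as a cross-check.

## Two-level analyses

All multilevel machinery rests on ML fits of a two-level multivariate
normal: each occasion variable is a latent person mean plus an occasion
deviation, `Σ_b` between persons, `Σ_w` within, unbalanced cluster sizes,
Cholesky-parameterized, with person-level covariates carrying no
within-level component. The within/between covariance matrices then give
in closed form: the null-model ICC; level-specific regression paths and R²
(the latent covariate approach — using latent person means avoids the
attenuation of manifest cluster means, which the suite demonstrates on a
5-occasions-per-person construction where the manifest between-slope is
substantially biased toward the within slope and the latent one is not);
level correlation matrices;
and mediation paths, for which `c = c' + Σ a·b` holds exactly at the
estimates.

Indirect-effect intervals use the Monte-Carlo method: the path vector is
sampled (100,000 draws, seeded) from its asymptotic normal distribution
(delta method through the numerical Hessian of the fit), and the product's
2.5/97.5 percentiles form the interval. This is asymptotically equivalent
to Bayesian product-of-coefficients intervals with flat priors; a Bayesian
backend was deliberately not added. Standardization follows the reporting
convention for binary predictors: paths out of a 0/1 predictor are
standardized only with respect to their dependent variable.

The dependent-correlation test resamples persons (1,999 replicates,
seeded) and recomputes *moment* estimates of the level correlations per
replicate (pooled within-person covariance; between-covariance of person
means minus `Σ_w · mean(1/n_j)`); the point estimate still comes from the
ML fit. Refitting the ML engine per replicate would cost three orders of
magnitude more for no inferential gain at these sizes.

The univariate null model supports ML (default) and REML. On balanced
data REML reproduces the one-way ANOVA moment estimators exactly (the
suite asserts agreement to 1e−6); ML divides the between mean square by
`J` rather than `J−1` and is the default because the multivariate engine
is ML throughout.

## Growth curves

Practice effects follow `y_ij = a_j − g_j · exp(−r · occasion_ij) + e_ij`
with occasions coded 0, 1, 2, … in *scheduled* prompt order (missed
prompts leave gaps; completed-order coding is a config choice). The gain
is defined as `g = asymptote − initial level`, the signed change
accumulated over the study: falling log RTs have a negative gain, rising
drift a positive one. `(a_j, g_j)` are bivariate normal random effects;
the rate is a fixed effect by default — person-specific rates are fragile
with ≤ 42 occasions — with a log-normal random-rate option (Gauss–Hermite
integrated) off by default. Given `r` the model is linear mixed, so the
fixed means are profiled by GLS inside the likelihood; per-person algebra
reduces to 2×2 capacitance matrices via Woodbury, vectorized across
persons, which is what makes the joint bivariate-outcome fit (4×4 random
effect block shared across outcomes, outcome-specific residual variances)
cheap. Equality of absolute gains is a 1-df Wald test via the delta
method on `|g₁| − |g₂|`; rates near the zero boundary trigger a
degeneracy warning (the curve collapses toward an intercept-plus-slope
trend).

## The synthetic generator

The generator emulates the study conditions end to end: 954 persons
(configurable), 7 days × 6 prompts, 75% completion (prompts missing
completely at random), five 0–100 affect items and three binary event
items, integer-second RTs. Person means of `θ` and `log γ` are normal
with SDs giving latent ICCs 0.31 and 0.39; neuroticism and depression
(standardized, correlated 0.5) load negatively on both person means;
momentary work lowers and recovery raises both `θ` and `log γ` by the
standardized amounts reported for such effects (−0.254/−0.133 and
+0.106/+0.075 within-SD units); practice trends add
`gain · (1 − exp(−0.25 · occasion))` with gains +0.752 (drift) and −0.825
(boundary) in total-SD units. Item responses are sampled from the exact
first-passage law with `μ = θ − v_h`, `α = γ/a_h`, plus a lognormal
per-occasion nondecision time.

Calibration constants chosen once from the emulated conditions and then
frozen: mean log boundary 1.5, `Ter ~ lognormal(0.85, 0.25)` seconds,
log-boundary SDs (0.20, 0.25), difficulties spread over [−0.5, 1.5] (so
negative affect is endorsed in a minority of moments). These jointly
reproduce the study's accounting at any design size: ≈ 3% of occasions
removed for invariant integer RTs, ≈ 0.1% of RTs above the 30 s cap, and
occasion mean log RT ≈ 1.42.

### What passing tests do and do not show

The generator draws every occasion independently given the person: no
time-of-day structure, no autocorrelated affect dynamics, no informative
missingness, no reminder-alarm behavior, and the nondecision time is
independent of the person parameters. Recovery results therefore certify
the estimation machinery under the model's own assumptions, not
robustness to the violations real EMA data will contain. Two attenuation
effects deserve note because they are *expected*, not bugs:

* **Scored ICCs are attenuated.** EAP shrinkage multiplies the ICC of the
  scored variables by roughly the per-occasion reliability, so scores
  from 5-item occasions show ICCs well below the latent 0.31/0.39. The
  self-consistency test asserts the configured ICC on the generator's
  true per-occasion parameters; the scored ICC is checked to be
  attenuated, never inflated.
* **The RT share explained by the scores is diluted** relative to what an
  error-free decomposition would give, because the generator's lognormal
  nondecision noise (unrelated to drift or caution) is a sizable share of
  log RT variance. Path signs and the cancellation structure are
  unaffected.

Integer rounding of RTs, the one measurement quirk the generator does
model, moves scored log-boundary values by < 0.05 mean absolute
difference at default settings — the continuous treatment of
integer-second RTs is safe.

## Sizes and tolerances used by the suite

Recovery tests run at the sizes where their tolerances are meaningful
rather than at full study scale: ~2,000 occasions for item recovery
(correlation ≥ 0.9), 500 × 20 for variance components (±15%) and latent
regression paths (±0.05 standardized), 500 × 30 for growth gains (±0.03),
100 × 8 × 100 replicates for mediation interval coverage. Density
normalization is checked to 1e−6, sampler agreement to 3 Monte-Carlo SEs,
and the sampler-vs-density Kolmogorov–Smirnov distance to < 0.02 at
10,000 draws.
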