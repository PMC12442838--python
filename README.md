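# emadiff

Drift-diffusion decomposition of response times in ecological momentary
assessment (EMA).

## The problem

EMA studies prompt people several times a day to rate momentary experiences
(e.g., five negative-affect items on a 0–100 scale). The response times
(RTs) to these items are routinely recorded but ambiguous: a fast answer
may mean the feeling was highly accessible (emotional clarity) *or* that
the respondent answered carelessly. The drift diffusion model separates
these processes. Each item response is treated as evidence accumulation
between two boundaries: the **drift rate** is how *fast* relevant
information is accessed, the **boundary separation** is how *much*
information the respondent requires before answering (response caution),
and a nondecision time absorbs reading and motor components.

`emadiff` implements the full response-process analysis for such data:

* a numerically careful two-boundary Wiener first-passage core
  (density, choice law, moments, exact-law sampler);
* the **D-diffusion item response model**: for person–occasion drift
  `θ` and boundary `γ`, item difficulty `v_h` and item time pressure `a_h`,

  ```
  μ_ph = θ_p − v_h,        α_ph = γ_p / a_h,
  P(x_ph = 1 | θ_p, γ_p) = exp(α_ph μ_ph) / (1 + exp(α_ph μ_ph)),
  ```

  fitted by marginal maximum likelihood (Gauss–Hermite quadrature over
  normal person effects) with per-occasion EAP scores, plus Q–Q RT
  diagnostics and a tetrachoric unidimensionality check;
* preprocessing exactly as practiced for these data: midpoint
  dichotomization of 0–100 ratings, removal of RTs above 30 s, removal of
  occasions with invariant RTs, work/recovery activity coding, mean log RT;
* two-level analyses of the scored occasions: variance decomposition and
  ICC (`ICC = τ²/(τ²+σ²)`), the latent covariate regression of observed
  RTs on drift and boundary at both levels, level-specific correlation
  matrices with dependent-correlation tests, and 1-1-1 / 2-1-1 mediation
  with drift and boundary as simultaneous mediators (Monte-Carlo intervals
  for products of coefficients);
* negative exponential growth curves `y = a − g·exp(−r·occasion)` for
  practice effects, with a joint bivariate-outcome Wald test comparing
  absolute gains;
* a calibrated synthetic-data generator that emulates the study design
  (954 persons × 7 days × 6 prompts, 75% completion, integer-second RTs,
  latent ICCs near 0.31/0.39, activity and covariate effects, practice
  trends) with the full ground truth exposed for recovery testing.

## Worked example

Simulate a 60-person study, fit the measurement model, and score occasions:

```python
from emadiff import data_model, diffirt, synthetic

cfg = synthetic.SyntheticConfig(seed=42, n_persons=60)
records, truth = synthetic.generate_dataset(cfg)
occasions, acct = data_model.preprocess(records, synthetic.affect_item_set(cfg))
fit = diffirt.fit_item_parameters(occasions)
scores = diffirt.scores_to_frame(diffirt.score_occasions(occasions, fit))
```

Running `python examples/03_fit_and_score.py` (this code plus the recovery
check) prints:

```
item      v_hat   a_hat   (true v, a up to the anchoring shift)
angry       0.494   0.276   ( 1.00, 0.80)
dejected    0.995   0.356   ( 1.50, 0.95)
frustrated -1.011   0.409   (-0.50, 1.10)
lonely      0.019   0.407   ( 0.50, 1.20)
stressed   -0.606   0.453   ( 0.00, 1.30)
omega_theta=0.774  omega_log_gamma=0.197  loglik=-17397.5
difficulty recovery correlation: 0.998
per-occasion EAP drift vs truth: r = 0.896 (shrinkage bounds precision at 5 items/occasion)
```

The estimated difficulties track the generating ones up to the anchoring
shift (population means of `θ` and `log γ` are fixed at 0), and the
per-occasion drift scores correlate 0.90 with the generating values even
though each occasion offers only five item responses.

The mediation example (`examples/05_mediation_work.py`) reproduces the
signature cancellation pattern — working lowers drift (slowing RTs) *and*
lowers caution (speeding RTs):

```
indirect via drift     +0.0812  95% CI [+0.0619, +0.1013]
indirect via boundary  -0.0311  95% CI [-0.0502, -0.0124]
total effect c:          +0.036
```

Both indirect effects are clearly nonzero with opposite signs while the
total effect on raw RTs is small — exactly why raw RTs alone mislead.

Each script in `examples/` is a short narrative for one capability
(Wiener core, simulation/preprocessing, fitting/scoring, reliability and
RT regression, mediation, growth). The `emadiff` command-line tool chains
the stages (`emadiff run --synthetic small --seed 7 --out results/`).

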