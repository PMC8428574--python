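# Methods

This note records the statistical conventions, numerical choices and known
limitations behind survkit. It is the place to look when a number depends
on a convention rather than on the data.

## Data model

A task holds an `n × p` numeric feature matrix, non-negative observed
times `T_i` and event indicators `δ_i ∈ {0, 1}` (1 = event, 0 =
right-censored). Only single-event right censoring is supported; the
`censoring_type` field is reserved for future schemes and anything other
than `"right"` is rejected. Times are unit-agnostic reals; ties are
allowed and preserved (no jittering). Missing values are a hard error —
imputation and categorical encoding are deliberately left to the caller.

## Survival-distribution objects

The `distr` prediction type is a discrete curve `S_i(t_k)` on a shared,
strictly increasing grid, interpreted as a right-continuous step function:

* `S_i(t) = 1` before the first grid point,
* `S_i(t) = S_i(t_k)` for `t ∈ [t_k, t_{k+1})`,
* constant extrapolation beyond the last grid point `t_m`.

These are the usual product-limit conventions; no interpolation or
parametric extrapolation is attempted. Consequences worth knowing:

* The **mean** functional is the restricted mean survival time
  `∫_0^{t_m} S_i(t) dt` of the step function. When `S_i(t_m) > 0` the
  unrestricted mean is undefined from the grid alone; the value saturates
  at the grid rather than guessing a tail.
* The **median** is the first grid time with `S ≤ 0.5`, saturating at
  `t_m` when the curve never crosses one half.
* Log-domain operations clamp `S` to `[1e-15, 1]` (the package-wide `EPS`)
  before `−log`, so cumulative hazards and log-losses stay finite.

## Learners

**Kaplan–Meier / Nelson–Aalen** use the event-time risk table (`d_j`
events, `n_j = #{T_i ≥ t_j}` at risk). A dataset with zero events yields
the curve `S ≡ 1` with a logged warning rather than an error, so pipelines
degrade gracefully on degenerate folds.

**Cox proportional hazards.** Breslow tie handling throughout — in the
partial likelihood, its derivatives and the baseline-hazard estimator.
(Efron weighting would differ on tie-rich data; references that default to
Efron will disagree there.) Features are centered internally and `lp` is
reported on the centered scale, which shifts `lp` values but not ranks or
hazard ratios. Fitting is Newton–Raphson from `β = 0` with step-halving;
convergence requires `max|score| ≤ 1e−9` (up to 100 iterations), with a
negligible-step escape (`max|Δβ| < 1e−10`) because for several thousand
subjects the score's float64 rounding floor can sit slightly above the
absolute tolerance. Monotone-likelihood separation — the MLE at infinity —
is detected by either an absolute coefficient bound (`|β_j| > 50`) or a
scale-aware one (`|β_j| · range(x_j) > 18`, i.e. fitted relative risks
beyond `e^18`); the scaled guard is the effective one, since on separable
data the score decays like `e^{−β}` and can dip under the tolerance while
`β` is still far from any fixed absolute bound. Constant covariates are
rejected up front (singular information).

**Weibull AFT.** `log T = μ + x'γ + σW` with `W` standard minimum-Gumbel;
the right-censored log-likelihood is maximized over `(μ, γ, log σ)` by
BFGS with an analytic gradient. The optimum is required to dominate the
log-likelihood at the moment-based initialization. `lp = μ + x'γ` is on
the log-time scale, so **higher lp means longer survival**; the crank
channel is `−lp` to keep the package-wide rule "higher crank = higher
risk". The response channel is the median `exp(lp + σ log log 2)`; the
distr channel evaluates the fitted parametric survival function on the
training event-time grid.

Crank conventions per learner: Cox `crank = lp`; AFT `crank = −lp`;
distribution-only learners `crank = −RMST` of their curve.

## Measures

All IPCW measures weight by a Kaplan–Meier estimate `G(t)` of the
censoring survival function (fit with the status flipped). Event-time
weights use the left limit `G(T_i⁻)`; at-risk weights at an evaluation
time `t` use `G(t)`. Denominators are floored at `1e−3` (weights capped at
1000) and floored evaluations are counted and logged.

The three scoring rules share one skeleton at each evaluation time `t`:
subjects dead by `t` contribute a loss on `1 − S_i(t)` weighted
`1/G(T_i⁻)`, subjects at risk past `t` a loss on `S_i(t)` weighted
`1/G(t)`, subjects censored by `t` nothing. The losses are squared error
(Graf/Brier), `−log` (log-loss, clamped by `EPS`) and absolute error
(Schmid). The default evaluation grid is the unique event times of the
test set; "integrated" means the trapezoid average over that grid
normalized by its range (a single evaluation time returns the pointwise
score). The log-loss here is the classification-style IPCW version at
each time point, not a density-based `−log f̂(T_i)`; the latter is a
different and equally defensible definition, and the choice is recorded
here precisely because the name "log-loss" does not pin it down.

Concordance: a pair is comparable iff the earlier subject's event was
observed (`T_i < T_j`, `δ_i = 1`); tied cranks count one half. Uno's
variant weights each comparable pair by `1/G(T_i⁻)²` and restricts to
`T_i < τ` (default: the largest event time); with no censoring it equals
Harrell's C exactly. The time-dependent AUC is the IPCW
cumulative/dynamic form: cases have events by the horizon, controls
survive past it.

Calibration: van Houwelingen's slope refits a one-covariate Cox model on
the predicted `lp` (ideal value 1; a doubled `lp` gives exactly ½ by the
Cox rescaling invariance). The KM-calibration measure is the numeric
counterpart of plotting the mean predicted curve over the test-set
Kaplan–Meier: it reports `max_t |S̄(t) − KM(t)|` and carries the curve
pair for plotting.

## Composition

With `η` the chosen channel (`lp` by default, `crank` allowed but then the
result is only rank-meaningful, which is logged):

* `ph`: `S_i = S_0^{exp(η)}` — exact constant hazard ratio;
* `po`: `S_i = S_0 / (exp(η) + (1 − exp(η)) S_0)` — chosen to satisfy the
  defining constant odds ratio `[F_i/S_i] / [F_0/S_0] = exp(η)` and the
  identity at `η = 0`, both of which are tested;
* `aft`: `S_i(t_k) = S_0(t_k e^{−η})` via the step convention, on the
  baseline grid (no re-gridding).

Under AFT, higher `η` stretches time and lengthens survival — the sign
asymmetry with ph/po is the standard convention and is deliberate. Because
the aft warp is evaluated on a finite step grid, the composed curve is
only *weakly* monotone in `η`: two nearby predictors can alias to the same
step pattern and tie in RMST. The ph/po forms are closed-form and exactly
rank-preserving.

## Resampling and benchmarking

`make_cv` builds a deterministic seeded partition with fold sizes
differing by at most one; optional stratification partitions events and
censored subjects separately (per-fold event counts within one of
proportionality). Within a benchmark, all learners share identical folds,
so comparisons are paired. IPCW weights are fitted on the **training**
fold by default (no test-outcome leakage into scoring weights); fitting on
the test fold is available via `ipcw_on="test"` as a sensitivity check.
Aggregation is the macro-average of fold scores; the per-fold table is
returned so pooled alternatives remain open to the caller. Zero-event test
folds score as missing with a warning and drop out of the aggregate; a
learner failure is confined to its grid cell. Execution is single-process
and deterministic.

## Simulator

Covariates are i.i.d. standard normal with linear effects
`η = x'β`. Event times are drawn by inversion — exactness and seed
stability are the reasons over rejection sampling:

* ph/exponential(λ): `T* = −log U / (λ e^η)`;
* ph/weibull(shape γ_w, scale s): `T* = [−log U / (s^{−γ_w} e^η)]^{1/γ_w}`;
* aft: `log T* = log s + η + W/γ_w`, `W` minimum-Gumbel.

Censoring is independent (exponential, administrative, or none). A target
censoring proportion is resolved by log-scale bisection of the exponential
rate on a fixed 20 000-subject pilot sample, making the realized
proportion a deterministic monotone function of the rate; the default
tolerance (0.005 on the pilot) leaves room for the ±0.02 sampling
variation of a fresh draw at that size. Each simulated task ships with a
hidden truth record (true event times, true linear predictors, censoring
times) used by the parameter-recovery and discrimination tests.

What the simulator does **not** emulate: correlated or non-Gaussian
covariate designs, non-linear or time-varying effects, informative
censoring, measurement error, competing risks. Tests passing on these
synthetic conditions validate the estimators and the scoring machinery,
not the adequacy of any model for a particular real dataset.

## Problem sizes used in tests

Parameter-recovery checks use n = 2000 (Cox, tolerance ±0.1 per
coefficient), n = 5000 (Weibull σ, ±0.05; calibration slopes, ±0.1);
scoring-rule oracle equivalence uses 200 random instances of n ≤ 20
against naive double-loop references at 1e−12; the benchmark replica uses
n = 600 with 3-fold CV. These sizes put Monte Carlo noise comfortably
inside the stated tolerances while keeping the whole suite fast.

## Known limitations

* Right censoring only; no truncation, competing risks or multi-state
  outcomes.
* Breslow ties only — no Efron option.
* Distributions are grid-restricted step functions; mean functionals
  saturate when curves do not reach 0.5 or 0 on the grid.
* Harrell/Uno concordance is computed via `O(n²)` pair matrices — fine to
  a few thousand subjects, not for `n ≫ 10⁴`.
* The learner set is intentionally small; external ML engines attach
  through the `fit`/`predict_surv`/`predict_types` contract rather than
  being bundled.
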