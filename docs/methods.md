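# Methods

## The growth model

Cumulative xylem cell production over a season is modelled with the
Gompertz function

    Y(t) = A * exp(-exp(beta - k * t)),

an asymmetric sigmoid with asymptote `A` (final cell number, cells), time
placement `beta` (dimensionless) and rate parameter `k` (per day).  Its
useful closed forms: the inflection sits at `t_p = beta / k`, where
`Y = A/e` and the slope peaks at `r_max = k A / e`; the day on which a
fraction `q` of the asymptote is reached is `t_q = (beta - ln(-ln q)) / k`.

The average rate between the 5% and 95% development dates has the exact
form `r_m = 0.9 A / (t95 - t5)`.  Because `t95 - t5 = ln(ln20 / ln(20/19)) / k`,
this is `0.60148 * r_max` for every parameter set.  The package defaults to
the conventional reporting approximation `r_m ≈ (9/40) e r_max =
0.61161 r_max` — the form under which published per-stand (r_max, r_m)
pairs round consistently at two decimals — and exposes the exact form via
`mean_rate(..., exact=True)`.  The two differ by less than 1.7% relative.

## Mixed-effects estimation

Each stand is fitted with a tree-level random asymptote:

    Y_ij = (A + a_i) * g(t_ij; beta, k) + eps_ij,
    a_i ~ N(0, sigma_A^2),  eps_ij ~ N(0, sigma_e^2),

with `g` the unit Gompertz curve.  Two structural facts make the fit exact
rather than linearization-based:

1. given `(beta, k)`, the random effect enters the mean *linearly*, so the
   marginal covariance of a tree's vector is the rank-one update
   `sigma_e^2 I + sigma_A^2 g g'` and the marginal likelihood integrates in
   closed form (Sherman–Morrison / matrix determinant lemma);
2. the population asymptote `A` is then the generalized-least-squares
   solution, so it is profiled out analytically.

The remaining four parameters `(beta, log k, log sigma_A, log sigma_e)` are
optimized by Nelder–Mead on the exact marginal log-likelihood (method
`"ml"`) or its restricted version (`"reml"`, the default), which adds the
usual `log |X' V^-1 X|` term with `X` the Jacobian of the mean in
`(A, beta, k)`.  At `sigma_A = 0` the objective reduces exactly to the
Gaussian nonlinear-least-squares likelihood (a continuity property the test
suite asserts).  With fewer than two trees the model degrades to plain NLS
with `sigma_A = 0` and a warning.

Starting values are deterministic: `A0 = 1.05 * max(y)`, and `(beta0, k0)`
by ordinary least squares on the linearization `ln(-ln(Y/A0)) = beta - k t`
restricted to interior points (`0.05 A0 < Y < 0.95 A0`).  Up to three
jittered restarts (seeded, default `random_state=0`) are attempted if the
first start does not converge; the convergence flag is reported honestly
and the best iterate returned either way.

Standard errors for `(A, beta, k)` come from the numerical observed
information at fixed variance components — the convention of standard NLME
software, reproduced here so the per-stand parameter table has the familiar
columns (estimate, SE, df = n_obs − 3, t).  Because count data are
heteroscedastic while the model assumes a common residual variance, the
estimator also provides tree-clustered sandwich SEs (`robust_se_`), with an
m/(m−1) small-sample factor.  With few trees the sandwich itself is noisy,
so calibration checks use the larger of the two — a deliberately
conservative interval.

`R^2` is population-level: `1 − SSE/SST` with fixed-effects-only
predictions, clamped to [0, 1].  (The definition used in published tables
is typically unstated; this choice is the most common and is documented
rather than inferred.)  Conditional (tree-level) predictions use the BLUPs
`a_i = sigma_A^2 g' V^-1 (y - A g)`.

## Phenology and extrema

Onset and end of wood cell development are the first and last *sampling*
days with a positive enlarging count (the row-averaged count used in
micro-core reading; "at least one row shows an enlarging cell").  No
interpolation between visits is attempted: published stand means are
consistent with integer sampling dates, and the sampling interval is the
honest resolution of the method.  An all-zero season returns an explicit
empty record rather than raising.  Durations satisfy
`duration = end − onset` by construction, and stand means inherit
`mean(duration) = mean(end) − mean(onset)` by linearity.

Phase trajectories are smoothed with LOWESS (locally weighted linear
regression, tricube weights, no robustness iterations — deterministic,
exact on constants and straight lines) at a default span of 0.25 of the
points.  Seasonal extrema are then local maxima/minima of the smoothed
series with prominence ≥ 0.5 cells (both config-exposed).  Boundary points
are eligible — dormant-season cambial counts typically peak at the first
sampling date — by padding the series with its minimum, which grants
boundary extrema a finite, comparable prominence.  When more than two
prominent maxima survive, the two most prominent are kept (day order
decides first vs. second) and the result is flagged ambiguous; equal
heights resolve to the earliest day.  The minimum between the two peaks and
the minimum after the second complete the quadruple; unimodal
(bell-shaped) phases report a single max/min pair.  Whether the second
peak stayed below the first is recorded as a flag, not enforced.

Defaults rationale: the two seasonal activity peaks are ~120 days apart,
while sampling is every 7–10 days; a span of 0.25 (~7–8 points ≈ 65 days)
suppresses sampling noise without merging peaks, and 0.5 cells is half the
smallest count increment a single row can produce.

## Rate vs. duration statistics

Age trends are tested, per seasonal characteristic, by regressing per-tree
values on stand age entered as a *numeric* covariate; the reported line is
the 1-df regression ANOVA (F equals the squared slope t).  A classical
one-way factor ANOVA (df = classes − 1) is available as `mode="factor"`.

The final cell number is regressed on per-tree formation rate and duration
by OLS (statsmodels), and the model's `R^2` is allocated between the two
predictors by the LMG decomposition: each predictor's share is the average,
over all orderings in which predictors could enter the model, of its
sequential `R^2` increment — computed from the subset-`R^2` formula with
combinatorial weights, for any number of predictors.  Shares are
non-negative and sum exactly to the full-model `R^2`; collinear (even
duplicated) predictors are allowed and split their joint contribution
symmetrically.  P-values come from exact F/t reference distributions with
no multiple-testing correction.

Because the duration definition (`end − onset`) and the "total cells ÷
duration" rate would make the decomposition circular, the per-tree rate
entering the regression is model-derived: `r_m` of the tree's
BLUP-adjusted asymptote by default, switchable to `r_max`
(`rate_def="max"`); the report manifest names the definition used.  The
per-tree inflection date is the stand-level `beta/k` (the curve shape is
shared; only the asymptote is tree-specific).

## The synthetic-data generator

The generator emulates a one-year, 5-stand × 5-tree micro-core campaign:
33 sampling dates every 9 days from day 51 to day 339 (825 observations),
per-stand asymptotes spanning ~95–360 cells across age classes, and a
dormant cambial baseline of 2–3 cells.

Cumulative production for a tree with asymptote `a` is a two-pulse
Gompertz mixture

    P(t) = a * [s * g(t) + (1 - s) * g(t - delta)],

which keeps the seasonal total S-shaped (a single-Gompertz fit to the
simulated totals still attains R² ≥ 0.85) while producing the bimodal
cambial/enlarging dynamics of subtropical seasons.  Phase counts follow by
fixed residence times — a cell enlarges for `enlarge_days` (default 18),
thickens for `thicken_days` (default 40), then counts as mature — so

    E_enlarging(t) = P(t) - P(t - e),
    E_thickening(t) = P(t - e) - P(t - e - w),
    E_mature(t) = P(t - e - w),

and the cambial count is `baseline + gain * dP/dt` (gain default 6 days:
peak cambial counts of ~5–9 cells above baseline at realistic peak rates).
The defaults place the wall-thickening peak between the two enlarging
peaks, as observed.  Tree asymptotes are `Normal(A_mean, A_sd)` truncated
at zero by resampling; noise is Poisson by default (integer,
variance-scaling, vanishing for near-zero expectations) with a
rounded-Gaussian alternative for controlled-SD experiments; counts are
clipped to non-negative integers and the total re-derived as the phase sum
so every row satisfies the table invariants.  Sub-seeds are derived by
SHA-256 hashing of `(seed, stand_id, tree_index)`, so adding a stand or
tree never perturbs other draws.

Two pulses merge into a single bump when they are close relative to their
width; bimodality requires roughly `k * delta ≳ 2.5`.  The five
campaign presets use published per-stand `(A, beta, k)` magnitudes with
`s = 0.55`, `delta = 90`; the sharply bimodal `bimodal_demo_scenario`
(k = 0.05, pulses peaking near days 110 and 235, peak counts ~12–18 cells
over Poisson noise, SNR > 3) is the reference fixture for phenology and
extrema studies, with its sampling window ending while expected enlarging
counts are still ~2 cells — as real campaigns end with 0–3 cells at the
last visits — so the end-of-season statistic is well-defined on the grid.

What the generator does *not* emulate: climate forcing, within-ring
anatomy, multi-year carry-over, observer/section-quality error, or any
correlation between a tree's asymptote and its timing.  Passing tests
therefore demonstrate internal correctness of the estimators on data
satisfying the model's assumptions, not robustness to every feature of
field data.

## Simulation sizes and numerical choices

Recovery and detection studies use sizes chosen to keep the full suite
fast while leaving clear statistical margin: 20 replicate stands (5 trees,
weekly sampling) for mixed-model recovery; 100 trees for
phenology/extrema detection; 100 random parameter draws against
grid/finite-difference oracles (relative tolerance 1e-4, grids bracketing
`t_p ± 4/k`).  Recovery simulations switch the cambial additive terms off
(`baseline = gain = 0`) so the simulated total follows the fitted model
exactly — parameter recovery is then a well-posed question; the campaign
presets keep the cambial terms, which is one reason their fitted
asymptotes need not equal the preset `A_mean`.

Optimizer: Nelder–Mead, function tolerance 1e-8, generous evaluation
budget, three jittered restarts.  Likelihood evaluations clip the
exponent `beta - k t` at ±700 to avoid overflow; degenerate proposals
(non-positive saddle terms) return +inf rather than raising.

## Known limitations

* Gaussian homoscedastic residuals on integer counts: faithful to standard
  practice in this literature, but mildly miscalibrated under Poisson-like
  noise — hence the robust-SE option.  With 5 trees per stand, ±2 SE
  intervals for the asymptote are near, not above, nominal coverage.
* The asymptote is an extrapolation whenever sampling stops before the
  curve plateaus; its SE is then large and right-skewed.
* Onset/end resolution is one sampling interval by design.
* Only the asymptote carries a random effect; no random `beta`/`k`, no
  residual autocorrelation, no alternative sigmoids.
* LMG enumerates predictor subsets (2^p fits); fine for the handful of
  predictors used here, not meant for high-dimensional designs.
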