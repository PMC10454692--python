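# Methods

## Pipeline overview

`platefit` analyzes microplate OD600 growth assays in five stages:

1. **Parsing** (`platefit.io`) — plate-reader exports in wide
   (`time` + one column per well) or long (`well,time,od`) delimited text;
   a separate layout config maps wells to (strain, condition, experiment,
   replicate, blank flag). Time is converted to hours with t = 0 at the
   first reading; growth rates are conventionally per hour and the
   derivative threshold below needs a fixed unit.
2. **Validation** (`validate_run`) — advisory flags only: first reading of
   an inoculated well ≥ 0.2 OD600, total span < 15 h, median cadence
   deviating from 20 min by more than 10%, series shorter than 10 points.
   Deviations warn rather than exclude, because exclusion rules are a
   judgment call for the experimenter (the design convention is to rerun
   failed experiments, not to drop wells post hoc).
3. **Blank correction** (`platefit.preprocess`) — per medium and experiment,
   blank wells are averaged pointwise; each inoculated curve has the blank
   reference subtracted at every time point and then its own minimum
   subtracted. The order is fixed (blank first, then minimum): the two
   operations do not commute when blanks drift in time. Values below the
   blank are kept (no clipping) so the minimum subtraction stays unbiased.
   The minimum is per curve, so every corrected curve starts its fit at
   exactly zero.
4. **Growth modelling** (`platefit.growth`) — logistic fit and the
   (OD_max, r_max, AUC) triple, below.
5. **Contrasts** (`platefit.contrasts`) — blocked ANOVA and Tukey pairwise
   comparisons per strain and metric, below.

## Logistic model and derived parameters

The fitted model is `N(t) = K/(1 + A e^{−rt})` with `A = (K − N0)/N0`,
`K, N0, r > 0`. Fitting is nonlinear least squares with a variable-projection
parameterization: for fixed (A, r) the optimal K is the linear-regression
closed form `K = (y·g)/(g·g)` with `g = 1/(1 + A e^{−rt})`, so the optimizer
runs over (log A, log r) only. This removes the ill-conditioned valley that
joint (K, A, r) optimization exhibits for curves still far from plateau at
the end of observation (noiseless worst-case recovery across
K ∈ [0.2, 1.5] × r ∈ [0.1, 2] × N0 ∈ [0.005, 0.05] improves from ~2·10⁻¹ to
~4·10⁻¹² relative). Starting values: K ← max(y), N0 ← max(first value,
10⁻³), r ← log-linear slope over the steeper half of the series. If the
optimizer reports failure, up to three restarts from log-normally perturbed
initials (seeded) are tried before a fit error is raised.

Derived parameters, all in closed form:

- `r_max = rK/4` — the maximum of the derivative `rN(1 − N/K)`, attained at
  `N = K/2` (time `ln(A)/r`, which may fall outside the observation window).
- Exponential-phase window: solve `rN(1 − N/K) = c` to get
  `N± = (K/2)(1 ± √(1 − 4c/(rK)))`, map to times by
  `t(N) = ln(AN/(K − N))/r`, intersect with the observation interval
  [0, t_end]. The window is empty when `rK/4 ≤ c`. Unclipped endpoints are
  retained in the window record. Default threshold `c = 0.005` OD600 per
  hour, exposed as a config/CLI parameter: the constant needs a time unit,
  hours is the convention used throughout this package, and the choice is
  documented rather than silent.
- `AUC = F(t_hi) − F(t_lo)` with `F(t) = (K/r)·ln(e^{rt} + A)`, evaluated
  via `logaddexp` for stability; an empty or fully clipped window gives 0.

**No-growth handling.** Curves whose corrected maximum never exceeds a floor
(default 0.02 OD600) are not fitted — a logistic fitted to pure noise yields
meaningless (K, r). They report (od_max = observed max, r_max = 0, auc = 0).
Curves essentially at plateau from the first reading (fitted N0 > 0.9 K) are
flagged `r-unidentifiable`: K is pinned by the data but r is not.

**OD_max convention.** OD_max is the fitted asymptote K, not the maximum
observed value; the observed maximum is reported alongside
(`od_obs_max`) for transparency.

## Blocked ANOVA and Tukey contrasts

Each replicate well contributes one observation (the default; a helper can
pre-average replicates per experiment instead). Per strain and metric the
model is additive fixed effects, `value = μ + condition_i + block_j + ε`,
with the experiment as block — three experiments is too few to estimate a
random-effect variance usefully, and blocking is the standard design here.
The design matrix uses reference or sum-to-zero coding (switchable; marginal
means and contrasts are coding-invariant, which the tests verify to 1e-10).
`σ² = RSS/df` with `df = N − k − b + 1`.

Marginal means are model predictions per condition averaged over block
levels with equal weight; in a balanced design they equal raw condition
means, and with missing cells (a failed well) they remain the model-based
means rather than dropping whole blocks. A design where a condition cannot
be separated from the blocks raises a design error.

Tukey's HSD: for each pair, the interval half-width is
`q(1−α; k, df)/√2 · SE(diff)` and the adjusted p-value is
`P(Q ≥ √2·|t|)` under the studentized-range distribution with (k, df)
(scipy's `studentized_range`, which evaluates the CDF numerically and
root-finds for quantiles; quantiles are cached per (α, k, df)). With k = 2
this reduces exactly to the unadjusted t-interval. Significance
(p_adj < α) and "the CI excludes zero" are dual by construction. Residual
diagnostics (Shapiro–Wilk, median-centred Levene across conditions) are
advisory and never gate the analysis. No correction is applied across
strains or metrics; the Tukey family is the set of condition pairs within
one model.

Report orientation: Δc rows are (prebiotic − control); the Δi-x row is
(inulin − XOS), positive when growth on inulin is greater; when a glucose
control is present, (condition − glucose) rows quantify how much observed
growth plain monosaccharide could explain.

## Synthetic data generator

No public raw dataset accompanies this kind of assay, so
`platefit.simulate` generates complete plate runs with known truth. Defaults
mirror the assay design: 3 experiments × 3 replicates per condition,
3 blanks per medium per experiment, 20-min cadence, 16 h duration, inoculum
N0 = 0.01 (< 0.2 as the protocol requires). Signal model per inoculated
well:

```
OD(t) = blank_level + blank_drift·t + logistic(K_w, r_w, N0) + N(0, noise_sd²)
```

with `blank_level = 0.09` (typical medium turbidity), `blank_drift = 0.002`
OD/h, and `noise_sd = 0.01` — small relative to typical OD_max of 0.3–0.9,
which matches plate-reader noise being approximately additive at low OD.
Experiment-level multipliers on K and r are log-normal with scale
`block_sd = 0.05`, shared by all wells of an experiment: inter-experiment
variation in inoculum and medium acts multiplicatively. This is a simulator
choice, not an empirical claim. Lag phases are not simulated; the logistic
has no lag term.

Ground-truth metrics per condition are computed by *independent numerics* —
finite-difference slope maximized by bounded scalar search, window endpoints
by bisection, AUC by adaptive quadrature, on an algebraically different
logistic form — so they can oracle the closed forms in `platefit.growth`
(agreement ≤ 1e-6 relative is tested).

Presets (`preset_scenarios`) encode qualitative response archetypes:
`responder-both` (both prebiotics raise K and r; includes a glucose
control), `xos-slow-but-high` (XOS halves r, raises K), `non-responder`
(global null), `inulin-preferrer` (inulin above XOS in all parameters). All
effect sizes are synthetic authors' choices for testing, not estimates of
any real strain.

**What the generator does not emulate:** diauxic shifts and lag phases,
substrate depletion kinetics, pH- or gas-driven artefacts, spatial plate
effects (edge evaporation), heteroscedastic noise at high OD, or condensation
spikes. Passing tests therefore demonstrate correctness of the estimation
and inference machinery under the design's statistical assumptions, not
robustness to every real-world artefact.

## Numerical notes and known limitations

- **Minimum-withdrawal shift.** Subtracting the per-curve minimum shifts a
  noiseless trajectory by N0, and `logistic − N0` is not itself a logistic;
  the refitted K therefore carries an O(N0) bias (measured 0.001–0.018 OD600
  for N0 = 0.01 depending on r). This is inherent to the correction
  procedure, which is standard for this assay; condition *differences*
  cancel most of it. End-to-end noiseless tests assert recovery at this
  shift scale (|ΔK| ≤ 2·N0 per well), while the fit stage in isolation is
  tested at 1e-4 relative.
- **Determinism.** All stochastic components (noise, block multipliers,
  optimizer restarts) derive from explicit integer seeds; identical config
  and seed reproduce byte-identical output tables.
- **Degenerate inputs.** All-zero or below-floor curves → no-growth metrics;
  constant residuals → flagged diagnostics, not errors; time-grid
  mismatches, missing blanks, singular designs and unknown condition labels
  raise typed exceptions naming the offending well/medium/condition.
- **Problem sizes.** The simulation-based checks use 2000 null datasets for
  family-wise error calibration, 200 runs per preset for power/sign
  recovery in the test suite (150/100 in the acceptance script), and 100
  noisy curves for recovery medians — sizes at which the binomial
  uncertainty of the estimated rates is comfortably inside the asserted
  bands.
- **Shared-blank correlation.** Because one averaged blank reference is
  subtracted from every replicate of a (medium, experiment) cell, its noise
  is shared by those replicates, inducing a small positive within-cell
  correlation that the independence assumption of the ANOVA ignores. Under
  the global-null preset this raises the realized any-pair family-wise rate
  to ~0.11 (any-Δc ~0.08) versus the 0.05 nominal / ~0.056 realized under
  an uncorrelated Gaussian null. This is a property of the blank-averaging
  design itself, not of the implementation; with more blank wells per
  medium (or noise-free blanks) the inflation vanishes.
- The package fits only the standard logistic (no Gompertz/Baranyi/Richards
  alternatives) and reports no model-free empirical AUC as a headline
  metric; both are deliberate scope limits.
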