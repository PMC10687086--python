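# Methods

## Model

lucikin analyses luciferase assays in which an injection of luciferin into
an enzyme solution produces a luminescence transient that is monitored to
complete substrate conversion.  The catalytic cycle is single-substrate
Michaelis–Menten catalysis extended by two dead-end equilibria:

```
E + S  <->  ES  ->  E + P        binding k1 / k_off, turnover k_cat
E + P  <->  EP                   product rebinding, K_p = k_off,P / k_on,P
ES + S <->  ESS                  substrate inhibition, K_s = k_off,S / k_on,S
```

Under the quasi-steady-state approximation (QSSA) the product-formation
rate is

```
v = k_cat · E0 · S / ( K_m·(1 + P/K_p) + S·(1 + S/K_s) )
```

with `K_m = (k_off + k_cat)/k1`.  Product rebinding (finite K_p) is
competitive and produces the characteristic flash-type decay of
coelenterazine luminescence; the ESS complex (finite K_s) is uncompetitive
substrate inhibition with a rate optimum at `S* = sqrt(K_m·K_s)`.  Both
constants accept `inf` as an explicit "pathway off" sentinel, and the
`KineticScheme` enumeration selects which pathways a fit or simulation may
use (`mm_basic`, `mm_prod_inhib`, `mm_prod_subs_inhib`, `mass_action`).
The true reaction topology of low-activity mutants is not established;
the scheme variants span the plausible alternatives rather than asserting
one.

Assumptions: total enzyme is constant (no inactivation over the ≤1000 s
assay; an experiment showing negligible luminescence on re-injection of
fresh enzyme supports treating depletion as substrate-side only), catalysis
is irreversible, temperature is constant and carried only as metadata, and
the solution is well mixed from the instant of injection.

Units are fixed package-wide: µM for concentrations, seconds for time,
RLU (relative light units) for intensity.  Converters live only at the I/O
boundary.

## Forward simulation

`integrate_progress` solves `dP/dt = v(S0−P, P)` with scipy's LSODA at
`rtol = 1e-8`, `atol = 1e-10 µM`; dense output is evaluated exactly at the
requested read times.  `simulate_mass_action` integrates the six-species
network; `derive_micro_rates` maps macroscopic constants to microscopic
ones using one shared association rate `k1` (default 100 µM⁻¹s⁻¹, the only
freedom the macroscopic constants leave), with `k_off = k1·K_m − k_cat`
(feasible only for `k1 > k_cat/K_m`) and EP/ESS off-rates `k1·K_p`,
`k1·K_s`.  Enzyme conservation `E+ES+ESS+EP = E0` and substrate
conservation `S+ES+2·ESS+EP+P = S0` are asserted at every output point to
1e-6 relative.

The mass-action `product` series is **total product formed** (free P plus
enzyme-bound EP).  Each turnover emits one photon, so this is the
luminescence-relevant quantity; it is nondecreasing by construction
(`d(P+EP)/dt = k_cat·ES`) and converges to the QSSA curve as binding gets
fast.  Free P alone carries a k1-independent deficit of order E0 (product
sequestered in EP) and is reported in the species map instead.

## Signal model

Plate readers integrate photons over each read window, so intensity is the
average product-formation rate over the interval,
`I_i = f·(P(t_i)−P(t_{i−1}))/Δt`, with `f` the scaling factor in RLU·s/µM.
Accumulating `I·Δt` telescopes back to `f·P(t)`: the cumulative
("conversion") curve is proportional to product concentration, which is
what lets full progress-curve kinetics run in relative units without
absolute photon-yield calibration.  A complete-conversion curve pins the
scaling factor down as `f = plateau / S0`; `calibrate_scaling` refuses
curves whose final signal rate is still above 0.5% of the maximal rate
unless explicitly overridden.

Baseline handling: the 10 s pre-injection segment defines the background as
its median; it is subtracted before all transforms and negative
post-subtraction intensities are clipped at zero with a logged count.
Specific activity is the mean background-corrected intensity over the
first 15 s after injection divided by the molar enzyme concentration
(RLU·s⁻¹·M⁻¹); a flag marks traces whose intensity drifts more than 2%
across that window.  The 15-s *mean* (rather than the first read) is a
deliberate choice — it is lower-variance and matches the monitoring span of
the activity assay — and is recorded in output metadata.

## Synthetic data

The generator emulates an injection-triggered luminometer run: baseline
reads for 10 s at the background level (default 100 RLU), injection, then
sampling at a fixed read interval until the 5-point-moving-median smoothed,
background-free signal drops below 0.5% of its running maximum, or until
the 1000 s cap.  The smoothing window exists solely to keep measurement
noise from triggering the stop early.

Defaults are the study conditions: substrate series at
{0.25, 0.5, 1, 2, 4}×K_m, three replicates, E0 = 0.01 µM, noise that is
Gaussian proportional (CV 2%) plus additive (5 RLU) on intensity with the
generating sigma recorded per point, and scaling factor 1e6 RLU·s/µM.
The read interval defaults to 0.5 s, chosen to resolve the fastest
(furimazine, k_cat ≈ 8 s⁻¹) transients; instrument read interval and
background level are not documented for the original assays, so both are
declared in trace metadata.  Ground-truth K_s defaults to ∞ (no substrate
inhibition) because no K_s values are published; a finite-K_s preset
(20 µM) exercises the ESS pathway in tests.  A ±5% uniform concentration
jitter is available (`jitter_concentrations`, `jitter_fraction`) but is off
by default so that recovery benchmarks run under the exact nominal
concentrations the fits assume.

What passing tests on these data do *not* show: robustness to injector
mixing artifacts, detector saturation or drift, well-to-well crosstalk,
photobleaching, or non-Gaussian noise — none of which are modelled.

## Two-stage estimation

Stage 1 (`initial_rate`): initial velocity is the least-squares slope of
the cumulative curve over the first 15 s (integrating the noise rather than
trusting the first read), and `v0(S0)` is fitted to
`Vmax·S/(K_m + S + S²/K_s)` by weighted (1/se², unweighted fallback)
log-space least squares with multistart.  When caller-supplied sigmas are
present the covariance is not rescaled by reduced chi² (noise scale
known); otherwise it is.  A K_s running into its bound (1e4·max S0) is
reported as "no detectable substrate inhibition" and the reduced model is
returned.  Stage 1 exists to lay out the 0.25–4×K_m series and to seed
stage 2.

Stage 2 (`global_fit`): all curves of an enzyme–luciferin study are fitted
simultaneously to `C(t) = f·P(t; k_cat, K_m, K_p[, K_s], S0·c, E0)` with
sigma-normalized residuals.  Kinetic parameters and scaling factors are
log-parameterized (positivity for free, spans the three-decade range of
published constants); per-curve concentration corrections `c` are linear
parameters hard-bounded to [0.95, 1.05] (enzyme-side corrections share the
bound and are off by default).  Optimization is scipy `least_squares`
(trf, bounds, `x_scale='jac'`), best of `multistart_n` (default 8) seeded
log-uniform ×/÷3 perturbed starts; ties break on chi², then on parameter
norm.  Standard errors come from the Jacobian at the optimum scaled by
reduced chi².  Per-point sigma is mandatory — a dataset without it is
refused rather than silently unweighted.  For synthetic data sigma is the
generating noise SD (so normalized residuals are unit-scaled under the
truth); for real CSVs lacking a sigma column, replicate scatter must be
supplied instead.

Observable: the default is the cumulative conversion curve, which matches
how the assays are analysed and anchors the scaling factor in the
conversion plateau.  Note that with white noise on intensity the cumulative
residuals are serially correlated (running sums of the same draws), so
chi²-based uncertainty statements from the cumulative objective are
optimistic.  The `intensity` observable is the same data decorrelated
(first differences); the confidence-region calibration benchmarks use it,
and it is the right mode whenever calibrated frequentist coverage matters.

When no analytical curve reaches completion inside the cap (slow
enzyme–luciferin pairs), the pipeline fixes the scaling factor from an
excess-enzyme calibration well instead of fitting it — mirroring the
experimental calibration protocol.  With all curves truncated below ~50%
conversion and no calibration, the scaling factor is weakly identified and
its standard error inflates accordingly (this is a documented failure mode,
demonstrated in the test suite, not an error).

## Derived quantities and identifiability

Specificity constants `k_cat/K_m` and fold changes between variants
propagate errors to first order assuming independence,
`se(x/y) = (x/y)·sqrt(cv_x² + cv_y²)`; a Monte-Carlo cross-check agrees
within 5% for the CV ≤ 10% regime of the published values.  Recomputing the
published table's ratios flags one row (the triple mutant with
coelenterazine) whose printed ratio disagrees with its printed numerator
and denominator beyond printing precision; the package reports computed
ratios and the flag rather than reproducing that printed value.

Confidence contours profile the chi² objective over a parameter pair on a
log-spaced grid (default 41×41, ×/÷10 around the estimate), re-optimizing
*all* remaining parameters — including scaling factors and concentration
corrections — at every node, with warm starts walked outward from the best
fit; nodes whose re-optimization fails are flagged NaN, never interpolated.
The default boundary is the classical profile rule
`chi²_min + q·s²·F_{q, n−p}(0.95)` with `q = 2` profiled parameters and
`s² = chi²_min/(n−p)`, which gives ~95% joint coverage of the pair; the
all-parameter rule (`ftest_all`, the joint-region convention of
FitSpace-style maps, conservative for a pair) and a chi²-quantile rule are
available by configuration.

## Benchmark problem sizes

The recovery and calibration benchmarks run at deliberately modest sizes:
noiseless recovery uses one replicate per concentration (replication adds
nothing without noise) at a 0.5 s read interval; the noisy-recovery study
uses the wild-type/coelenterazine generator at a 2 s read interval with
3 replicates over 100 seeds (60 in the acceptance script); coverage uses
the wild-type/furimazine generator (fast, so each refit is cheap) over
100 seeds (60 in the script).  The tested claims are per-study medians and
coverage counts, which are stable at these sizes.

## Known limitations

- No enzyme-inactivation term (the hook exists but defaults to zero);
  assays longer than ~1000 s with labile enzymes would violate this.
- The QSSA observable assumes E0 well below S0 + K_m; the mass-action
  simulator is the reference when that is doubtful.
- Ratio SEs assume independent numerator and denominator; for strongly
  correlated pairs use the contour machinery instead.
- Emission spectra, quantum-yield photophysics, multi-enzyme mixtures and
  temperature dependence are out of scope.
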