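# Methods

## The reaction model

Colistimethate (CMS), the sulfomethylated prodrug of the antibiotic colistin
(CS), converts to CS under acid catalysis. Over a single hydrolysis run the
system is treated as a closed two-species pool with first-order kinetics in
both directions:

    dA/dt = -k_f A + k_r (c0 - A),    A(0) = c0,

where `A` is the percent of prodrug remaining (c0 = 100 at the normalisation
point), `k_f` (min⁻¹) the forward hydrolysis rate and `k_r` (min⁻¹) a small
reverse rate. The exact solution is

    A(t) = A_eq + (c0 - A_eq) exp(-(k_f + k_r) t),
    A_eq = c0 k_r / (k_f + k_r),

i.e. exponential relaxation at the observed rate `k_f + k_r` toward the
equilibrium floor `A_eq`. The converted species is tracked implicitly as
`c0 - A`; mass is conserved by construction. Setting `k_r = 0` recovers
pure first-order decay `A = c0 exp(-k_f t)`.

Two trajectory routes exist deliberately: the closed form is the reference,
and a numerical integrator (`scipy.integrate.solve_ivp`, LSODA,
rtol 1e-11 / atol 1e-12) provides an independent path that is required to
agree with the closed form to 1e-8 relative on any grid. The ODE route keeps
the architecture open to multi-step schemes the closed form cannot cover.

## Rate-constant estimation

**Early-window log-linear fit.** During the first minutes nothing has
converted, the reverse flux is negligible and `ln A(t)` is effectively
linear: `ln A = ln c0 - k t`. We fit ordinary least squares of `ln(value)`
on time over a window (default 10 min, at least 3 points, all values
positive) and report `k = -slope`, the intercept (an estimate of
`ln(initial %)` — 4.605 for a 100 % start) and R². A mathematical note: the
initial log-slope of the reversible trajectory is exactly `-k_f`
(d ln A/dt|₀ = -(k_f + k_r)(1 - A_eq/c0) = -k_f), so a shrinking window
estimates the forward rate, not the observed sum; the property suite checks
this limit at the smallest window the sampling grid supports (4 min,
3 points, 1 % tolerance).

**Full-course reversible fit.** Over the whole run we minimise the
unweighted sum of squares on the percent scale,

    SSE(k_f, k_r) = Σᵢ (yᵢ - A(tᵢ; k_f, k_r))²,

with a trust-region reflective solver (`scipy.optimize.least_squares`),
bounds `k_f > 0`, `k_r ≥ 0`, and convergence tolerance 1e-8 on the relative
SSE change. Fitting on the concentration scale (not log) mirrors
trajectory-matching kinetics simulators and weights the information-rich
early points naturally; the log scale is reserved for the early-window
method. No weighting scheme is applied: percent-remaining values share one
measurement scale and the noise model below is close to homoscedastic over
the fitted range.

Initialisation (when none is supplied): `k_f` from the early-window fit and
`k_r` from the last observed value read as the equilibrium plateau
(`k_r = k_f · f/(1-f)` with `f = y_last/100`). Convergence is verified to be
initialisation-independent (1e-6 relative over a 10-point random init grid).

Uncertainties come from the Gauss–Newton covariance `(JᵀJ)⁻¹ · SSE/(n-2)`.
When the optimum pins `k_r` at its physical bound of zero the Wald
covariance is meaningless for that parameter and is reported as undefined
(NaN) rather than as a spuriously tight number — this matters for runs
truncated near the half-life, where the plateau (hence `k_r`) is weakly
identified.

## Arrhenius analysis

Rate constants across temperature follow `ln k = ln A - Ea/(R T)` with
R = 8.314 J mol⁻¹ K⁻¹ and T in kelvin (K = °C + 273.15). We regress `ln k`
on `1/T` by unweighted OLS — with three points any weighting is moot —
giving `Ea = -slope · R` and `lnA = intercept`. Predictions
`k(T) = exp(lnA - Ea/(RT))` are allowed outside the fitted range but carry
an extrapolation flag, since shelf-life estimation is precisely an
extrapolation from accelerated conditions (40–60 °C) down to ambient.

Half-life uses the conventional rounded constant, `t½ = 0.693/k`, so that
published half-life tables computed that way are reproduced digit for
digit; `exact=True` switches to ln 2. The verification error between an
observed out-of-range rate constant and the Arrhenius prediction is
`%E = (k_obs - k_pred)/k_pred`, reported as a fraction; this convention
(rather than normalising by the observed value) is the one under which the
reference study's printed verification number is recovered, and the
comparison is made against the prediction at tabulated precision (4 d.p.)
because that is how such verification tables are assembled.

Time to a target completeness inverts the closed form:
`t = ln((100 - A_eq)/(target - A_eq))/(k_f + k_r)`; targets at or below the
equilibrium floor are unreachable and raise.

## Quantitation statistics

Calibration curves are least-squares polynomials — linear for colistin A
and B, quadratic for the heterogeneous CMS peak — with coefficient standard
errors from the fit covariance and R². Replicate runs are compared with the
extra sum-of-squares F test: the null model shares all coefficients across
runs, the alternative fits each run separately, and

    F = ((SS_pooled - SS_separate)/(df_pooled - df_separate))
        / (SS_separate/df_separate),

with p from the F distribution; p > 0.05 accepts the pooled curve. Identical
duplicated data give F = 0, p = 1 without dividing by zero.

Detection limits follow the σ/slope convention: LOD = 3.3 σ/S,
LOQ = 10 σ/S, so LOQ/LOD = 10/3.3 identically. σ defaults to the response
standard deviation of the lowest-level replicates; the regression residual
SD is selectable. For the quadratic CMS curve, limits are computed from an
OLS line over the lowest three levels (the curve's effectively linear part),
and that choice is configurable.

Quantitation inverts the fitted curve: algebraically for lines, and for
quadratics by selecting the unique real root inside the calibrated
concentration range (unique because the curve is monotone there); zero or
two in-range roots raise an ambiguity error rather than guessing.

The reference standard's fixed colistin A : B mass split (30.1 : 69.9) maps
total-colistin amounts to per-form amounts with exact mass conservation.
Circulating prodrug is determined indirectly as
`CMS = CS_total − CS_before hydrolysis`; a caveat flag is attached when the
hydrolysis protocol is marked sub-complete, since the difference then
underestimates CMS. Accuracy is the worst absolute percent deviation of a
run mean from nominal (reported as a bound, hence the absolute value);
repeatability is the worst within-run %RSD; intermediate precision is the
%RSD of run means. A single replicate leaves precision undefined (reported
missing, never zero).

## Synthetic data

The generator reproduces the study design: accelerated runs at 40/50/60 °C
plus a 20 °C verification run, sampled every 2 min to 10 min and then every
10 min to 130 min (18 points). Forward rates derive from a generating
Arrhenius law — by default the (Ea, lnA) implied by regressing the three
reference rate constants (0.0146, 0.0709, 0.4485 min⁻¹), so noiseless
generation followed by fitting is an exact round trip. Reverse rates are
per-temperature constants (2.2e-3, 3.54e-3, 2.11e-3 min⁻¹), reflecting
their lack of a temperature trend.

Noise on percent-remaining values is multiplicative Gaussian with a 2 %
coefficient of variation: LC-MS peak-area noise scales with signal, and 2 %
sits in the %RSD band of the validated assay. The t = 0 point is anchored at
exactly 100 (it is the normalisation point and carries no noise); draws that
would go negative are truncated at zero. Calibration responses add Gaussian
noise (SD 20/60/30 response units for CSA/CSB/CMS, a few percent of the
mid-range response). Every stream is seeded deterministically per
(seed, temperature) or (seed, analyte), so distinct series are independent
and everything is bit-reproducible under one study seed.

What the generator does not emulate — chromatographic peak shapes, matrix
effects, drift between analytical days, the heterogeneous speciation of CMS
itself — bounds what passing tests demonstrate: they validate the
estimators against the assumed reversible/Arrhenius model and noise
structure, not against instrument systematics.

## Numerical choices and edge cases

* Degenerate scheme (`k_f + k_r = 0`) and negative times/amounts raise.
* Series must be strictly increasing in time and non-negative; file readers
  sort out-of-order rows with a warning and name the offending line on
  parse errors.
* A non-decreasing series triggers a model-mismatch warning but the fit
  still runs (the diagnostics then speak for themselves).
* Monte-Carlo guarantees in the test suite (F-test null acceptance ≥ 90 %
  of 200 simulations; forward-rate recovery within 5 % in ≥ 95 % of 200
  seeded 2 %-noise runs; coefficient SEs within 20 % of the sampling SD
  over 500 curves) were established by running the simulations at those
  sizes; the whole suite runs in a few seconds.

## Known limitations

* Only the 0.5 M sulfuric-acid condition is modelled; acid-concentration
  dependence of the rates is out of scope.
* CMS is treated as a single species; its component speciation is not
  modelled.
* Temperatures far outside 20–60 °C rely on the Arrhenius extrapolation
  holding, which the package flags but cannot verify.
* Runs truncated at the half-life leave `k_r` weakly identified; the
  undefined-covariance report is the honest output, not a failure.
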