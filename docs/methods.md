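# Methods

## Kinetic models

The core assumption set is the standard one for competition association
experiments: a single population of non-interacting receptor sites; two
ligands binding mutually exclusively by mass action; both ligands in large
excess over receptor so free concentrations are constant (no depletion);
simultaneous addition to unoccupied receptor at t = 0; and a measured
signal proportional to tracer occupancy after nonspecific-binding
subtraction. Under these assumptions the coupled system

    dRL/dt = k1[L](N − RL − RI) − k2·RL
    dRI/dt = k3[I](N − RL − RI) − k4·RI

has the bi-exponential Motulsky–Mahan solution implemented in
`bindkin.models.motulsky_mahan_occupancy`, with observed eigen-rates
`K_F ≥ K_S` returned by `eigen_rates`. The same mass-action system,
integrated numerically (`ode_occupancy`, LSODA at rtol 1e-10), serves as
an independent oracle in the tests; agreement is checked to 1e-5 relative
over 200 random parameter draws with rates log-uniform over
[1e-2, 1e1] min⁻¹ (dissociation) and [1e5, 1e9] M⁻¹min⁻¹ (association),
concentrations log-uniform over [1e-10, 1e-5] M.

**Repeated root.** The printed closed form is singular at K_F = K_S.
When |K_F − K_S|/K_F < 1e-9 the implementation switches to the analytic
limit (L'Hôpital in K_S → K_F = K):

    [RL]_t = N[L]k1 · { k4/K² − e^{−Kt}[ k4/K² + t(k4−K)/K ] }

The switch threshold sits far above double-precision cancellation noise
and far below any physically distinguishable eigenvalue splitting; the
test suite checks continuity across the switch.

**Rapid-competitor limit.** When k4 → ∞ at fixed K_I = k4/k3 the full
model converges to the mono-exponential rapid-equilibration form; the
maximal relative deviation falls roughly one decade per decade of k4
(≈1% at k4 = 10³ min⁻¹ for a tracer with k2 ≈ 0.44 min⁻¹). Only K_I is
identifiable in this regime — fitting the full model to such data drives
k4 to a bound or inflates its standard error, which is exactly the
failure mode the model-selection workflow is designed to catch.

**Overshoot.** With k4 < k2 (competitor leaves the receptor more slowly
than the tracer) the trace at intermediate [I] rises to an interior
maximum and relaxes down as the slow competitor progressively occupies
receptor; the rapid model, being mono-exponential, can never overshoot.
The tests assert overshoot appears exactly when k4 < k2 across a sweep.

Units are molar and minutes everywhere in the core; conversions (nM/µM
suffixes) happen only at the CLI boundary. N (B_max) is in arbitrary
signal units on the plate-reader scale.

## Fitting

Two-step estimation mirrors practice: tracer kinetics (k1, k2, N) are
determined first from competitor-free association traces at ≥ 3 tracer
concentrations (globally shared parameters), then held fixed while
competition traces at ≥ 2 non-zero competitor concentrations are fitted
globally for (k3, k4, N) — full model — or (K_I, N) — rapid model. N is
shared across curves by default. The tracer fit also reports the
classical linearisation (per-trace k_obs regressed on [L]: slope k1,
intercept k2) as a cross-check.

All rate/affinity parameters are optimised as log10 values, making
positivity structural; `scipy.optimize.least_squares` (TRF) runs from 5
log-spaced starts (perturbations of a data-derived guess) and the lowest
SSR wins. Least squares is unweighted (plate noise on a ratiometric
signal is approximately homoscedastic). Standard errors come from the
Gauss–Newton covariance s²(JᵀJ)⁻¹ at the optimum, delta-mapped back to
the linear scale. A fit is flagged *ambiguous* when a log-scale standard
error dwarfs its estimate (>10×), an estimate sits within 1% of the
log-box bound (±12), or the optimiser fails; a fitted k4 > 1 min⁻¹
additionally flags unresolvable dissociation.

**Model selection.** The rapid model (2 parameters) is the null; the
full model (3) is the alternative. The extra-sum-of-squares F-statistic

    F = ((SSR_s − SSR_c)/(dof_s − dof_c)) / (SSR_c/dof_c)

is referred to F(df_num, df_den); the complex model is selected iff
p < α (default α = 0.05, configurable). A negative numerator (a
multistart artefact — the simpler fit happening to edge out the richer
one) clamps F to 0.

A caveat documented here because it is easy to misread: under the null
the truth lies on the k4 → ∞ *boundary* of the full model's parameter
space, so the F-test is conservative — the large-sample rejection rate
is approximately α/2 (the likelihood-ratio statistic follows the
½χ²₀ + ½χ²₁ mixture), and the Monte-Carlo calibration in the test suite
measures ≈2–3% at a nominal 5%. The test therefore protects against
over-selecting the kinetic model; it does not attain exactly nominal
size.

## Equilibrium analyses

Concentration–response curves use the 3-parameter logistic with the Hill
slope fixed at ±1 (one-site competition justifies unit slope; a
free-slope 4PL is available as a diagnostic, not the default). Responses
are first normalised linearly to reference wells (reference_max → 100,
reference_min → 0, out-of-range values passed through unclamped so
negative lower plateaus survive). Quality flags rather than hard errors
mark flat curves, unresolved plateaus (< 1 log-unit concentration span or
logEC50 SE > 1), EC50 outside the tested range, and systematic residual
runs (Wald–Wolfowitz test at p < 0.025, applied only when residuals
exceed numerical noise) — the latter catches e.g. unit-slope fits to
steep data.

Schild analysis computes dose ratios from fitted p50s of full curves,
excludes DR ≤ 1 points with a warning, regresses log10(DR−1) on log10[B]
(slope, pA2 = −x-intercept) and re-fits with slope pinned to 1 for pKB
(pKB = mean(log10(DR−1) − log10[B])); the two coincide exactly at slope
1. Saturation binding is a two-parameter hyperbola fit; Cheng–Prusoff
inverts competition IC50s given tracer concentration and KD. Nonspecific
binding is defined per plate by dedicated saturating-competitor wells and
subtracted before kinetic fitting (`bindkin.io.subtract_nsb`).

## Stability pharmacokinetics

Half-lives come from the slope of ln(percent remaining) vs time across
all points including t = 0 (not forced through 100%); a non-negative
slope reports t½ = ∞ with a `stable` flag, and non-positive percentages
are excluded with a warning. Intrinsic clearance uses ln 2 (not the
3-s.f. constant 0.693) divided by t½ times microsomal protein
concentration (mg/µl), giving µl·min⁻¹·mg⁻¹.

## Synthetic data

The generators emulate a kinetic competition plate (closed-form traces
plus additive Gaussian noise and a constant NSB floor), sigmoidal
dose–response series (optionally Gaddum-shifted for antagonism
pipelines), and exponential depletion series. Defaults reflect the
reference assay conditions: tracer k1 = 2.86e7 M⁻¹min⁻¹,
k2 = 0.4397 min⁻¹ at 5 nM; slow competitor k3 = 3.25e8 M⁻¹min⁻¹,
k4 = 0.0248 min⁻¹; reads over 0–60 min; noise additive on the
BRET-ratio-like scale (ratiometric reads have roughly constant error; a
proportional term is available). Every generator returns a ground-truth
record so recovery tests assert against the generating values, never
re-typed constants.

What the generators deliberately do not emulate: luciferase substrate
decay, instrument drift, well-position effects, ligand depletion at high
receptor density, or outliers. Passing recovery tests therefore
demonstrate correctness of the estimators under the models' own
assumptions, not robustness to real-plate artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use compact designs chosen to keep the suite
quick while leaving every parameter identifiable: 4–5 competitor
concentrations × 10–25 time points for kinetic fits, 11–15 point
dose–response curves, 200 random draws for the ODE-oracle sweep and 500
replicates for the F-test calibration. Optimiser tolerances are 1e-12
(xtol/ftol/gtol); ODE oracle rtol 1e-10/atol 1e-14. Ties and degenerate
inputs: t = 0 always returns exactly 0 binding; clip-to-zero guards
sub-epsilon negative values from exponential cancellation; I = 0 traces
are handled by the same code path (the eigen-rate expressions reduce
smoothly).

## Known limitations

- One site, two ligands only: no allosteric or two-site schemes, no
  ligand-depletion correction, no temperature dependence.
- The F-test's boundary conservatism (above) means genuinely fast-off
  compounds are, if anything, slightly over-assigned to the rapid model —
  the safe direction, since the rapid model's K_I remains consistent.
- Standard errors are asymptotic (Gauss–Newton); no bootstrap or profile
  likelihood intervals.
- The Welch test utility operates on summary statistics of fitted
  parameters; full ANOVA/multiple-comparison machinery is out of scope.
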