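# Methods

## Structural model

Dabigatran disposition is a two-compartment mammillary model parameterised
by clearance `CL`, intercompartment clearance `Q`, central volume `V1` and
peripheral volume `V2`, with zero-order drug inputs into the central
compartment.  All four PK parameters are standardised to a 70-kg body
weight through allometric models,

    P_i = P_std * (W_i / 70)^EXP,    EXP = 0.75 (CL, Q), 1 (V1, V2),

so cohort members of different weights share one set of typical values.
An effect compartment is linked to plasma by the first-order constant
`keo`, stored on its reported scale as the equilibration half-time
`t_half_keo = ln 2 / keo`.  Thromboelastographic reaction time responds to
the effect-site concentration through a sigmoid Emax function,

    R_dabi(Ce) = E0 + Emax * Ce^N / (Ce50^N + Ce^N).

Idarucizumab reversal is empirical: each reversal dose contributes a unit
amount (the compartment is unit-normalised, so `slope_ida` absorbs scale
and no dose-proportionality is assumed) infused over `dur_ida` into a
compartment eliminated at `k_ida`; its amount lowers R-time linearly with
slope `slope_ida`.  Observed R-time is the sum of both effects, floored at
zero because reaction times are physically non-negative.  Boluses are
represented as zero-order inputs over their actual administration times
(1 min for dabigatran, 30 s for idarucizumab); a nominal duration of zero
is replaced by 10^-3 min.

Units throughout: minutes, litres, milligrams, mg/L, kg.

### Evaluation paths

The default path evaluates trajectories in closed form by superposing
unit-rate infusion step responses of the bi-exponential disposition system;
the effect site is the exact convolution of those exponentials with the
first-order keo filter, and the reversal compartment is mono-exponential.
Removable singularities (coincident eigenvalues, keo equal to a
disposition eigenvalue) are handled by relative nudges of 1 part in 10^6,
which perturbs trajectories far below the 10^-3 relative tolerance asserted
elsewhere.  `expm1` is used so slow eigenvalues do not lose precision.
A second path integrates the same equations with LSODA (rtol 1e-9,
atol 1e-11), split at input discontinuities, and carries a cumulative
elimination state; it serves as the independent oracle in tests, which
require 0.1% relative agreement and 0.1% mass balance.  The closed-form
kernels are numba-compiled because they sit inside the mixed-effects inner
loop.

## Default parameter values

Typical values: CL 0.0453 L/min/70 kg, Q 0.268 L/min/70 kg, V1 2.94 L/70
kg, V2 9.51 L/70 kg, t_half_keo 1.04 min, Ce50 64.2 mg/L, Emax 180 min.
The remaining defaults are documented package choices, configurable and
clearly not estimates:

* `E0` = 6 min — midpoint of the normal 4–8 min R-time range; `N` = 1.
* Between-subject variability: 30% CV (log-scale variance 0.09) on CL, Q,
  V1, V2, Emax and Ce50; none elsewhere.  Omegas are diagonal.
* Residual error: concentration 10% proportional + 0.1 mg/L additive;
  R-time 10% proportional + 0.5 min additive, combined as
  `y = f (1 + eps_p) + eps_a` with independent normal components.
* Idarucizumab: `k_ida` 0.1 /min, `dur_ida` 5 min, `slope_ida` 6.3534 min
  per unit.  These were chosen once, analytically, so that a reversal dose
  produces a peak R-time reduction of 5.0 min developing over ~5 min and
  washing out first-order — the magnitude and time course reported for the
  15 mg/kg dose.  No dose-response is implied.

## Synthetic cohorts

`paper_design()` reproduces the in-vivo study: five sheep (configurable),
dabigatran 4 mg/kg IV over 1 min at t = 0, idarucizumab 15 mg/kg over 30 s
at 120 min, paired concentration and R-time samples at 5, 15, 30, 60, 90,
120 min and 5, 15, 30, 60, 120, 240, 480 min and 24 h after the reversal
dose.  Subject weights are uniform on 50–80 kg — a documented stand-in, as
the study's demographic table is not available in the source text.  The
generator draws, per subject and in fixed order, weight, etas and residual
vectors from a single seeded generator, so datasets are reproducible and
byte-identical across runs.  Observations that sample negative under the
additive error are truncated at zero and flagged (`TRUNC` column) rather
than resampled; the estimation step deliberately does not model the
truncation, which keeps the error model honest but means late, near-zero
concentrations carry a small positive distortion.

What the generator does not emulate: assay quantification limits,
inter-occasion variability, covariate effects beyond weight, and any PK
interaction of idarucizumab with dabigatran concentrations (the reversal
model is purely additive on R-time).  Passing recovery tests therefore
demonstrate internal consistency of estimator and generator under the
declared model, not robustness to real-data misspecification.

## Estimation

The marginal likelihood is approximated subject-by-subject with a
Laplace-type expansion around the empirical Bayes eta.  Writing `l(eta)`
for the conditional -2 log-likelihood and `Omega` for the BSV covariance,

    -2 log L_i ~= n_i log 2pi + log|Omega| + l(eta^) + eta^' Omega^-1 eta^
                  + log|M(eta^)|,

where `M` is the curvature of the joint objective.  Method `focei` uses
the Fisher/Gauss-Newton curvature including the eta-dependence of the
residual variance (the "interaction" term) and finds `eta^` by damped
Newton steps with forward-difference Jacobians, always started from zero
so the outer objective is a pure, deterministic function of the
parameters.  Method `laplace` uses a full numeric Hessian of the joint
objective; `naive` pools all data without random effects.  Against a
60-point Gauss–Hermite evaluation of the exact marginal likelihood on a
single-subject problem, FOCEI and Laplace agree with the exact value to
better than one objective unit.

Fixed effects, BSV standard deviations and residual components are
searched on the log scale (positivity by construction, matching the
exponential eta model).  The outer optimiser is a Nelder-Mead start
followed by an L-BFGS-B polish with finite-difference gradients; objective
values are full -2 log-likelihoods, so nested fits compare directly on the
chi-square scale (3.84 at one degree of freedom for alpha = 0.05).
Standard errors come from the numeric Hessian of the objective at the
optimum (`cov = 2 H^-1`), with confidence intervals
`estimate * exp(+/- 1.96 SE_log)`.

The sequential PPPD workflow fits the population PK to concentrations
first, then fixes PK fixed effects and variances, retains the
concentration data in the likelihood (keeping PK etas informed) and
estimates E0, Emax, Ce50 and t_half_keo, with BSV on Emax and Ce50 and the
R-time residual components.  Simulation-study fits initialise at the
configured typical values, the standard convention for recovery
experiments; `heuristic_pk_initials` supplies noncompartmental starting
values (dose/AUC, dose/Cmax) for real datasets.

### Known identifiability limit

Under the study sampling schedule the first observation falls at 5 min,
roughly five equilibration half-times, so the profile likelihood of
`t_half_keo` is nearly flat between 0 and ~1 min (refitting one 20-subject
cohort with t_half_keo pinned at 0.06 vs 1.04 min changes the objective by
under 2 units).  Maximum-likelihood estimates of t_half_keo consequently
scatter widely and skew low across replicate cohorts, while the other six
reported parameters recover to within a few percent on average.  This is a
property of the design, not of the estimator, and it is the main caveat on
the equilibration half-time's recovery experiments.

## Visual predictive check

The pcVPC corrects each observation by (bin median population prediction) /
(record population prediction), bins by nominal sampling time (bins with
fewer than three observations merge into a neighbour, with a warning), and
compares observed 10/50/90th percentiles with bands formed from replicate
cohorts simulated at the observed design.  Percentiles are linear-
interpolation (type 7).  Randomness is streamed per (replicate, subject)
from the seed, making the bands invariant to dataset row order.  The
default replicate count is 1000; calibration runs in the test suite use
300–500, where a 30-cohort study put the observed-median-in-CI rate at
~96%, consistent with the nominal 95%.

## Dose design on bypass

The circuit is a third well-stirred compartment (prime volume V3, pump
flow Q3) exchanging with plasma at rate Q3 and adding no elimination;
equations are integrated in amounts, so total mass is conserved exactly.
The printed form of the circuit equation in the source material drops the
circuit-to-plasma return flow; it is implemented as Q3 (C1 - C3), which is
the only form consistent with mass balance and with the description of Q3
as pump flow.  The linear system (with an extra quadrature state for the
running integral of central amount) is propagated by matrix exponentials
per constant-rate segment, so time-averaged concentrations are exact
rather than grid-limited.  V3 = 1 L and Q3 = 2 L/min are configurable
sheep-scale defaults; the study's exact circuit values are not published,
which is why the dose-reproduction check carries a ±20% band.

`design_regimen` primes the circuit at the target, loads target x V1 per
kg over 1 min, and picks two stepped infusion rates (switch at horizon/3
by default) by bounded golden-section minimisation of the squared
deviation from target over each segment — deterministic by construction.
The plan's tolerance report is computed from its own re-simulation over a
maintenance window from 5 min to the horizon.  With the reported PK values
and a 5 mg/L target this search lands at 0.0174 and 0.0072 mg/kg/min,
alongside the published 0.0175/0.0075 regimen.

## Problem sizes used in checks

Recovery experiments use 20-subject cohorts at the study sampling times
(five replicate seeds in the acceptance script, one in the test suite);
LRT calibration uses 400 naive-pooled null replicates of a two-subject
concentration design with the intercompartment clearance as the tested
parameter; VPC self-consistency pools twenty 5-sheep cohorts at 500
replicates each.

## Limitations

* No covariate models beyond allometric weight; no inter-occasion
  variability; diagonal omega only.
* No mechanism-based idarucizumab–dabigatran binding model; reversal is
  additive and calibrated to a single dose level.
* FOCE-class approximations carry small finite-sample bias (a few percent
  at 20 subjects for this design); the package reports maximum-likelihood
  style estimates, not bias-corrected ones.
* The truncation of negative simulated observations is not reflected in
  the likelihood (no censoring model).
* Hemodilution and temperature effects on PK/PD during bypass are out of
  scope; circuit parameters enter only through V3 and Q3.
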