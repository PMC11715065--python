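"""Small parameter-recovery experiment.

Simulates a 10-sheep cohort from the default population model (reported
typical values, 30% between-subject CV, combined residual error), then
re-estimates the model by FOCEI (PK stage) and the sequential PPPD scheme
(PD stage).  Prints estimate vs generating value for each parameter.
"""

import dabipkpd as dp

pop = dp.default_population()
truth = pop.parameter_values()

dataset = dp.generate_cohort(pop, dp.paper_design(n_subjects=10, seed=42))
fit = dp.fit_sequential_pppd(dataset, pop)

print(f"objective (stage 2, -2LL): {fit.objective:.1f}")
print(f"{'parameter':>12} {'estimate':>10} {'truth':>10} {'error':>8}")
for name in ("CL", "Q", "V1", "V2", "Ce50", "Emax", "E0", "t_half_keo"):
    est = fit.estimates[name]
    print(f"{name:>12} {est:10.4g} {truth[name]:10.4g} "
          f"{100 * (est / truth[name] - 1):+7.1f}%")

print()
print("With 10 rich-sampled subjects the fixed effects typically come back")
print("within ~10-20% of the generating values; variability terms need")
print("larger cohorts.  Stage 1 objective:",
      f"{fit.stages['pk'].objective:.1f}")
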