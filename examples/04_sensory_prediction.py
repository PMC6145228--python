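"""Predict sensory texture from instrumental attributes.

Two routes: evaluate the published per-treatment equations verbatim,
or re-derive an equation by two-phase forward stepwise regression
(main effects first, then squares and cross products of the
survivors).
"""

from tpafish import (
    aggregate_fish, builtin_equation, default_cohort_spec, predict,
    residualize_table, simulate_cohort, stepwise_fit,
)

# published fresh-frozen equation: flaky = 7.533 - 0.0124 * hardness-1,
# evaluated at the published fresh-frozen hardness mean of 220.51 N
eq = builtin_equation("fresh_frozen", "flaky")
score = predict(eq, {"hardness_1": 220.51})
print(f"published equation predicts flaky = {score:.3f} at the group-mean "
      "hardness (published sensory group mean: 4.79)\n")

# stepwise refit on a synthetic cohort
cohort = simulate_cohort(default_cohort_spec(seed=7))
fish = aggregate_fish(cohort.tpa, cohort.sensory)
fish = residualize_table(fish, mode="fixed")
ff = fish[fish.treatment == "fresh_frozen"]

candidates = ["hardness_1", "hardness_1b", "hardness_2", "cohesiveness",
              "springiness", "resilience", "adhesiveness", "thickness_1",
              "thickness_2", "residual_chewiness_1"]
fitted, report = stepwise_fit(ff, "firmness", candidates,
                              group="fresh_frozen")
terms = ", ".join(f"{t.coef:+.4g}*{t.name}" for t in fitted.terms)
print(f"stepwise fit for sensory firmness (n={report.n} fish): "
      f"{fitted.intercept:.3g} {terms}")
print(f"RMSE {report.rmse:.3f}, R^2 {report.r_squared:.3f}, "
      f"adj R^2 {report.adj_r_squared:.3f}, R {report.r:.3f}")
print("entry p-values:", {k: round(v, 4) for k, v in report.entry_p.items()})
print("\nthe generator links firmness to hardness-1, so hardness-type "
      "attributes should dominate the selected terms.")
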