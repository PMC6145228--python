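"""Published equations, prediction, fit statistics, stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from tpafish import (
    PredictionEquation, Term, builtin_equation, builtin_equations, evaluate,
    predict, stepwise_fit,
)


class TestBuiltinEquations:
    def test_fresh_frozen_flaky_is_single_hardness_term(self):
        eq = builtin_equation("fresh_frozen", "flaky")
        assert eq.intercept == 7.533
        assert len(eq.terms) == 1
        assert eq.terms[0].attributes == ("hardness_1",)
        assert eq.terms[0].coef == -0.0124

    def test_iqf_moisture_retention_has_no_model(self):
        assert builtin_equation("iqf", "moisture_retention") is None

    def test_ff_moisture_retention_terms(self):
        eq = builtin_equation("fresh_frozen", "moisture_retention")
        assert len(eq.terms) == 5
        assert set(eq.predictors) == {"thickness_2", "residual_hardness_1b"}

    def test_group_counts_and_aliases(self):
        ff = builtin_equations("FF")
        iqf = builtin_equations("IQF")
        assert len(ff) == 10 and all(eq is not None for eq in ff.values())
        assert len(iqf) == 10
        assert sum(eq is None for eq in iqf.values()) == 1
        with pytest.raises(ValueError):
            builtin_equations("thawed")


class TestPredict:
    def test_ff_flaky_at_group_mean_hardness(self):
        # OLS mean identity: the single-predictor equation evaluated at
        # the group-mean hardness reproduces the group-mean sensory score
        eq = builtin_equation("fresh_frozen", "flaky")
        assert predict(eq, {"hardness_1": 220.51}) == pytest.approx(4.799,
                                                                    abs=1e-3)

    def test_iqf_residual_cohesiveness_of_mass_at_group_mean(self):
        eq = builtin_equation("iqf", "residual_cohesiveness_of_mass")
        assert predict(eq, {"residual_chewiness_1": -4.326}) \
            == pytest.approx(0.0244, abs=1e-4)

    def test_zero_input_returns_intercept(self):
        eq = builtin_equation("iqf", "fibrous")
        zeros = {a: 0.0 for a in eq.predictors}
        assert predict(eq, zeros) == pytest.approx(eq.intercept)

    def test_missing_attribute_named(self):
        eq = builtin_equation("fresh_frozen", "firmness")
        with pytest.raises(KeyError, match="hardness_1"):
            predict(eq, {"thickness_1": 14.0})

    def test_square_and_cross_terms(self):
        eq = PredictionEquation(
            target="t", group="g", intercept=1.0,
            terms=(Term("square", ("a",), 2.0), Term("cross", ("a", "b"), 3.0)))
        assert predict(eq, {"a": 2.0, "b": 5.0}) == pytest.approx(
            1.0 + 2.0 * 4.0 + 3.0 * 10.0)


class TestEvaluate:
    def test_perfect_linear_fit(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 + 3.0 * df["x"]
        eq = PredictionEquation(target="y", group="", intercept=2.0,
                                terms=(Term("linear", ("x",), 3.0),))
        rep = evaluate(eq, df)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_model(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.normal(5.0, 2.0, 40)})
        eq = PredictionEquation(target="y", group="",
                                intercept=float(df["y"].mean()), terms=())
        rep = evaluate(eq, df)
        assert rep.r_squared == pytest.approx(0.0, abs=1e-12)
        assert rep.rmse == pytest.approx(df["y"].std(ddof=1), rel=1e-12)

    def test_matches_statsmodels_ols(self):
        # independent oracle for RMSE / R^2 / adjusted R^2
        import statsmodels.api as sm
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x1": rng.normal(size=30),
                           "x2": rng.normal(size=30)})
        df["y"] = 1.0 + 0.5 * df.x1 - 1.5 * df.x2 + rng.normal(0, 0.3, 30)
        res = sm.OLS(df["y"], sm.add_constant(df[["x1", "x2"]])).fit()
        eq = PredictionEquation(
            target="y", group="", intercept=float(res.params["const"]),
            terms=(Term("linear", ("x1",), float(res.params["x1"])),
                   Term("linear", ("x2",), float(res.params["x2"]))))
        rep = evaluate(eq, df)
        assert rep.r_squared == pytest.approx(res.rsquared, abs=1e-10)
        assert rep.adj_r_squared == pytest.approx(res.rsquared_adj, abs=1e-10)
        assert rep.rmse == pytest.approx(np.sqrt(res.mse_resid), abs=1e-10)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        eq = PredictionEquation(target="y", group="", intercept=0.0,
                                terms=(Term("linear", ("x",), 1.0),))
        with pytest.raises(ValueError, match="n > p"):
            evaluate(eq, df)


def make_candidates(rng, n, k=10):
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"attr_{i:02d}" for i in range(k)])


class TestStepwise:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(21)
        df = make_candidates(rng, 500)
        df = df.rename(columns={"attr_00": "hardness_1"})
        df["y"] = 2.0 * df["hardness_1"] + rng.normal(0, 0.1, 500)
        eq, rep = stepwise_fit(df, "y", [c for c in df.columns if c != "y"])
        assert eq.terms[0].attributes == ("hardness_1",)
        coef = next(t.coef for t in eq.terms
                    if t.kind == "linear" and t.attributes == ("hardness_1",))
        assert coef == pytest.approx(2.0, rel=0.05)
        assert rep.entry_p["hardness_1"] < 0.05

    def test_interaction_recovered_in_phase_two(self):
        rng = np.random.default_rng(4)
        n = 400
        df = pd.DataFrame({"a": rng.normal(2.0, 1.0, n),
                           "b": rng.normal(3.0, 1.0, n),
                           "c": rng.normal(size=n)})
        df["y"] = df.a * df.b + rng.normal(0, 0.2, n)
        eq_main, rep_main = stepwise_fit(df, "y", ["a", "b", "c"],
                                         interactions=False)
        eq, rep = stepwise_fit(df, "y", ["a", "b", "c"])
        assert any(t.kind == "cross" and set(t.attributes) == {"a", "b"}
                   for t in eq.terms)
        assert rep.r_squared > rep_main.r_squared

    def test_r_squared_non_decreasing_and_entries_below_alpha(self):
        rng = np.random.default_rng(17)
        df = make_candidates(rng, 200, 6)
        df["y"] = df.attr_01 - 0.5 * df.attr_03 + rng.normal(0, 0.5, 200)
        eq, rep = stepwise_fit(df, "y", [c for c in df.columns if c != "y"])
        assert all(p < 0.05 for p in rep.entry_p.values())

    def test_null_entry_rate_matches_selection_theory(self):
        # pure-noise response, 10 independent candidates: P(any enters)
        # ~ 1 - 0.95^10 ~ 40%
        rng = np.random.default_rng(2718)
        n_rep, entered = 400, 0
        for _ in range(n_rep):
            df = make_candidates(rng, 100)
            df["y"] = rng.normal(size=100)
            eq, _ = stepwise_fit(df, "y", [c for c in df.columns if c != "y"],
                                 interactions=False)
            entered += bool(eq.terms)
        rate = entered / n_rep
        assert abs(rate - (1 - 0.95 ** 10)) < 0.07

    def test_mean_prediction_identity_for_linear_fit(self, small_cohort):
        from tpafish import aggregate_fish
        agg = aggregate_fish(small_cohort.tpa, small_cohort.sensory)
        sub = agg[agg.treatment == "iqf"]
        eq, rep = stepwise_fit(sub, "firmness",
                               ["hardness_1", "thickness_1", "springiness"],
                               interactions=False)
        yhat = predict(eq, sub)
        yhat = np.full(len(sub), yhat) if np.ndim(yhat) == 0 else yhat
        assert float(np.mean(yhat)) == pytest.approx(
            sub["firmness"].mean(), abs=1e-10)

    def test_intercept_only_when_nothing_qualifies(self):
        rng = np.random.default_rng(99)
        df = make_candidates(rng, 60, 3)
        df["y"] = rng.normal(size=60)
        # alpha so small that nothing can enter
        eq, rep = stepwise_fit(df, "y", [c for c in df.columns if c != "y"],
                               alpha=1e-9)
        assert eq.terms == ()

    def test_constant_candidate_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           "x": [1.0] * 6})
        with pytest.raises(ValueError, match="constant"):
            stepwise_fit(df, "y", ["x"])


class TestGeneratorRecovery:
    def test_stepwise_finds_linked_attribute_in_cohort(self):
        # cohort with one known sensory link: forward selection should
        # pick the linked attribute first and estimate its coefficient
        from tpafish import CohortSpec, SensoryLink, iqf_group, \
            simulate_cohort, aggregate_fish
        links = {"firmness": SensoryLink(intercept=0.5,
                                         coefs={"hardness_1": 0.02},
                                         noise_sd=0.3)}
        spec = CohortSpec(groups=(iqf_group(400, sensory_links=links),),
                          seed=77)
        cohort = simulate_cohort(spec)
        agg = aggregate_fish(cohort.tpa, cohort.sensory)
        eq, rep = stepwise_fit(
            agg, "firmness",
            ["hardness_1", "thickness_1", "cohesiveness", "springiness",
             "resilience", "adhesiveness"], interactions=False)
        assert eq.terms[0].attributes == ("hardness_1",)
        coef = eq.terms[0].coef
        assert coef == pytest.approx(0.02, rel=0.1)
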