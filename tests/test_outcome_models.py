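"""Linear and logistic outcome models, stepwise selection, effect transforms."""

import numpy as np
import pandas as pd
import pytest

from dentasym import (
    ModelSpec,
    fit_linear_log_age,
    fit_logistic,
    odds_ratio,
    percent_change,
    stepwise_select,
)
from dentasym.errors import ComputationError, ValidationError
from dentasym.outcome_models import effect_table


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestLinearFit:
    def test_noiseless_data_recovers_coefficients_exactly(self, rng):
        # the immature age model's coefficient vector, recovered to 1e-10
        b0, b_fa, b_pd = 2.095, 0.176, 0.460
        n = 50
        fa = rng.normal(size=n)
        pd_flag = rng.integers(0, 2, size=n).astype(float)
        df = pd.DataFrame(
            {"log_age": b0 + b_fa * fa + b_pd * pd_flag, "fa_z": fa, "pd_present": pd_flag}
        )
        fit = fit_linear_log_age(df, "log_age ~ fa_z + pd_present")
        assert fit.coef("Intercept") == pytest.approx(b0, abs=1e-10)
        assert fit.coef("fa_z") == pytest.approx(b_fa, abs=1e-10)
        assert fit.coef("pd_present") == pytest.approx(b_pd, abs=1e-10)

    def test_rescaling_response_only_shifts_intercept(self, rng):
        n = 80
        x = rng.normal(size=n)
        age = np.exp(2.0 + 0.3 * x + rng.normal(0, 0.2, n))
        c = 7.0
        df1 = pd.DataFrame({"log_age": np.log(age), "x": x})
        df2 = pd.DataFrame({"log_age": np.log(age * c), "x": x})
        f1 = fit_linear_log_age(df1, "log_age ~ x")
        f2 = fit_linear_log_age(df2, "log_age ~ x")
        assert f2.coef("x") == pytest.approx(f1.coef("x"), abs=1e-12)
        assert f2.coef("Intercept") - f1.coef("Intercept") == pytest.approx(np.log(c))

    def test_rank_deficient_design_names_aliased_term(self, rng):
        n = 30
        x = rng.normal(size=n)
        df = pd.DataFrame({"log_age": rng.normal(size=n), "x": x, "x2": 2 * x})
        with pytest.raises(ComputationError, match="alias"):
            fit_linear_log_age(df, "log_age ~ x + x2")

    def test_adjusted_r2_never_exceeds_r2(self, rng):
        n = 40
        df = pd.DataFrame(
            {"log_age": rng.normal(size=n), "a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        fit = fit_linear_log_age(df, "log_age ~ a + b")
        import statsmodels.formula.api as smf

        raw = smf.ols("log_age ~ a + b", df).fit().rsquared
        assert fit.adj_r2 <= raw


class TestLogisticFit:
    def test_balanced_no_predictor_data_gives_zero_intercept(self):
        df = pd.DataFrame({"y": [0, 1] * 20})
        fit = fit_logistic(df, "y ~ 1")
        assert fit.coef("Intercept") == pytest.approx(0.0, abs=1e-8)
        assert fit.mcfadden_r2 == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_fit_equals_logit_of_proportion(self):
        # 28 affected of 68: intercept = ln(28/40)
        df = pd.DataFrame({"y": [1] * 28 + [0] * 40})
        fit = fit_logistic(df, "y ~ 1")
        assert fit.coef("Intercept") == pytest.approx(np.log(28 / 40), abs=1e-8)

    def test_simulated_laterality_model_recovers_coefficients(self, rng):
        """Data generated at the bilaterality model's coefficients
        (intercept 1.534, FA slope 0.967) is recovered within 2 SE at n=500."""
        n = 500
        fa = rng.normal(size=n)
        y = (rng.random(n) < _invlogit(1.534 + 0.967 * fa)).astype(float)
        fit = fit_logistic(pd.DataFrame({"y": y, "fa_z": fa}), "y ~ fa_z")
        for term, truth in (("Intercept", 1.534), ("fa_z", 0.967)):
            err = abs(fit.coef(term) - truth)
            assert err < 2 * fit.params.loc[term, "se"] + 1e-12

    def test_mcfadden_r2_invariant_to_predictor_rescaling(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = (rng.random(n) < _invlogit(0.5 + 0.8 * x)).astype(float)
        f1 = fit_logistic(pd.DataFrame({"y": y, "x": x}), "y ~ x")
        f2 = fit_logistic(pd.DataFrame({"y": y, "x": 100 * x}), "y ~ x")
        assert f1.mcfadden_r2 == pytest.approx(f2.mcfadden_r2, abs=1e-8)

    def test_complete_separation_reported_with_term(self):
        df = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": np.arange(40.0)})
        with pytest.raises(ComputationError, match="separation"):
            fit_logistic(df, "y ~ x")

    def test_single_class_response_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValidationError):
            fit_logistic(df, "y ~ x")


class TestStepwise:
    def test_empty_candidate_set_returns_intercept_only(self, rng):
        df = pd.DataFrame({"log_age": rng.normal(size=20)})
        spec, path = stepwise_select(df, ModelSpec("log_age", [], "linear"))
        assert spec.predictors == []
        assert any("intercept" in line for line in path)

    def test_pure_noise_predictor_rarely_selected(self, rng):
        """Under AIC a useless predictor enters with probability near
        P(chi2_1 > 2) ~ 0.157; check the empirical rate over 300 runs."""
        hits = 0
        runs = 300
        for _ in range(runs):
            df = pd.DataFrame(
                {"log_age": rng.normal(size=60), "noise": rng.normal(size=60)}
            )
            spec, _ = stepwise_select(df, ModelSpec("log_age", ["noise"], "linear"))
            hits += "noise" in spec.predictors
        rate = hits / runs
        assert 0.09 < rate < 0.23

    def test_strong_predictor_almost_always_selected(self, rng):
        hits = 0
        runs = 60
        for _ in range(runs):
            x = rng.normal(size=100)
            df = pd.DataFrame({"log_age": x + rng.normal(size=100), "x": x})
            spec, _ = stepwise_select(df, ModelSpec("log_age", ["x"], "linear"))
            hits += "x" in spec.predictors
        assert hits / runs > 0.95

    def test_selection_is_idempotent_at_a_local_optimum(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"log_age": x + rng.normal(size=100), "x": x})
        spec1, _ = stepwise_select(df, ModelSpec("log_age", ["x"], "linear"))
        spec2, _ = stepwise_select(df, ModelSpec(spec1.response, spec1.predictors, "linear"))
        assert spec2.predictors == spec1.predictors


class TestEffectTransforms:
    @pytest.mark.parametrize(
        "b, expected",
        [
            (0.176, 19.2),  # one SD of FA -> longer life, immature cohort
            (0.460, 58.4),  # PD presence -> longer life, immature cohort
            (-0.393, -32.5),  # PNBF x PD co-occurrence -> shorter life
            (0.0, 0.0),
        ],
    )
    def test_percent_change_round_trips_reported_effects(self, b, expected):
        assert percent_change(b).effect == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "b, expected", [(0.967, 2.63), (0.0, 1.0), (np.log(3.0), 3.0)]
    )
    def test_odds_ratio_round_trips_reported_effects(self, b, expected):
        assert odds_ratio(b).effect == pytest.approx(expected, abs=0.005)

    def test_transforms_are_strictly_increasing_and_order_preserving(self):
        bs = np.linspace(-2, 2, 41)
        pc = [percent_change(b).effect for b in bs]
        orr = [odds_ratio(b).effect for b in bs]
        assert all(a < b for a, b in zip(pc, pc[1:]))
        assert all(a < b for a, b in zip(orr, orr[1:]))
        eff = percent_change(0.3, ci=(0.1, 0.5))
        assert eff.ci_low < eff.effect < eff.ci_high

    def test_effect_table_is_consistent_with_coefficients(self, rng):
        n = 200
        x = rng.normal(size=n)
        df = pd.DataFrame({"log_age": 1 + 0.2 * x + rng.normal(0, 0.1, n), "x": x})
        fit = fit_linear_log_age(df, "log_age ~ x")
        table = effect_table(fit)
        row = table[table["term"] == "x"].iloc[0]
        assert row["percent_change"] == pytest.approx(
            100 * np.expm1(fit.coef("x")), rel=1e-12
        )
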