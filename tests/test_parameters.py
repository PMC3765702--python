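import math

import numpy as np
import pytest
from scipy import integrate, stats

from afcua.parameters import (
    PSA_REGISTRY,
    BetaFit,
    GammaFit,
    ParameterError,
    ParameterSet,
    ParameterValue,
    apply_overrides,
    default_parameter_set,
    fit_beta_from_ci,
    fit_gamma_from_ci,
    fit_lognormal_from_ci,
    fitted_mean,
    load_parameter_set,
    sample_psa_draw,
    save_parameter_set,
    validate_parameter_set,
)


class TestDefaults:
    def test_genotyping_cost(self, params):
        assert params.cost_genotyping == 615

    def test_bleed_probability(self, params):
        assert params.p_bleed_annual_inrange == 0.014

    def test_te_split_sums_to_one(self, params):
        assert sum(params.te_split_warfarin.values()) == pytest.approx(1.0, abs=1e-12)

    def test_ich_outcomes_sum_to_one(self, params):
        assert sum(params.ich_outcomes.values()) == pytest.approx(1.0, abs=1e-12)

    def test_dab_bleed_split_normalizes(self, params):
        raw = params.bleed_split_dab_raw
        assert sum(raw.values()) == pytest.approx(1.03)
        total = sum(raw.values())
        assert sum(v / total for v in raw.values()) == pytest.approx(1.0, abs=1e-12)

    def test_globals(self, params):
        assert params.horizon_days == 1825
        assert params.discount_annual == 0.03
        assert params.cohort_size == 10000
        assert params.n_replicates == 1000
        assert params.wtp_threshold == 50000

    def test_validates(self, params):
        validate_parameter_set(params)


class TestSerialization:
    def test_round_trip_identity(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameter_set(params, path)
        assert load_parameter_set(path) == params

    def test_missing_field_named(self, params, tmp_path):
        import yaml

        data = params.to_dict()
        del data["cost_genotyping"]
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ParameterError, match="cost_genotyping"):
            load_parameter_set(path)

    def test_out_of_range_value_rejected(self, params, tmp_path):
        import yaml

        data = params.to_dict()
        data["p_bleed_annual_inrange"] = 1.5
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(data))
        with pytest.raises(ParameterError, match="p_bleed_annual_inrange"):
            load_parameter_set(path)

    def test_config_override_day_cost(self, params, tmp_path):
        import yaml

        data = params.to_dict()
        data["cost_dab_daily"] = 5.0
        path = tmp_path / "p.yaml"
        path.write_text(yaml.safe_dump(data))
        assert load_parameter_set(path).cost_dab_daily == 5.0

    def test_shipped_baseline_file_matches_defaults(self):
        from importlib import resources

        with resources.as_file(
            resources.files("afcua.data") / "params_table1.yaml"
        ) as path:
            assert load_parameter_set(path) == default_parameter_set()


class TestOverrides:
    def test_scalar_override(self, params):
        out = apply_overrides(params, {"rr_bleed_dab": 0.81})
        assert out.rr_bleed_dab == 0.81
        assert params.rr_bleed_dab == 0.93  # original untouched

    def test_empty_overrides_identity(self, params):
        assert apply_overrides(params, {}) == params

    def test_nested_override(self, params):
        out = apply_overrides(params, {"utilities.no_event_dab": 0.98})
        assert out.utilities["no_event_dab"] == 0.98

    def test_unknown_key_raises(self, params):
        with pytest.raises(ParameterError, match="no_such"):
            apply_overrides(params, {"no_such_field": 1})

    def test_invalid_value_rejected(self, params):
        with pytest.raises(ParameterError):
            apply_overrides(params, {"p_te_annual_inrange": -0.1})


class TestParameterValue:
    def test_baseline_outside_range_rejected(self):
        with pytest.raises(ParameterError):
            ParameterValue("x", 2.0, 0.0, 1.0, "beta")

    def test_beta_range_must_be_unit_interval(self):
        with pytest.raises(ParameterError):
            ParameterValue("x", 1.5, 0.5, 2.0, "beta")

    def test_unknown_family(self):
        with pytest.raises(ParameterError):
            ParameterValue("x", 0.5, 0.0, 1.0, "weird")


class TestBetaFit:
    def test_symmetric_interval_gives_equal_shapes(self):
        fit = fit_beta_from_ci(0.5, 0.3, 0.7)
        assert fit.alpha == pytest.approx(fit.beta, rel=1e-6)

    def test_mean_preserved_by_numeric_integration(self):
        fit = fit_beta_from_ci(0.64, 0.55, 0.69)
        mean, _ = integrate.quad(
            lambda x: x * stats.beta.pdf(x, fit.alpha, fit.beta), 0, 1
        )
        assert mean == pytest.approx(0.64, rel=1e-6)

    def test_quantiles_near_range(self):
        fit = fit_beta_from_ci(0.64, 0.55, 0.69)
        q = stats.beta.ppf([0.025, 0.975], fit.alpha, fit.beta)
        assert q[0] == pytest.approx(0.55, abs=0.02)
        assert q[1] == pytest.approx(0.69, abs=0.02)

    def test_degenerate_range_is_fixed(self):
        assert fit_beta_from_ci(0.5, 0.5, 0.5) is None

    def test_mean_outside_range_raises(self):
        with pytest.raises(ParameterError):
            fit_beta_from_ci(0.9, 0.1, 0.5)


class TestGammaFit:
    def test_mean_is_shape_times_scale(self):
        fit = fit_gamma_from_ci(3.20, 1.0, 5.0)
        assert fit.shape * fit.scale == pytest.approx(3.20, rel=1e-9)

    def test_degenerate_range_is_fixed(self):
        assert fit_gamma_from_ci(2.0, 2.0, 2.0) is None

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            fit_gamma_from_ci(-1.0, 0.5, 2.0)


class TestLognormalFit:
    def test_sigma_symmetric_ci_rule(self):
        fit = fit_lognormal_from_ci(0.93, 0.81, 1.07)
        expected_sigma = (math.log(1.07) - math.log(0.81)) / (2 * 1.959963984540054)
        assert fit.sigma == pytest.approx(expected_sigma, rel=1e-9)
        assert fit.mean_constrained

    def test_mean_preserved(self):
        fit = fit_lognormal_from_ci(4.7, 3.57, 10.0)
        assert math.exp(fit.mu + fit.sigma**2 / 2) == pytest.approx(4.7, rel=1e-9)

    def test_infeasible_mean_falls_back_to_log_midpoint(self):
        fit = fit_lognormal_from_ci(20.0, 1.0, 10.0)
        assert not fit.mean_constrained
        assert fit.mu == pytest.approx(0.5 * (math.log(1) + math.log(10)))

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            fit_lognormal_from_ci(1.0, 0.0, 2.0)


class TestFittedMeanInvariant:
    @pytest.mark.parametrize(
        "entry", [e for e in PSA_REGISTRY if e.low is not None and e.low < e.high],
        ids=lambda e: e.name,
    )
    def test_registry_fit_reproduces_mean(self, entry):
        if entry.family == "beta":
            fit = fit_beta_from_ci(entry.baseline, entry.low, entry.high)
        elif entry.family == "gamma":
            fit = fit_gamma_from_ci(entry.baseline, entry.low, entry.high)
        else:
            fit = fit_lognormal_from_ci(entry.baseline, entry.low, entry.high)
        assert fitted_mean(fit) == pytest.approx(entry.baseline, rel=1e-6)


class TestPSADraw:
    def test_same_seed_identical(self, params):
        assert sample_psa_draw(params, 42) == sample_psa_draw(params, 42)

    def test_different_seed_differs(self, params):
        assert sample_psa_draw(params, 1) != sample_psa_draw(params, 2)

    def test_splits_and_trees_unchanged(self, params):
        draw = sample_psa_draw(params, 9)
        assert draw.te_split_warfarin == params.te_split_warfarin
        assert draw.ich_outcomes == params.ich_outcomes
        assert draw.stroke_outcomes == params.stroke_outcomes
        assert draw.bleed_split_warfarin == params.bleed_split_warfarin

    def test_fixed_parameters_unchanged(self, params):
        draw = sample_psa_draw(params, 9)
        assert draw.cost_lmwh_course == params.cost_lmwh_course
        assert draw.rr_te_dab["dvt"] == params.rr_te_dab["dvt"]

    def test_all_fixed_registry_returns_baseline(self, params, monkeypatch):
        import afcua.parameters as mod

        fixed = tuple(
            ParameterValue(e.name, e.baseline, family="fixed") for e in PSA_REGISTRY
        )
        monkeypatch.setattr(mod, "PSA_REGISTRY", fixed)
        assert sample_psa_draw(params, 7) == params

    def test_marginal_mean_of_rr_bleed(self, params):
        draws = np.array(
            [
                sample_psa_draw(params, seed).rr_bleed_out_of_range
                for seed in range(2000)
            ]
        )
        fit = fit_lognormal_from_ci(4.7, 3.57, 10.0)
        mean = math.exp(fit.mu + fit.sigma**2 / 2)
        sd = mean * math.sqrt(math.exp(fit.sigma**2) - 1.0)
        se = sd / math.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 3 * se

    def test_draw_validates(self, params):
        validate_parameter_set(sample_psa_draw(params, 3))
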