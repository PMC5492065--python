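import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import stagehmm as sh
from stagehmm.covariates import GROWTH_INTERCEPTS, ParameterLayout
from stagehmm.states import live_index


def make_params(structure=None, **overrides) -> sh.ParameterVector:
    base = dict(
        b0=np.zeros(5 if structure is None or structure.survival_grouping == "full_stage" else 2),
        a0=np.zeros(7),
        p_live=np.full(6, 0.5),
        p_dead=np.full(5, 0.5),
        egg_survival=0.9,
        egg_hatch=0.6,
        pupation=0.4,
    )
    base.update(overrides)
    return sh.ParameterVector(**base)


CONST = sh.ModelStructure("constant", "full_stage", "constant")
DATE = sh.ModelStructure("date", "full_stage", "constant")
GROUPED = sh.ModelStructure("constant", "early_grouped", "constant")


class TestSurvivalLink:
    def test_zero_intercept_gives_half(self):
        assert sh.survival_probability("I2", None, make_params(), CONST) == pytest.approx(0.5)

    def test_log_odds_nine_gives_point_nine(self):
        p = make_params(b0=np.full(5, np.log(9.0)))
        assert sh.survival_probability("I1", None, p, CONST) == pytest.approx(0.9)

    def test_slope_moves_through_logistic(self):
        p = make_params(b1=np.full(5, np.log(9.0)))
        assert sh.survival_probability("I4", 1.0, p, DATE) == pytest.approx(0.9)

    def test_grouping_pools_early_instars(self):
        p = make_params(GROUPED, b0=np.array([1.0, -1.0]))
        for s in ("I1", "I2", "I3", "I4"):
            assert sh.survival_probability(s, None, p, GROUPED) == pytest.approx(
                1 / (1 + np.exp(-1.0))
            )
        assert sh.survival_probability("I5", None, p, GROUPED) == pytest.approx(
            1 / (1 + np.exp(1.0))
        )

    def test_egg_survival_is_the_informative_parameter(self):
        assert sh.survival_probability("egg", None, make_params(), CONST) == 0.9

    def test_pupa_and_missing_covariate_raise(self):
        with pytest.raises(ValueError, match="pupa"):
            sh.survival_probability("pupa", None, make_params(), CONST)
        with pytest.raises(ValueError, match="covariate"):
            sh.survival_probability("I1", None, make_params(b1=np.zeros(5)), DATE)


class TestGrowthLink:
    def test_symmetric_logits_give_equal_thirds(self):
        probs = sh.growth_probabilities("I2", None, make_params(), CONST)
        np.testing.assert_allclose(probs, [1 / 3] * 3)

    def test_single_destination_zero_intercept_gives_half(self):
        probs = sh.growth_probabilities("I4", None, make_params(), CONST)
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_single_destination_log_three(self):
        a0 = np.zeros(7)
        a0[6] = np.log(3.0)
        probs = sh.growth_probabilities("I4", None, make_params(a0=a0), CONST)
        np.testing.assert_allclose(probs, [0.25, 0.75])

    def test_egg_and_fifth_instar_use_informative_probabilities(self):
        p = make_params()
        np.testing.assert_allclose(sh.growth_probabilities("egg", None, p, CONST), [0.4, 0.6])
        np.testing.assert_allclose(sh.growth_probabilities("I5", None, p, CONST), [0.6, 0.4])

    def test_simplex_sums_to_one_for_random_parameters(self, rate_rng):
        struct = sh.ModelStructure("constant", "full_stage", "date")
        for _ in range(1000):
            p = make_params(
                a0=rate_rng.normal(0, 5, 7), a1=rate_rng.normal(0, 5, 4)
            )
            for stage in ("I1", "I2", "I3", "I4"):
                probs = sh.growth_probabilities(stage, rate_rng.normal(), p, struct)
                assert abs(probs.sum() - 1.0) < 1e-12
                assert np.all(probs >= 0)

    def test_overflow_guard(self):
        p = make_params(a0=np.full(7, 600.0))
        probs = sh.growth_probabilities("I1", None, p, CONST)
        assert np.isfinite(probs).all() and abs(probs.sum() - 1.0) < 1e-12


class TestAssembleVitalRates:
    def test_constant_structure_is_time_invariant(self):
        p = make_params()
        a = sh.assemble_vital_rates(p, CONST)
        b = sh.assemble_vital_rates(p, CONST)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_zero_slopes_reproduce_the_constant_model(self):
        pc = make_params()
        pd_ = make_params(b1=np.zeros(5), a1=np.zeros(4))
        struct = sh.ModelStructure("date", "full_stage", "date")
        a = sh.assemble_vital_rates(pc, CONST)
        b = sh.assemble_vital_rates(pd_, struct, survival_covariate=1.7, growth_covariate=-0.4)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.psi, b.psi)

    def test_slope_sign_sets_direction_of_change(self):
        p = make_params(b1=np.full(5, 0.8))
        early = sh.assemble_vital_rates(p, DATE, survival_covariate=-1.0)
        late = sh.assemble_vital_rates(p, DATE, survival_covariate=1.0)
        instars = [live_index(s) for s in ("I1", "I2", "I3", "I4", "I5")]
        assert np.all(late.phi[instars] > early.phi[instars])


class TestDensityAndTemperature:
    def test_stage_mean_lengths_sum(self):
        assert sh.size_scaled_density([4.1, 19.9]) == pytest.approx(24.0)

    def test_empty_plant_and_count_metric(self):
        assert sh.size_scaled_density([]) == 0.0
        assert sh.size_scaled_density([3.0, 9.0, 12.5], metric="count") == 3.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            sh.size_scaled_density([4.0, -1.0])

    @given(st.lists(st.floats(0, 50), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_density_is_permutation_invariant(self, lengths):
        rev = list(reversed(lengths))
        for metric in ("size", "count"):
            assert sh.size_scaled_density(lengths, metric) == pytest.approx(
                sh.size_scaled_density(rev, metric), rel=1e-12
            )

    def test_constant_series_mean(self):
        hourly = pd.DataFrame({"hour": np.arange(72), "temp": 70.0})
        assert sh.interval_mean_temperature(hourly, 0.0) == pytest.approx(70.0)

    def test_linear_ramp_means_to_midpoint(self):
        hourly = pd.DataFrame(
            {"hour": np.arange(72), "temp": np.linspace(60, 80, 72)}
        )
        assert sh.interval_mean_temperature(hourly, 0.0) == pytest.approx(70.0)

    def test_excess_missing_hours_error(self):
        hourly = pd.DataFrame({"hour": np.arange(58), "temp": 70.0})  # 20% missing
        with pytest.raises(ValueError, match="missing"):
            sh.interval_mean_temperature(hourly, 0.0)


class TestModelGrid:
    def test_default_grid_has_18_structures(self):
        grid = sh.enumerate_model_grid()
        assert len(grid) == 18
        assert len(set(grid)) == 18

    def test_single_and_product_counts(self):
        assert len(sh.enumerate_model_grid(("constant",), ("full_stage",), ("date",))) == 1
        assert (
            len(
                sh.enumerate_model_grid(
                    ("constant", "date"),
                    ("full_stage", "early_grouped"),
                    ("constant", "temperature"),
                )
            )
            == 8
        )

    def test_order_is_deterministic(self):
        grid = sh.enumerate_model_grid()
        assert grid[0] == sh.ModelStructure("constant", "full_stage", "constant")
        assert grid[-1] == sh.ModelStructure("density", "early_grouped", "temperature")

    def test_empty_options_error(self):
        with pytest.raises(ValueError):
            sh.enumerate_model_grid((), ("full_stage",), ("constant",))


class TestParameterLayout:
    @pytest.mark.parametrize(
        "structure",
        [
            CONST,
            GROUPED,
            sh.ModelStructure("date", "early_grouped", "temperature"),
            sh.ModelStructure("density", "full_stage", "date"),
        ],
    )
    def test_round_trip_through_both_scales(self, structure, rate_rng):
        layout = ParameterLayout(structure)
        p = make_params(
            structure,
            b0=rate_rng.normal(size=len(structure.survival_groups)),
            b1=rate_rng.normal(size=len(structure.survival_groups))
            if structure.survival_form != "constant"
            else None,
            a0=rate_rng.normal(size=7),
            a1=rate_rng.normal(size=4) if structure.growth_form != "constant" else None,
            p_live=rate_rng.uniform(0.1, 0.9, 6),
            p_dead=rate_rng.uniform(0.1, 0.9, 5),
        )
        nat = layout.natural(p)
        z = layout.unconstrained(p)
        np.testing.assert_allclose(layout.natural_from_unconstrained(z), nat, atol=1e-12)
        p2 = layout.from_unconstrained(z)
        np.testing.assert_allclose(layout.natural(p2), nat, atol=1e-12)
        assert layout.size == len(layout.names) == len(layout.kinds)

    def test_intercept_layout_matches_allowed_transitions(self):
        assert len(GROWTH_INTERCEPTS) == 7
        assert GROWTH_INTERCEPTS[0] == ("I1", "I2")
        assert GROWTH_INTERCEPTS[-1] == ("I4", "I5")


def test_build_covariates_standardizes_and_uses_observed_density(small_cohort):
    cfg, histories, tables, _ = small_cohort
    cov = sh.build_covariates(histories, tables["temperature"])
    n = len(histories)
    T = histories[0].n_occasions
    for arr in (cov.x_date, cov.x_density, cov.x_temperature):
        assert arr.shape == (n, T)
        assert np.isfinite(arr).all()
        assert abs(arr.mean()) < 1e-9
    # standardization is invertible
    std = cov.standardizers["date"]
    np.testing.assert_allclose(std.inverse(cov.x_date[0]), histories[0].days, atol=1e-9)
    # the density covariate reflects observed co-occupants: an occasion where
    # the individual itself was the only detected instar on its plant equals
    # its own standardized length
    h = histories[0]
    xs, xg = cov.for_structure(sh.ModelStructure("density", "full_stage", "temperature"))
    assert xs.shape == (n, T) and xg.shape == (n, T)
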