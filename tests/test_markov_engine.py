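import logging

import numpy as np
import pytest

from lbpcea.cost_model import CycleCosts
from lbpcea.markov_engine import (
    CohortTrace,
    Conventions,
    HealthState,
    accumulate_outcomes,
    build_transition_matrix,
    discount_factor,
    effective_recovery_probability,
    enumerate_paths_occupancy,
    evaluate_strategy,
    run_cohort,
    validation_summary,
)
from lbpcea.parameters import (
    ModelSettings,
    ParameterError,
    TransitionParameters,
    UtilitySet,
)

BASE = dict(t_atc=0.24, t_wtc=0.16, t_ctw=0.35, t_rr=1.40)


def params(mortality=0.001, n=20, **overrides):
    kwargs = {**BASE, **overrides}
    return TransitionParameters(mortality=np.full(n, mortality), **kwargs)


class TestTransitionMatrix:
    def test_usual_care_rows_without_mortality(self):
        m = build_transition_matrix("usual_care", params(mortality=0.0))
        np.testing.assert_allclose(m[HealthState.ACUTE], [0, 0.24, 0.76, 0], atol=1e-15)
        np.testing.assert_allclose(m[HealthState.CHRONIC], [0, 0.65, 0.35, 0], atol=1e-15)
        np.testing.assert_allclose(m[HealthState.WELL], [0, 0.16, 0.84, 0], atol=1e-15)
        np.testing.assert_allclose(m[HealthState.DEAD], [0, 0, 0, 1], atol=0)

    def test_collaborative_recovery_applies_risk_ratio(self):
        m = build_transition_matrix("collaborative", params(mortality=0.0))
        assert m[HealthState.CHRONIC, HealthState.WELL] == pytest.approx(0.49, abs=1e-12)

    def test_mortality_scales_survivor_split(self):
        m = build_transition_matrix("usual_care", params(mortality=0.001))
        assert m[HealthState.ACUTE, HealthState.CHRONIC] == pytest.approx(0.23976, abs=1e-12)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-15)

    def test_risk_ratio_clamped_with_warning(self, caplog):
        p = params(t_ctw=0.9, t_rr=1.4)
        with caplog.at_level(logging.WARNING):
            eff = effective_recovery_probability("collaborative", p)
        assert eff == 1.0
        assert "clamped" in caplog.text

    def test_rate_scale_risk_ratio(self):
        p = params(t_ctw=0.35, t_rr=1.4)
        eff = effective_recovery_probability("collaborative", p, rr_scale="rate")
        assert eff == pytest.approx(1 - 0.65**1.4, abs=1e-12)
        assert eff < 1.0

    def test_invalid_mortality_rejected(self):
        with pytest.raises(ParameterError):
            TransitionParameters(mortality=np.full(20, 1.5), **BASE)

    def test_cycle_index_outside_schedule_rejected(self):
        with pytest.raises(ParameterError):
            build_transition_matrix("usual_care", params(n=5), cycle_index=7)


class TestRunCohort:
    def test_absorbing_well_state_with_no_recurrence(self):
        """With no recurrence and no deaths the cohort settles in well."""
        p = params(mortality=0.0, t_wtc=0.0, t_ctw=0.0)
        trace = run_cohort("usual_care", p, ModelSettings())
        np.testing.assert_allclose(trace.occupancy[1], [0, 0.24, 0.76, 0], atol=1e-15)
        # chronic never recovers, well never relapses: occupancy frozen after cycle 1
        for t in range(2, 21):
            np.testing.assert_allclose(trace.occupancy[t], trace.occupancy[1], atol=1e-15)

    @pytest.mark.parametrize("strategy", ["usual_care", "collaborative"])
    @pytest.mark.parametrize("n_cycles", [3, 4])
    def test_matches_path_enumeration_oracle(self, strategy, n_cycles):
        """Cohort propagation equals brute-force enumeration of all state paths."""
        mortality = np.array([0.001, 0.002, 0.0025, 0.003])
        p = TransitionParameters(mortality=mortality, **BASE)
        settings = ModelSettings(n_cycles=n_cycles)
        trace = run_cohort(strategy, p, settings)
        oracle = enumerate_paths_occupancy(strategy, p, n_cycles)
        np.testing.assert_allclose(trace.occupancy, oracle, atol=1e-12)

    def test_matches_matrix_power(self):
        p = params(mortality=0.001)
        trace = run_cohort("usual_care", p, ModelSettings())
        m = build_transition_matrix("usual_care", p)
        start = np.array([1.0, 0, 0, 0])
        np.testing.assert_allclose(trace.occupancy[20], start @ np.linalg.matrix_power(m, 20), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_monotone_death(self, config, seed):
        from lbpcea.parameters import sample_parameter_set

        draw = sample_parameter_set(
            config.distribution_specs(), seed, mortality=config.mortality_schedule()
        )
        for strategy in ("usual_care", "collaborative"):
            trace = run_cohort(strategy, draw.transitions, ModelSettings())
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
            dead = trace.occupancy[:, HealthState.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_no_mortality_means_no_deaths(self):
        trace = run_cohort("usual_care", params(mortality=0.0), ModelSettings())
        assert np.all(trace.occupancy[:, HealthState.DEAD] == 0.0)

    def test_collaboration_accumulates_fewer_chronic_cycles(self):
        p = params(mortality=0.001)
        uc = run_cohort("usual_care", p, ModelSettings())
        ac = run_cohort("collaborative", p, ModelSettings())
        cum_uc = np.cumsum(uc.occupancy[:, HealthState.CHRONIC])
        cum_ac = np.cumsum(ac.occupancy[:, HealthState.CHRONIC])
        assert np.all(cum_ac <= cum_uc + 1e-15)


class TestDiscounting:
    def test_discount_factor_values(self):
        settings = ModelSettings()
        assert discount_factor(0, settings) == 1.0
        assert discount_factor(4, settings) == pytest.approx(1 / 1.05, abs=1e-12)
        assert discount_factor(20, settings) == pytest.approx(1.05**-5, abs=1e-12)

    def test_discounted_never_exceeds_undiscounted(self, base):
        for outcome in base["outcomes"].values():
            assert outcome.qaly_discounted < outcome.qaly_undiscounted
            assert outcome.cost_discounted < outcome.cost_undiscounted

    def test_zero_rate_makes_variants_equal(self):
        settings = ModelSettings(annual_discount_rate=0.0)
        outcome = evaluate_strategy(
            "usual_care", params(), UtilitySet(), CycleCosts(275_740, 232_036), settings
        )
        assert outcome.qaly_discounted == outcome.qaly_undiscounted


class TestAccumulateOutcomes:
    def test_all_well_closed_form(self):
        occupancy = np.tile([0.0, 0.0, 1.0, 0.0], (21, 1))
        trace = CohortTrace(occupancy=occupancy, strategy="usual_care")
        settings = ModelSettings(annual_discount_rate=0.0)
        outcome = accumulate_outcomes(trace, UtilitySet(), CycleCosts(275_740, 232_036), settings)
        assert outcome.qaly == pytest.approx(20 * 0.25 * 0.96, abs=1e-12)
        assert outcome.cost == 0.0

    def test_base_case_headline_numbers(self, base):
        uc = base["outcomes"]["usual_care"]
        ac = base["outcomes"]["collaborative"]
        assert uc.qaly == pytest.approx(4.11, rel=0.05)
        assert ac.qaly == pytest.approx(4.24, rel=0.05)
        assert uc.cost == pytest.approx(2_988_203, rel=0.05)
        assert ac.cost == pytest.approx(3_447_840, rel=0.05)

    def test_reward_timing_conventions_differ(self):
        p = params()
        common = (UtilitySet(), CycleCosts(275_740, 232_036), ModelSettings())
        start = evaluate_strategy("usual_care", p, *common, Conventions(reward_timing="start"))
        end = evaluate_strategy("usual_care", p, *common, Conventions(reward_timing="end"))
        half = evaluate_strategy("usual_care", p, *common, Conventions(half_cycle=True))
        # the all-acute entry cycle earns no cost under start timing but the
        # first transition's chronic share does under end timing
        assert start.cost < end.cost
        assert min(start.cost, end.cost) < half.cost < max(start.cost, end.cost)

    def test_mismatched_trace_rejected(self):
        occupancy = np.tile([0.0, 0.0, 1.0, 0.0], (11, 1))
        trace = CohortTrace(occupancy=occupancy, strategy="usual_care")
        with pytest.raises(ParameterError):
            accumulate_outcomes(trace, UtilitySet(), CycleCosts(1, 1), ModelSettings())


class TestValidationSummary:
    def test_constant_trace(self):
        occupancy = np.tile([0.0, 0.3, 0.7, 0.0], (21, 1))
        trace = CohortTrace(occupancy=occupancy, strategy="usual_care")
        summary = validation_summary(trace, cohort_size=10_000)
        assert summary["mean_chronic_cases"] == pytest.approx(3_000)

    def test_base_case_calibration(self, base):
        summary = base["validation"]
        assert summary["final_chronic_share"] == pytest.approx(0.2971, abs=0.02)
        assert summary["mean_chronic_cases"] == pytest.approx(2_982, rel=0.05)

    def test_stationary_share_matches_eigenvector(self):
        """Without mortality the alive chain tends to chronic share tWTC/(tWTC+tCTW)."""
        p = params(mortality=0.0, n=3_000)
        trace = run_cohort("usual_care", p, ModelSettings(n_cycles=3_000))
        expected = 0.16 / (0.16 + 0.35)
        assert trace.occupancy[-1, HealthState.CHRONIC] == pytest.approx(expected, abs=1e-10)
        # independent linear-algebra oracle: leading eigenvector of the 2x2 sub-chain
        sub = np.array([[0.65, 0.35], [0.16, 0.84]])
        values, vectors = np.linalg.eig(sub.T)
        stationary = np.real(vectors[:, np.argmax(np.real(values))])
        stationary /= stationary.sum()
        assert stationary[0] == pytest.approx(expected, abs=1e-12)
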