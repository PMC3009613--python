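import math

import numpy as np
import pytest

from lbpcea.meta_analysis import (
    NonInformativeStudyError,
    PooledEffect,
    StudyArmData,
    dersimonian_laird_pool,
    log_rr_and_se,
    pooled_to_lognormal,
)
from lbpcea.parameters import DistributionSpec, ParameterError
from lbpcea.synthetic_data import SyntheticMetaConfig, generate_meta_studies


def study(label, et, nt, ec, nc):
    return StudyArmData(label, et, nt, ec, nc)


# two small study sets with externally computed random-effects results
# (inverse-variance DL pooling of log risk ratios, R metafor 4.8-0)
HOMOGENEOUS = [
    study("h1", 30, 100, 20, 100),
    study("h2", 45, 150, 35, 150),
    study("h3", 40, 120, 28, 115),
    study("h4", 22, 80, 18, 85),
    study("h5", 60, 200, 50, 210),
]
HOMOGENEOUS_EXPECTED = dict(log_rr=0.2794409853, se=0.0930187791, tau2=0.0, q=0.3905148340)

HETEROGENEOUS = [
    study("x1", 50, 100, 20, 100),
    study("x2", 30, 150, 35, 150),
    study("x3", 60, 120, 30, 115),
    study("x4", 25, 80, 20, 85),
    study("x5", 55, 200, 50, 210),
]
HETEROGENEOUS_EXPECTED = dict(log_rr=0.3684284810, se=0.1842789786, tau2=0.1256810608, q=15.9183824879)


class TestLogRR:
    def test_identical_arms_give_zero(self):
        log_rr, _ = log_rr_and_se(study("s", 10, 100, 10, 100))
        assert log_rr == 0.0

    def test_hand_arithmetic(self):
        log_rr, se = log_rr_and_se(study("s", 20, 100, 10, 100))
        assert log_rr == pytest.approx(math.log(2), abs=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 20 - 1 / 100 + 1 / 10 - 1 / 100), abs=1e-12)
        assert se == pytest.approx(0.3606, abs=1e-4)

    def test_zero_event_arm_continuity_correction(self):
        log_rr, se = log_rr_and_se(study("s", 0, 50, 10, 50))
        assert math.isfinite(log_rr) and math.isfinite(se)
        assert log_rr < 0

    def test_double_zero_study_non_informative(self):
        with pytest.raises(NonInformativeStudyError):
            log_rr_and_se(study("s", 0, 50, 0, 50))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ParameterError):
            study("s", 60, 50, 10, 50)


class TestDerSimonianLaird:
    def test_single_study_passthrough(self):
        single = HOMOGENEOUS[0]
        pooled = dersimonian_laird_pool([single])
        log_rr, se = log_rr_and_se(single)
        assert pooled.log_rr == pytest.approx(log_rr)
        assert pooled.se_log_rr == pytest.approx(se)
        assert pooled.tau_squared == 0.0
        assert pooled.k == 1

    def test_no_informative_studies_rejected(self):
        with pytest.raises(ParameterError):
            dersimonian_laird_pool([study("s", 0, 50, 0, 50)])

    def test_identical_studies_have_no_heterogeneity(self):
        copies = [study(f"c{i}", 30, 100, 20, 100) for i in range(4)]
        pooled = dersimonian_laird_pool(copies)
        log_rr, se = log_rr_and_se(copies[0])
        assert pooled.tau_squared == 0.0
        assert pooled.log_rr == pytest.approx(log_rr)
        assert pooled.se_log_rr == pytest.approx(se / 2)  # se / sqrt(k)

    @pytest.mark.parametrize(
        "studies, expected",
        [(HOMOGENEOUS, HOMOGENEOUS_EXPECTED), (HETEROGENEOUS, HETEROGENEOUS_EXPECTED)],
        ids=["homogeneous", "heterogeneous"],
    )
    def test_against_frozen_reference_implementation(self, studies, expected):
        pooled = dersimonian_laird_pool(studies)
        assert pooled.log_rr == pytest.approx(expected["log_rr"], abs=1e-8)
        assert pooled.se_log_rr == pytest.approx(expected["se"], abs=1e-8)
        assert pooled.tau_squared == pytest.approx(expected["tau2"], abs=1e-8)
        assert pooled.q_statistic == pytest.approx(expected["q"], abs=1e-8)

    def test_against_statsmodels_on_heterogeneous_data(self):
        from statsmodels.stats.meta_analysis import combine_effects

        effects, variances = zip(*(log_rr_and_se(s) for s in HETEROGENEOUS))
        res = combine_effects(np.array(effects), np.array(variances) ** 2, method_re="dl")
        pooled = dersimonian_laird_pool(HETEROGENEOUS)
        assert pooled.tau_squared == pytest.approx(res.tau2, abs=1e-10)
        assert pooled.log_rr == pytest.approx(res.mean_effect_re, abs=1e-10)
        assert pooled.se_log_rr == pytest.approx(res.sd_eff_w_re, abs=1e-10)

    def test_tau_zero_reduces_to_fixed_effect(self):
        effects, ses = zip(*(log_rr_and_se(s) for s in HOMOGENEOUS))
        weights = 1 / np.array(ses) ** 2
        fixed = np.sum(weights * np.array(effects)) / weights.sum()
        pooled = dersimonian_laird_pool(HOMOGENEOUS)
        assert pooled.tau_squared == 0.0
        assert pooled.log_rr == pytest.approx(fixed, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        order = rng.permutation(len(HETEROGENEOUS))
        shuffled = [HETEROGENEOUS[i] for i in order]
        a = dersimonian_laird_pool(HETEROGENEOUS)
        b = dersimonian_laird_pool(shuffled)
        assert a.log_rr == pytest.approx(b.log_rr, abs=1e-14)
        assert a.tau_squared == pytest.approx(b.tau_squared, abs=1e-14)

    def test_pooled_effect_within_study_range(self):
        for studies in (HOMOGENEOUS, HETEROGENEOUS):
            effects = [log_rr_and_se(s)[0] for s in studies]
            pooled = dersimonian_laird_pool(studies)
            assert min(effects) <= pooled.log_rr <= max(effects)

    def test_recovers_planted_effect_from_synthetic_studies(self):
        config = SyntheticMetaConfig(
            k=50, true_log_rr=0.34, tau_between=0.1, arm_size_range=(200, 500), seed=17
        )
        pooled = dersimonian_laird_pool(generate_meta_studies(config))
        assert abs(pooled.log_rr - 0.34) < 3 * pooled.se_log_rr


class TestPooledToLognormal:
    def test_matches_reported_risk_ratio(self):
        pooled = PooledEffect(log_rr=0.34, se_log_rr=0.05, tau_squared=0.0, k=6)
        spec = pooled_to_lognormal(pooled)
        assert spec.family == "lognormal"
        assert pooled.rr_point == pytest.approx(1.405, abs=0.001)
        assert pooled.rr_point == pytest.approx(1.40, rel=0.01)

    def test_null_effect(self):
        pooled = PooledEffect(log_rr=0.0, se_log_rr=0.2, tau_squared=0.0, k=3)
        assert pooled.rr_point == 1.0

    def test_round_trip_through_sampling(self):
        spec = pooled_to_lognormal(PooledEffect(log_rr=0.34, se_log_rr=0.05, tau_squared=0.0, k=6))
        draws = spec.sample(np.random.default_rng(23), 100_000)
        assert np.log(draws).mean() == pytest.approx(0.34, abs=0.002)
        assert np.log(draws).std() == pytest.approx(0.05, abs=0.002)
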