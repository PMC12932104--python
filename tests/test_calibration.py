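"""Curve anchors, fitters and the free-parameter tuner."""
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dietabm as d
from dietabm.calibration import FitFailureError, MMFit, TuningResult

from conftest import constant_calibration, small_uniform_env


class TestLogisticCurves:
    def test_close_association_anchors(self, default_calib):
        close = default_calib.close_given_assoc
        assert d.logistic_eval(close, 0.0) == pytest.approx(0.975, abs=1e-9)
        assert 0.836 <= d.logistic_eval(close, 6.0) <= 0.838
        assert d.logistic_eval(close, 14.0) == pytest.approx(0.255, abs=0.01)

    def test_association_stays_near_constant_through_dependency(self, default_calib):
        assoc = default_calib.assoc
        assert np.all(assoc.prob(np.array([1.0, 2.0, 3.0])) >= 0.99)
        assert np.all(assoc.prob(np.array([4.0, 5.0, 6.0, 7.0])) >= 0.97 - 1e-12)

    def test_zero_slope_is_constant(self):
        curve = d.LogisticCurve(intercept=0.3, slope_age=0.0)
        ages = np.linspace(0, 15, 7)
        assert np.allclose(curve.prob(ages), curve.prob(0.0))

    @given(st.floats(min_value=0.0, max_value=15.0))
    def test_hierarchy_ordering_at_every_age(self, age):
        calib = d.default_calibration()
        p_assoc, p_close_g, p_peer_g = calib.state_probs(age)
        p_close = p_assoc * p_close_g
        p_peer = p_close * p_peer_g
        assert p_peer <= p_close <= p_assoc

    @given(st.floats(min_value=0.0, max_value=15.0))
    def test_close_exploration_dominates_distant(self, age):
        calib = d.default_calibration()
        assert calib.explore_close.prob(age) >= calib.explore_distant.prob(age)


def test_exploration_hump_shape():
    curve = d.ExplorationCurve(peak_age=2.0, peak_prob=0.2)
    assert curve.prob(0.0) == 0.0
    ages = np.linspace(0.01, 15, 400)
    assert curve.prob(2.0) == pytest.approx(0.2)
    assert np.max(curve.prob(ages)) <= 0.2 + 1e-12
    late = curve.prob(np.linspace(2.0, 15, 50))
    assert np.all(np.diff(late) < 0)
    with pytest.raises(ValueError):
        d.ExplorationCurve(peak_age=2.0, peak_prob=1.5)


def test_default_calibration_is_idempotent_and_serializes_losslessly():
    c1, c2 = d.default_calibration(), d.default_calibration()
    assert c1 == c2
    rt = d.CalibrationSet.from_dict(c1.to_dict())
    assert rt == c1


class TestLogisticFitter:
    def test_two_point_exact_fit(self):
        # logit(0.731) - logit(0.5) ~= 1 per year
        curve = d.fit_logistic_age_curve(
            ages=[0.0, 1.0], successes=[500, 731], trials=[1000, 1000]
        )
        assert curve.slope_age == pytest.approx(1.0, abs=0.01)

    def test_constant_half_rate_gives_null_curve(self):
        curve = d.fit_logistic_age_curve(
            ages=[0, 2, 4, 8], successes=[50, 50, 50, 50], trials=[100] * 4
        )
        assert curve.slope_age == pytest.approx(0.0, abs=1e-6)
        assert curve.intercept == pytest.approx(0.0, abs=1e-6)

    def test_single_age_is_rank_deficient(self):
        with pytest.raises(FitFailureError):
            d.fit_logistic_age_curve([3.0, 3.0], [5, 6], [10, 10])

    def test_complete_separation_warns(self):
        with pytest.warns(UserWarning, match="separation"):
            d.fit_logistic_age_curve(
                [0, 1, 2, 3], [100, 100, 0, 0], [100, 100, 100, 100]
            )

    def test_recovers_close_association_slope_at_field_scale(self):
        # truth: the close-association curve; ~30 individuals x 2,600 scans
        truth = d.LogisticCurve(3.664, -0.339)
        rng = np.random.default_rng(8)
        ages = rng.uniform(0, 15, 30 * 10)
        trials = np.full(ages.size, 260)
        successes = rng.binomial(trials, truth.prob(ages))
        fit = d.fit_logistic_age_curve(ages, successes, trials)
        assert fit.slope_age == pytest.approx(-0.339, abs=0.05)


class TestMichaelisMenten:
    def test_eval_half_saturation_origin_and_asymptote(self):
        fit = MMFit(vmax=248.0, k=1000.0)
        assert d.mm_eval(fit, 1000) == pytest.approx(124.0)
        assert d.mm_eval(fit, 0) == 0.0
        assert d.mm_eval(fit, 1e9) == pytest.approx(248.0, abs=0.001)
        n = np.array([10, 100, 1000, 10_000, 100_000])
        assert np.all(np.diff(d.mm_eval(fit, n)) > 0)

    def test_noiseless_recovery_within_one_item(self):
        truth = MMFit(vmax=248.0, k=5000.0)
        n = np.unique(np.logspace(1, 5.6, 30).astype(int))
        fit = d.fit_mm(n_scans=n, unique_items=d.mm_eval(truth, n))
        assert fit.vmax == pytest.approx(248.0, abs=1.0)
        assert fit.k == pytest.approx(5000.0, rel=0.01)

    def test_pooling_identical_individuals_changes_nothing(self):
        truth = MMFit(vmax=100.0, k=500.0)
        n = np.array([10, 100, 1000, 5000])
        y = d.mm_eval(truth, n)
        one = d.fit_mm(n_scans=n, unique_items=y)
        two = d.fit_mm(n_scans=np.tile(n, 2), unique_items=np.tile(y, 2))
        assert two.vmax == pytest.approx(one.vmax, rel=1e-6)
        assert two.k == pytest.approx(one.k, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            d.fit_mm(n_scans=[10, 10], unique_items=[3, 3])


@pytest.mark.parametrize(
    "vmax,fraction,expected", [(248, 0.9, 223), (248, 1.0, 248), (100, 0.5, 50)]
)
def test_adult_like_threshold_floor(vmax, fraction, expected):
    assert d.adult_like_threshold(vmax, fraction) == expected


def test_adult_like_threshold_rejects_bad_fraction():
    with pytest.raises(ValueError):
        d.adult_like_threshold(248, 0.0)


class TestPeeringEffect:
    def test_small_exact_counts(self):
        events = pd.DataFrame(
            {
                "age": [1, 2, 3, 4, 5, 6, 7, 8],
                "explored_before_1h": [True, True, False, False, False, False, False, False],
                "explored_after_1h": [False, False, True, True, True, False, True, True],
            }
        )
        eff = d.estimate_peering_effect(events)
        assert eff.p_before == pytest.approx(2 / 8)
        assert eff.p_after == pytest.approx(5 / 6)  # over the 6 no-prior events
        assert eff.ci_after[0] < eff.p_after < eff.ci_after[1]

    def test_all_prior_explored_is_degenerate(self):
        events = pd.DataFrame(
            {
                "age": [1.0, 2.0],
                "explored_before_1h": [True, True],
                "explored_after_1h": [True, False],
            }
        )
        with pytest.raises(FitFailureError):
            d.estimate_peering_effect(events)


class TestTuner:
    def test_self_consistency_recovers_known_targets(self, default_calib):
        # targets generated from known parameters must be re-attained when
        # tuning restarts from a perturbed calibration (same seeds)
        from dataclasses import replace

        env = small_uniform_env(n_items=30, complexity=5, patch_mean=0.5)
        config_seed = 77
        targets = []
        cfg = d.SimulationConfig(years=3, independence_age=2, cohort_size=12)
        for tr in d.TREATMENTS:
            trajs = d.run_cohort(env, default_calib, tr, cfg, config_seed)
            targets.append(float(np.mean([d.repertoire_at_age(t, 3.0) for t in trajs])))

        start = replace(
            default_calib,
            explore_distant=replace(default_calib.explore_distant, peak_prob=0.02),
            explore_close=replace(default_calib.explore_close, peak_prob=0.05),
            peer_given_close=replace(default_calib.peer_given_close, intercept=-4.0),
        )
        result = d.tune_free_parameters(
            env,
            start,
            targets=tuple(targets),
            cohort_size=12,
            master_seed=config_seed,
            milestone_age=3.0,
        )
        assert isinstance(result, TuningResult)
        for achieved, target in zip(result.achieved, result.targets):
            assert achieved == pytest.approx(target, abs=1.5)

    def test_peering_insensitivity_is_flagged(self, default_calib):
        env = small_uniform_env(n_items=10, complexity=0, patch_mean=5.0)
        no_peer_anywhere = (d.EXPOSURE_ONLY, d.EXPOSURE_ONLY, d.EXPOSURE_ONLY)
        with pytest.warns(UserWarning, match="insensitive"):
            result = d.tune_free_parameters(
                env,
                default_calib,
                targets=(5.0, 5.0, 5.0),
                treatments=no_peer_anywhere,
                cohort_size=8,
                master_seed=3,
                milestone_age=2.0,
            )
        assert not all(result.identifiable)
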