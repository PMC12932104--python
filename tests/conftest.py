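import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dietabm as d

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_env() -> d.Environment:
    return d.default_environment()


@pytest.fixture(scope="session")
def default_calib() -> d.CalibrationSet:
    return d.default_calibration()


@pytest.fixture(scope="session")
def treatment_cohorts(default_env, default_calib):
    """The three treatment cohorts at full published scale (250 immatures
    each, 15 years, independent master seeds), shared by the milestone and
    exposure analyses."""
    config = d.SimulationConfig(cohort_size=250)
    return {
        tr.name: d.run_cohort(default_env, default_calib, tr, config, 101 + i)
        for i, tr in enumerate(d.TREATMENTS)
    }


@pytest.fixture(scope="session")
def coupled_cohorts(default_env, default_calib):
    """Three 100-immature cohorts sharing one master seed: identical
    patch/uniform streams make treatment comparisons pathwise-coupled,
    which is the right construction for stochastic-ordering checks."""
    config = d.SimulationConfig(cohort_size=100)
    return {
        tr.name: d.run_cohort(default_env, default_calib, tr, config, 55)
        for tr in d.TREATMENTS
    }


def small_uniform_env(n_items: int = 20, complexity: int = 0, patch_mean: float = 27.0):
    """Tiny uniform environment with a single complexity rank everywhere."""
    items = [
        d.FoodItem(item_id=i, label=f"item-{i}", complexity=complexity,
                   encounter_prob=1.0 / n_items)
        for i in range(n_items)
    ]
    return d.Environment(items=items, daily_patch_mean=patch_mean)


def constant_calibration(
    p_assoc=0.5, p_close=0.5, p_peer=0.5, p_explore=0.5
) -> d.CalibrationSet:
    """Age-independent calibration for degenerate-case tests."""
    return d.CalibrationSet(
        assoc=d.ConstantCurve(p_assoc),
        close_given_assoc=d.ConstantCurve(p_close),
        peer_given_close=d.ConstantCurve(p_peer),
        explore_distant=d.ConstantCurve(p_explore),
        explore_close=d.ConstantCurve(p_explore),
        explore_after_peer=d.ConstantCurve(p_explore),
    )
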