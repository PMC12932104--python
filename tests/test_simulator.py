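"""Per-patch state machine, vectorized daily loop, cohort reproducibility."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietabm as d

from conftest import constant_calibration, small_uniform_env


class TestSocialStateAssignment:
    def test_exposure_only_never_reaches_close_or_peering(self, default_calib):
        rng = np.random.default_rng(0)
        states = {
            d.assign_social_state(age, default_calib, d.EXPOSURE_ONLY, rng)
            for age in np.linspace(0, 15, 40)
            for _ in range(25)
        }
        assert states <= {d.SocialState.ALONE, d.SocialState.DISTANT}

    def test_certain_curves_force_peering(self):
        calib = constant_calibration(1.0, 1.0, 1.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            assert d.assign_social_state(2.0, calib, d.FULL, rng) == d.SocialState.PEERING

    def test_infants_are_nearly_always_accompanied(self, default_calib):
        rng = np.random.default_rng(2)
        draws = 20_000
        alone = sum(
            d.assign_social_state(2.0, default_calib, d.FULL, rng) == d.SocialState.ALONE
            for _ in range(draws)
        )
        assert 1 - alone / draws >= 0.99


class TestExplorationProbability:
    def test_alone_rate_equals_distant_rate(self, default_calib):
        for age in np.linspace(0, 15, 31):
            assert d.exploration_probability(
                d.SocialState.ALONE, age, default_calib
            ) == d.exploration_probability(d.SocialState.DISTANT, age, default_calib)

    def test_post_peering_anchor_at_mid_dependency(self, default_calib):
        p = d.exploration_probability(d.SocialState.PEERING, 4.5, default_calib)
        assert p == pytest.approx(0.677, abs=0.005)

    def test_close_dominates_distant_and_rates_interior(self, default_calib):
        ages = np.linspace(0.01, 15, 61)
        for age in ages:
            p_d = d.exploration_probability(d.SocialState.DISTANT, age, default_calib)
            p_c = d.exploration_probability(d.SocialState.CLOSE, age, default_calib)
            assert 0.0 < p_d <= p_c < 1.0


class TestStepPatch:
    def test_known_item_feeds_without_counter_change(self, default_env, default_calib):
        agent = d.AgentState(age_days=700, repertoire={3}, exploration_counts={3: 1})
        rng = np.random.default_rng(0)
        assert d.step_patch(agent, 3, d.SocialState.CLOSE, default_env, default_calib, rng) == "feed"
        assert agent.exploration_counts == {3: 1}

    def test_simple_item_learned_in_one_forced_exploration(self, default_calib):
        env = small_uniform_env(n_items=4, complexity=0)
        calib = constant_calibration(p_explore=1.0)
        agent = d.AgentState(age_days=700)
        out = d.step_patch(agent, 2, d.SocialState.DISTANT, env, calib, np.random.default_rng(0))
        assert out == "explore" and 2 in agent.repertoire

    def test_tool_assisted_item_needs_four_explorations(self, default_calib):
        env = small_uniform_env(n_items=4, complexity=5)
        calib = constant_calibration(p_explore=1.0)
        agent = d.AgentState(age_days=700)
        rng = np.random.default_rng(0)
        for _ in range(3):
            d.step_patch(agent, 1, d.SocialState.CLOSE, env, calib, rng)
        assert 1 not in agent.repertoire
        d.step_patch(agent, 1, d.SocialState.CLOSE, env, calib, rng)
        assert 1 in agent.repertoire

    def test_unknown_item_id_rejected(self, default_env, default_calib):
        with pytest.raises(ValueError):
            d.step_patch(
                d.AgentState(), 999, d.SocialState.ALONE, default_env, default_calib,
                np.random.default_rng(0),
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25)
    def test_repertoire_and_counters_stay_consistent(self, seed):
        """After every patch: repertoire == items whose counters reached
        their threshold, and the repertoire never shrinks."""
        env = small_uniform_env(n_items=6, complexity=3)
        calib = constant_calibration(p_explore=0.5)
        rng = np.random.default_rng(seed)
        agent = d.AgentState(age_days=365)
        prev_size = 0
        for _ in range(200):
            item = int(env.draw_items(rng, 1)[0])
            d.step_patch(agent, item, d.SocialState.DISTANT, env, calib, rng)
            expected = {
                i for i, c in agent.exploration_counts.items()
                if c >= int(env.thresholds[i])
            }
            assert agent.repertoire == expected
            assert len(agent.repertoire) >= prev_size
            prev_size = len(agent.repertoire)


class TestSimulateImmature:
    def test_equals_set_union_oracle_on_shared_stream(self):
        """With exploration == 1 and thresholds == 1, learning is exactly
        first encounter: the simulator must equal a brute-force
        distinct-set oracle replaying the same seeded stream."""
        env = small_uniform_env(n_items=25, complexity=0)
        calib = constant_calibration(p_explore=1.0)
        config = d.SimulationConfig(years=3, independence_age=2, cohort_size=1)
        seed = 123
        traj = d.simulate_immature(env, calib, d.FULL, config, np.random.default_rng(seed))

        rng = np.random.default_rng(seed)
        counts = rng.poisson(env.daily_patch_mean, config.n_days)
        items = env.draw_items(rng, int(counts.sum()))
        seen: set[int] = set()
        expected = np.empty(config.n_days, dtype=int)
        pos = 0
        for day, n in enumerate(counts):
            seen.update(items[pos : pos + n].tolist())
            expected[day] = len(seen)
            pos += n
        assert np.array_equal(traj.repertoire_size_by_day, expected)

    def test_no_exploration_means_no_diet(self, default_env):
        calib = constant_calibration(p_explore=0.0)
        config = d.SimulationConfig()
        traj = d.simulate_immature(
            default_env, calib, d.FULL, config, np.random.default_rng(0)
        )
        assert traj.final_size == 0
        assert traj.event_tallies["explore"] == 0
        assert traj.event_tallies["feed"] == 0

    def test_trajectory_monotone_and_bounded(self, default_env, default_calib):
        config = d.SimulationConfig()
        traj = d.simulate_immature(
            default_env, default_calib, d.FULL, config, np.random.default_rng(9)
        )
        series = traj.repertoire_size_by_day
        assert len(series) == 5475
        assert np.all(np.diff(series) >= 0)
        assert series[-1] <= default_env.n_items
        tallies = traj.event_tallies
        assert tallies["feed"] + tallies["explore"] + tallies["ignore"] == tallies["patches"]
        assert (
            tallies["alone"] + tallies["distant"] + tallies["close"] + tallies["peering"]
            == tallies["patches"]
        )


class TestRunCohort:
    def test_same_master_seed_reproduces_everything(self, default_calib):
        env = small_uniform_env(n_items=10)
        config = d.SimulationConfig(years=2, independence_age=1, cohort_size=4)
        a = d.run_cohort(env, default_calib, d.FULL, config, 42)
        b = d.run_cohort(env, default_calib, d.FULL, config, 42)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.repertoire_size_by_day, tb.repertoire_size_by_day)
            assert ta.event_tallies == tb.event_tallies

    def test_agents_depend_only_on_master_seed_and_index(self, default_calib):
        env = small_uniform_env(n_items=10)
        small = d.SimulationConfig(years=2, independence_age=1, cohort_size=3)
        big = d.SimulationConfig(years=2, independence_age=1, cohort_size=6)
        a = d.run_cohort(env, default_calib, d.FULL, small, 7)
        b = d.run_cohort(env, default_calib, d.FULL, big, 7)
        for ta, tb in zip(a, b[:3]):
            assert np.array_equal(ta.repertoire_size_by_day, tb.repertoire_size_by_day)

    def test_agents_use_disjoint_streams(self, default_calib):
        env = small_uniform_env(n_items=10)
        config = d.SimulationConfig(years=2, independence_age=1, cohort_size=6)
        trajs = d.run_cohort(env, default_calib, d.FULL, config, 5)
        tallies = [tuple(sorted(t.event_tallies.items())) for t in trajs]
        assert len(set(tallies)) == len(tallies)

    def test_patch_scaling_with_daily_mean(self, default_calib):
        """Expected encounters scale linearly with the daily patch mean."""
        env = small_uniform_env(n_items=10)
        config = d.SimulationConfig(years=2, independence_age=1, cohort_size=30)
        halved = d.Treatment("half", False, False, daily_patch_mean=13.5)
        full = d.run_cohort(env, default_calib, d.EXPOSURE_ONLY, config, 11)
        half = d.run_cohort(env, default_calib, halved, config, 11)
        m_full = np.mean([t.event_tallies["patches"] for t in full])
        m_half = np.mean([t.event_tallies["patches"] for t in half])
        assert m_half / m_full == pytest.approx(0.5, abs=0.02)


def test_treatment_ordering_at_every_age(coupled_cohorts):
    """Mean repertoire: full >= no-peering >= exposure-only at every
    recorded day (pathwise-coupled cohorts of 100)."""
    means = {
        name: np.mean([t.repertoire_size_by_day for t in trajs], axis=0)
        for name, trajs in coupled_cohorts.items()
    }
    full = means["exposure_enhancement_peering"]
    nopeer = means["exposure_enhancement"]
    exponly = means["exposure_only"]
    assert np.all(full >= nopeer)
    assert np.all(nopeer >= exponly)
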