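"""The daily-loop agent-based model of diet-repertoire development.

One simulated immature is followed from birth to the end of immaturity
(15 years of 365 days).  Each day it visits a Poisson number of feeding
patches, each holding one food item.  At every patch the immature is
assigned a social state through a hierarchy of Bernoulli decisions —
associated? close? peering? — whose probabilities are age-dependent
logistic curves; treatments remove forms of social learning by forcing
the corresponding branch to fail.  Unknown items are explored with a
probability set by age and social state; once an item has been explored
as many times as its processing complexity requires, it enters the diet
repertoire permanently.  Known items are simply fed on.

`simulate_immature` runs a vectorized implementation of this process
with a documented random-draw order so that brute-force oracles can
replay the exact stream; `assign_social_state` / `step_patch` expose the
equivalent per-patch state machine for direct inspection and property
testing.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .calibration import CalibrationSet
from .environment import Environment

__all__ = [
    "SocialState",
    "Treatment",
    "AgentState",
    "Trajectory",
    "SimulationConfig",
    "FULL",
    "NO_PEERING",
    "EXPOSURE_ONLY",
    "TREATMENTS",
    "assign_social_state",
    "exploration_probability",
    "step_patch",
    "simulate_immature",
    "run_cohort",
]


class SocialState(IntEnum):
    ALONE = 0
    DISTANT = 1
    CLOSE = 2
    PEERING = 3


@dataclass(frozen=True)
class Treatment:
    """Which forms of social learning are available to the cohort.

    Exposure (being led to feeding patches) is always present; peering
    and close association (enhancement) can be switched off, which
    forces the corresponding branch of the social-state hierarchy to
    fail while leaving every other curve untouched.  ``daily_patch_mean``
    overrides the environment's daily patch mean when set (used by the
    exposure-gradient sweep); the three standard treatments inherit the
    environment's mean of 27.
    """

    name: str
    allow_peering: bool
    allow_close: bool
    daily_patch_mean: float | None = None

    def effective_patch_mean(self, env: Environment) -> float:
        return (
            self.daily_patch_mean
            if self.daily_patch_mean is not None
            else env.daily_patch_mean
        )


FULL = Treatment("exposure_enhancement_peering", True, True)
NO_PEERING = Treatment("exposure_enhancement", False, True)
EXPOSURE_ONLY = Treatment("exposure_only", False, False)
TREATMENTS = (FULL, NO_PEERING, EXPOSURE_ONLY)


@dataclass
class AgentState:
    """Mutable per-agent learning state (used by the scalar state machine)."""

    age_days: int = 0
    exploration_counts: dict[int, int] = field(default_factory=dict)
    repertoire: set[int] = field(default_factory=set)


@dataclass
class SimulationConfig:
    years: int = 15
    days_per_year: int = 365
    independence_age: int = 9
    cohort_size: int = 250
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.years < 1 or self.days_per_year < 1:
            raise ValueError("years and days_per_year must be >= 1")
        if not (0 <= self.independence_age < self.years):
            raise ValueError("independence_age must lie within the simulated span")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")

    @property
    def n_days(self) -> int:
        return self.years * self.days_per_year


@dataclass
class Trajectory:
    """One immature's simulated development.

    ``repertoire_size_by_day[d-1]`` is the repertoire size at the end of
    day ``d`` (non-decreasing, bounded by the item universe);
    ``event_tallies`` counts patches, feeding/exploration/ignore events
    and time spent in each social state.
    """

    repertoire_size_by_day: np.ndarray
    event_tallies: dict[str, int]
    seed: int
    days_per_year: int = 365

    @property
    def n_days(self) -> int:
        return len(self.repertoire_size_by_day)

    @property
    def final_size(self) -> int:
        return int(self.repertoire_size_by_day[-1]) if self.n_days else 0


def assign_social_state(
    age: float,
    calib: CalibrationSet,
    treatment: Treatment,
    rng: np.random.Generator,
) -> SocialState:
    """Draw one patch's social state through the decision hierarchy:
    associated? → close? → peering?, with removed forms of social
    learning forcing their branch to fail."""
    if float(rng.random()) >= float(calib.assoc.prob(age)):
        return SocialState.ALONE
    p_close = float(calib.close_given_assoc.prob(age)) if treatment.allow_close else 0.0
    if float(rng.random()) >= p_close:
        return SocialState.DISTANT
    p_peer = float(calib.peer_given_close.prob(age)) if treatment.allow_peering else 0.0
    if float(rng.random()) >= p_peer:
        return SocialState.CLOSE
    return SocialState.PEERING


def exploration_probability(
    state: SocialState, age: float, calib: CalibrationSet
) -> float:
    """Probability of exploring an unknown item, given age and social state.

    The alone rate equals the distant-association rate: an alone-specific
    rate cannot be estimated from field data because dependent immatures
    are essentially never observed alone.
    """
    if state in (SocialState.ALONE, SocialState.DISTANT):
        return float(calib.explore_distant.prob(age))
    if state == SocialState.CLOSE:
        return float(calib.explore_close.prob(age))
    if state == SocialState.PEERING:
        return float(calib.explore_after_peer.prob(age))
    raise ValueError(f"unknown social state {state!r}")


def step_patch(
    agent: AgentState,
    item_id: int,
    state: SocialState,
    env: Environment,
    calib: CalibrationSet,
    rng: np.random.Generator,
) -> str:
    """Process one feeding patch for the scalar state machine.

    Known item → ``"feed"`` (no counter change).  Unknown item →
    Bernoulli(exploration probability) decides ``"explore"`` (counter
    increments; the item joins the repertoire when the counter reaches
    its complexity threshold) versus ``"ignore"``.
    """
    if not (0 <= item_id < env.n_items):
        raise ValueError(f"item_id {item_id} not in environment")
    if item_id in agent.repertoire:
        return "feed"
    age = agent.age_days / 365.0
    p = exploration_probability(state, age, calib)
    if float(rng.random()) < p:
        count = agent.exploration_counts.get(item_id, 0) + 1
        agent.exploration_counts[item_id] = count
        if count >= int(env.thresholds[item_id]):
            agent.repertoire.add(item_id)
        return "explore"
    return "ignore"


def simulate_immature(
    env: Environment,
    calib: CalibrationSet,
    treatment: Treatment,
    config: SimulationConfig,
    rng: np.random.Generator,
    seed_label: int = -1,
) -> Trajectory:
    """Simulate one immature from birth to the end of the configured span.

    Vectorized but stream-equivalent to a per-patch process with the
    following fixed draw order from ``rng``:

    1. ``poisson(daily_patch_mean, n_days)`` — patch count per day;
    2. one uniform per patch → item id (inverse CDF, ``env.draw_items``);
    3. three uniforms per patch → association / close / peering branches;
    4. one uniform per patch → exploration decision.

    The exploration uniform is drawn for every patch and simply ignored
    when the item is already known, which leaves the learning dynamics
    identical to the sequential state machine (counters only matter up
    to the learning threshold, and known items never revert).
    """
    n_days = config.n_days
    counts = rng.poisson(treatment.effective_patch_mean(env), n_days)
    total = int(counts.sum())
    items = env.draw_items(rng, total)
    u_assoc = rng.random(total)
    u_close = rng.random(total)
    u_peer = rng.random(total)
    u_explore = rng.random(total)

    day_age = np.arange(1, n_days + 1, dtype=float) / config.days_per_year
    p_assoc_d = np.asarray(calib.assoc.prob(day_age), dtype=float)
    p_close_d = (
        np.asarray(calib.close_given_assoc.prob(day_age), dtype=float)
        if treatment.allow_close
        else np.zeros(n_days)
    )
    p_peer_d = (
        np.asarray(calib.peer_given_close.prob(day_age), dtype=float)
        if treatment.allow_peering
        else np.zeros(n_days)
    )
    p_dist_expl_d = np.asarray(calib.explore_distant.prob(day_age), dtype=float)
    p_close_expl_d = np.asarray(calib.explore_close.prob(day_age), dtype=float)
    p_peer_expl_d = np.asarray(calib.explore_after_peer.prob(day_age), dtype=float)

    day_of_patch = np.repeat(np.arange(n_days), counts)  # 0-based day index
    assoc = u_assoc < p_assoc_d[day_of_patch]
    close = assoc & (u_close < p_close_d[day_of_patch])
    peer = close & (u_peer < p_peer_d[day_of_patch])
    state = assoc.astype(np.int8) + close + peer  # 0..3 == SocialState values

    p_explore = p_dist_expl_d[day_of_patch]
    p_explore = np.where(state == SocialState.CLOSE, p_close_expl_d[day_of_patch], p_explore)
    p_explore = np.where(state == SocialState.PEERING, p_peer_expl_d[day_of_patch], p_explore)
    explored = u_explore < p_explore

    # Learning: for each item, the patch at which its cumulative count of
    # exploration successes reaches the item's threshold is the learning
    # event (draws at already-known patches never matter: the cumulative
    # count crosses the threshold exactly once).
    order = np.argsort(items, kind="stable")
    items_sorted = items[order]
    expl_sorted = explored[order].astype(np.int64)
    cum = np.cumsum(expl_sorted)
    group_start = np.searchsorted(items_sorted, np.arange(env.n_items), side="left")
    group_end = np.searchsorted(items_sorted, np.arange(env.n_items), side="right")
    present = group_start < group_end
    starts = group_start[present]
    offsets = np.where(starts > 0, cum[starts - 1], 0)
    # within-group cumulative = cum - explorations recorded before the group
    offset_per_item = np.zeros(env.n_items, dtype=np.int64)
    offset_per_item[present] = offsets
    within_cum = cum - offset_per_item[items_sorted]
    thresholds_sorted = env.thresholds[items_sorted]
    hit = (expl_sorted == 1) & (within_cum == thresholds_sorted)

    learn_patch_sortedpos = np.flatnonzero(hit)
    learn_items = items_sorted[learn_patch_sortedpos]
    learn_patch = order[learn_patch_sortedpos]
    learn_day = day_of_patch[learn_patch]

    repertoire_by_day = np.cumsum(
        np.bincount(learn_day, minlength=n_days)
    ).astype(np.int64)

    # Event labels: a patch is "feeding" iff its item was learned at an
    # earlier patch (patch order == chronological order within the day
    # sequence, and `order` is stable, so sorted position order preserves
    # chronology within each item group).
    learn_pos_per_item = np.full(env.n_items, np.iinfo(np.int64).max, dtype=np.int64)
    learn_pos_per_item[learn_items] = learn_patch_sortedpos
    pos_sorted = np.arange(total)
    known_sorted = pos_sorted > learn_pos_per_item[items_sorted]
    known = np.empty(total, dtype=bool)
    known[order] = known_sorted

    n_feed = int(np.count_nonzero(known))
    n_explore = int(np.count_nonzero(explored & ~known))
    n_ignore = total - n_feed - n_explore

    tallies = {
        "patches": total,
        "feed": n_feed,
        "explore": n_explore,
        "ignore": n_ignore,
        "alone": int(np.count_nonzero(state == SocialState.ALONE)),
        "distant": int(np.count_nonzero(state == SocialState.DISTANT)),
        "close": int(np.count_nonzero(state == SocialState.CLOSE)),
        "peering": int(np.count_nonzero(state == SocialState.PEERING)),
    }
    return Trajectory(
        repertoire_size_by_day=repertoire_by_day,
        event_tallies=tallies,
        seed=seed_label,
        days_per_year=config.days_per_year,
    )


def run_cohort(
    env: Environment,
    calib: CalibrationSet,
    treatment: Treatment,
    config: SimulationConfig,
    master_seed: int,
) -> list[Trajectory]:
    """Run ``config.cohort_size`` independent immatures.

    Agent ``i`` uses the substream ``SeedSequence(master_seed).spawn()[i]``,
    so its trajectory depends only on ``(master_seed, i)`` and cohorts are
    reproducible regardless of execution order.
    """
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(config.cohort_size)
    return [
        simulate_immature(
            env,
            calib,
            treatment,
            config,
            np.random.default_rng(child),
            seed_label=i,
        )
        for i, child in enumerate(children)
    ]
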