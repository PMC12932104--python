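"""Food-item universe and daily feeding-patch generation.

The simulated habitat is a fixed universe of food items (262 by default,
matching the number of distinct items recorded at Suaq Balimbing), each
carrying an encounter probability and a processing-complexity rank from 0
(eaten whole) to 5 (tool-assisted processing).  A foraging day consists of
a Poisson number of feeding patches (mean 27, the observed daily patch
count of mothers), and each patch contains exactly one food item drawn
i.i.d. from the encounter distribution.

The field encounter-frequency table is deposited externally; the default
environment built here uses a rank power-law for encounter probabilities
whose tail exponent is calibrated so that an adult-scale accumulation
curve, fitted with the Michaelis–Menten estimator, plateaus at the
published adult repertoire asymptote (248 of 262 items).  A CSV loader
accepts the real table when available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FoodItem",
    "Environment",
    "threshold_for_complexity",
    "sample_daily_patches",
    "build_default_environment",
    "default_environment",
    "calibrate_tail_exponent",
    "load_food_table",
    "save_food_table",
    "COMPLEXITY_THRESHOLDS",
    "DEFAULT_N_ITEMS",
    "DEFAULT_PATCH_MEAN",
    "DEFAULT_TAIL_EXPONENT",
    "DEFAULT_COMPLEXITY_MIX",
]

#: Explorations required to learn a food item, by processing-complexity rank.
#: Items eaten whole (rank 0) need a single exploration; each two steps of
#: added complexity cost one further exploration.
COMPLEXITY_THRESHOLDS: dict[int, int] = {0: 1, 1: 2, 2: 2, 3: 3, 4: 3, 5: 4}

DEFAULT_N_ITEMS = 262
DEFAULT_PATCH_MEAN = 27.0

#: Rank power-law exponent of the default encounter distribution, calibrated
#: (analysis/01_calibrate_environment.py) so the Michaelis–Menten asymptote
#: fitted to adult-scale accumulation data (95 adults x ~4,232 draws) is
#: 248 items.
DEFAULT_TAIL_EXPONENT = 1.3583

#: Default proportions of items in complexity categories 0..5.  The true
#: category mix of the 262 items is not published; this mix makes simple
#: items common and tool-assisted items rare, and is config-overridable.
DEFAULT_COMPLEXITY_MIX = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04)

#: Fixed stream for the canonical default environment build, so that the
#: packaged exploration parameters always refer to the same item universe.
_DEFAULT_ENV_SEED = 20_240_727


class NoSolutionError(RuntimeError):
    """Raised when a calibration target cannot be attained."""


def threshold_for_complexity(complexity: int) -> int:
    """Number of explorations an immature needs to learn an item of the
    given processing-complexity rank (0–5)."""
    if isinstance(complexity, bool) or not isinstance(complexity, (int, np.integer)):
        raise ValueError(f"complexity must be an integer in 0..5, got {complexity!r}")
    if complexity not in COMPLEXITY_THRESHOLDS:
        raise ValueError(f"complexity must be in 0..5, got {complexity}")
    return COMPLEXITY_THRESHOLDS[int(complexity)]


@dataclass(frozen=True)
class FoodItem:
    """One consumable item: a species/part combination with an encounter
    probability and a processing-complexity rank."""

    item_id: int
    label: str
    complexity: int
    encounter_prob: float
    required_explorations: int = -1  # filled from complexity if unset

    def __post_init__(self) -> None:
        if self.complexity not in COMPLEXITY_THRESHOLDS:
            raise ValueError(f"complexity {self.complexity} outside 0..5")
        if not (0.0 < self.encounter_prob <= 1.0):
            raise ValueError(
                f"encounter_prob must be in (0, 1], got {self.encounter_prob}"
            )
        expected = threshold_for_complexity(self.complexity)
        if self.required_explorations == -1:
            object.__setattr__(self, "required_explorations", expected)
        elif self.required_explorations != expected:
            raise ValueError(
                "required_explorations inconsistent with complexity rank: "
                f"{self.required_explorations} != {expected}"
            )


@dataclass
class Environment:
    """The food-item universe plus the daily patch-count distribution."""

    items: list[FoodItem]
    daily_patch_mean: float = DEFAULT_PATCH_MEAN

    # cached arrays for the vectorized simulator
    _probs: np.ndarray = field(init=False, repr=False)
    _cumprobs: np.ndarray = field(init=False, repr=False)
    _thresholds: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("environment needs at least one food item")
        if self.daily_patch_mean <= 0:
            raise ValueError("daily_patch_mean must be positive")
        probs = np.array([it.encounter_prob for it in self.items], dtype=float)
        total = probs.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"encounter probabilities sum to {total}, not 1")
        self._probs = probs
        self._cumprobs = np.cumsum(probs)
        self._cumprobs[-1] = 1.0  # guard against rounding at the top end
        self._thresholds = np.array(
            [it.required_explorations for it in self.items], dtype=np.int64
        )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def encounter_probs(self) -> np.ndarray:
        """Encounter probability per item_id (read-only view)."""
        v = self._probs.view()
        v.flags.writeable = False
        return v

    @property
    def thresholds(self) -> np.ndarray:
        """Explorations-to-learn per item_id (read-only view)."""
        v = self._thresholds.view()
        v.flags.writeable = False
        return v

    def draw_items(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` item ids i.i.d. from the encounter distribution.

        Uses inverse-CDF sampling on a single block of uniforms; the
        simulator and all data generators share this routine so that
        oracle tests can replay the exact stream.
        """
        if n == 0:
            return np.empty(0, dtype=np.int64)
        u = rng.random(n)
        return np.searchsorted(self._cumprobs, u, side="right").astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [it.item_id for it in self.items],
                "label": [it.label for it in self.items],
                "complexity": [it.complexity for it in self.items],
                "encounter_prob": [it.encounter_prob for it in self.items],
            }
        )


def sample_daily_patches(env: Environment, rng: np.random.Generator) -> np.ndarray:
    """One day of feeding patches: a Poisson(daily_patch_mean) number of
    item ids drawn from the encounter distribution (repeats allowed; an
    empty day is valid)."""
    n = int(rng.poisson(env.daily_patch_mean))
    return env.draw_items(rng, n)


def _rank_power_probs(n_items: int, tail_exponent: float) -> np.ndarray:
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    if tail_exponent < 0:
        raise ValueError("tail_exponent must be >= 0")
    ranks = np.arange(1, n_items + 1, dtype=float)
    w = ranks ** (-tail_exponent)
    return w / w.sum()


def _complexity_counts(n_items: int, mix) -> np.ndarray:
    """Largest-remainder apportionment of n_items across the six categories."""
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (6,):
        raise ValueError("complexity_mix must have six proportions")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("complexity_mix must sum to 1")
    raw = mix * n_items
    counts = np.floor(raw).astype(int)
    remainder = n_items - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def build_default_environment(
    n_items: int = DEFAULT_N_ITEMS,
    tail_exponent: float = DEFAULT_TAIL_EXPONENT,
    complexity_mix=DEFAULT_COMPLEXITY_MIX,
    rng: np.random.Generator | None = None,
    daily_patch_mean: float = DEFAULT_PATCH_MEAN,
    rarity_bias_sd: float = 0.15,
) -> Environment:
    """Build the synthetic stand-in for the field food table.

    Encounter probabilities follow a rank power-law ``p_r ∝ r^(-s)``;
    complexity is assigned rarity-biased (rarer items tend to carry higher
    complexity ranks, reflecting that complex foods are rarely
    encountered), with a noisy rank so the association is strong but not
    degenerate.  Deterministic for a given seeded ``rng``.

    ``rarity_bias_sd`` is the s.d. of the rank noise, as a fraction of
    ``n_items``.
    """
    if rng is None:
        rng = np.random.default_rng(_DEFAULT_ENV_SEED)
    probs = _rank_power_probs(n_items, tail_exponent)
    counts = _complexity_counts(n_items, complexity_mix)
    # complexity labels ordered low→high, handed out along a noisy rarity rank
    labels = np.repeat(np.arange(6), counts)
    noisy_rank = np.arange(n_items) + rng.normal(0.0, rarity_bias_sd * n_items, n_items)
    complexity = np.empty(n_items, dtype=int)
    complexity[np.argsort(noisy_rank)] = labels
    items = [
        FoodItem(
            item_id=i,
            label=f"item-{i:03d}",
            complexity=int(complexity[i]),
            encounter_prob=float(probs[i]),
        )
        for i in range(n_items)
    ]
    return Environment(items=items, daily_patch_mean=daily_patch_mean)


def default_environment() -> Environment:
    """The canonical packaged environment (fixed build stream), to which
    the packaged calibration defaults refer."""
    return build_default_environment()


def calibrate_tail_exponent(
    target_vmax: float = 248.0,
    n_items: int = DEFAULT_N_ITEMS,
    n_adults: int = 95,
    scans_per_adult: int = 4232,
    rng: np.random.Generator | None = None,
    bracket: tuple[float, float] = (0.0, 3.0),
    tol: float = 1e-3,
    max_iter: int = 40,
) -> float:
    """Find the rank power-law exponent whose environment yields a fitted
    Michaelis–Menten asymptote of ``target_vmax`` items at adult-scale
    sampling effort (default: 95 adults x 4,232 draws each, the field
    effort of 402,082 scans split across adults).

    Bisection over the exponent; the fitted Vmax is a decreasing function
    of the exponent (a heavier tail hides more items from the sample).
    Common random numbers are used across evaluations so the bracketing
    function is deterministic.
    """
    from .calibration import fit_mm
    from .synthetic_data import generate_accumulation_data

    if target_vmax > n_items:
        raise NoSolutionError(
            f"target_vmax {target_vmax} exceeds the {n_items}-item universe"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    eval_seed = int(rng.integers(0, 2**31))

    def fitted_vmax(exponent: float) -> float:
        env = build_default_environment(
            n_items=n_items,
            tail_exponent=exponent,
            rng=np.random.default_rng(_DEFAULT_ENV_SEED),
        )
        data = generate_accumulation_data(
            env, n_adults=n_adults, scans_per_adult=scans_per_adult,
            rng=np.random.default_rng(eval_seed),
        )
        return fit_mm(data).vmax

    lo, hi = bracket
    v_lo = fitted_vmax(lo)
    if v_lo < target_vmax - 0.5:
        raise NoSolutionError(
            f"even a flat distribution reaches only Vmax={v_lo:.1f} "
            f"< target {target_vmax} at this sampling effort"
        )
    v_hi = fitted_vmax(hi)
    if v_hi > target_vmax:
        raise NoSolutionError(
            f"upper bracket exponent {hi} still gives Vmax={v_hi:.1f} "
            f"> target {target_vmax}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if fitted_vmax(mid) > target_vmax:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def load_food_table(path, daily_patch_mean: float = DEFAULT_PATCH_MEAN) -> Environment:
    """Load a food table CSV (columns item_id,label,complexity,encounter_prob).

    Probabilities are renormalized on load; a warning is emitted if they
    were off by more than 1e-6.
    """
    df = pd.read_csv(path)
    required = {"item_id", "label", "complexity", "encounter_prob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"food table missing columns: {sorted(missing)}")
    total = float(df["encounter_prob"].sum())
    if abs(total - 1.0) > 1e-6:
        warnings.warn(
            f"encounter probabilities sum to {total:.8f}; renormalizing",
            stacklevel=2,
        )
    probs = df["encounter_prob"].to_numpy(dtype=float) / total
    items = [
        FoodItem(
            item_id=int(r.item_id),
            label=str(r.label),
            complexity=int(r.complexity),
            encounter_prob=float(p),
        )
        for r, p in zip(df.itertuples(index=False), probs)
    ]
    return Environment(items=items, daily_patch_mean=daily_patch_mean)


def save_food_table(env: Environment, path) -> None:
    env.to_frame().to_csv(path, index=False)
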