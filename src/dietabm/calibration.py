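"""Age-dependent probability curves and the estimators behind them.

Three kinds of quantity live here:

* The curves that drive the simulator — logistic curves in age for the
  social-state hierarchy (association, close association given
  association, peering given close association) and for exploration
  after peering, plus a parametric hump for the baseline exploration
  rate in distant/close association.
* Fitters that estimate those curves from (synthetic) focal-follow data:
  a trial-weighted binomial logistic fit, the before/after peering-effect
  estimator, and a pooled Michaelis–Menten fit for adult repertoire
  asymptotes.
* The tuner for the three curve magnitudes that are not published
  anywhere (both exploration peak heights and the peering intercept),
  identified against the three published treatment means at the
  independence milestone.

Slopes of the logistic curves are the published mixed-model age
coefficients (association −0.4, close association −0.339, peering −0.12,
post-peering exploration +0.12 on the log-odds scale per year); the
fitters here are weighted fixed-effects binomial fits — random effects
are not estimated because only point predictions feed the simulator.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.special import expit, logit

__all__ = [
    "LogisticCurve",
    "ExplorationCurve",
    "ConstantCurve",
    "CalibrationSet",
    "MMFit",
    "PeeringEffect",
    "TuningResult",
    "logistic_eval",
    "default_calibration",
    "fit_logistic_age_curve",
    "mm_eval",
    "fit_mm",
    "adult_like_threshold",
    "estimate_peering_effect",
    "tune_free_parameters",
    "FitFailureError",
]


class FitFailureError(RuntimeError):
    """Raised when an estimator fails to converge or is degenerate."""


@dataclass(frozen=True)
class LogisticCurve:
    """p(age) = logistic(intercept + slope_age * age)."""

    intercept: float
    slope_age: float

    def prob(self, age):
        return expit(self.intercept + self.slope_age * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class ExplorationCurve:
    """Hump-shaped exploration rate p(a) = c * (a/tau) * exp(1 - a/tau).

    Zero at birth, peaks at value ``peak_prob`` (c) at age ``peak_age``
    (tau), then decays — a parametric stand-in for the smoothed
    age-exploration curves estimated from scan data, which peak in the
    first few years of life.
    """

    peak_age: float
    peak_prob: float

    def __post_init__(self) -> None:
        if self.peak_age <= 0:
            raise ValueError("peak_age must be positive")
        if not (0.0 < self.peak_prob < 1.0):
            raise ValueError("peak_prob must be in (0, 1)")

    def prob(self, age):
        a = np.asarray(age, dtype=float) / self.peak_age
        return self.peak_prob * a * np.exp(1.0 - a)


@dataclass(frozen=True)
class ConstantCurve:
    """Age-independent probability (degenerate curve for tests/overrides)."""

    p: float

    def prob(self, age):
        return np.full_like(np.asarray(age, dtype=float), self.p)


def logistic_eval(curve: LogisticCurve, age) -> float | np.ndarray:
    """Evaluate a logistic age curve as a probability."""
    return curve.prob(age)


@dataclass(frozen=True)
class CalibrationSet:
    """The full set of age curves driving the simulator.

    The exploration rate when alone is tied to the distant-association
    rate (``alone_equals_distant``): immatures are essentially never
    observed alone during dependency, so an alone-specific rate cannot be
    estimated from field data.
    """

    assoc: LogisticCurve
    close_given_assoc: LogisticCurve
    peer_given_close: LogisticCurve
    explore_distant: ExplorationCurve | ConstantCurve
    explore_close: ExplorationCurve | ConstantCurve
    explore_after_peer: LogisticCurve | ConstantCurve
    alone_equals_distant: bool = True

    def state_probs(self, age):
        """(P(assoc), P(close|assoc), P(peer|close)) at the given age(s)."""
        return (
            self.assoc.prob(age),
            self.close_given_assoc.prob(age),
            self.peer_given_close.prob(age),
        )

    # --- flat serialization ------------------------------------------------
    _CURVES = (
        "assoc",
        "close_given_assoc",
        "peer_given_close",
        "explore_distant",
        "explore_close",
        "explore_after_peer",
    )

    def to_dict(self) -> dict[str, float | bool]:
        out: dict[str, float | bool] = {}
        for name in self._CURVES:
            curve = getattr(self, name)
            if isinstance(curve, LogisticCurve):
                out[f"{name}.intercept"] = curve.intercept
                out[f"{name}.slope_age"] = curve.slope_age
            elif isinstance(curve, ExplorationCurve):
                out[f"{name}.peak_age"] = curve.peak_age
                out[f"{name}.peak_prob"] = curve.peak_prob
            else:
                out[f"{name}.p"] = curve.p
        out["alone_equals_distant"] = self.alone_equals_distant
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSet":
        kwargs = {}
        for name in cls._CURVES:
            if f"{name}.intercept" in d:
                kwargs[name] = LogisticCurve(
                    float(d[f"{name}.intercept"]), float(d[f"{name}.slope_age"])
                )
            elif f"{name}.peak_age" in d:
                kwargs[name] = ExplorationCurve(
                    float(d[f"{name}.peak_age"]), float(d[f"{name}.peak_prob"])
                )
            elif f"{name}.p" in d:
                kwargs[name] = ConstantCurve(float(d[f"{name}.p"]))
            else:
                raise ValueError(f"no parameters for curve {name!r}")
        return cls(**kwargs, alone_equals_distant=bool(d.get("alone_equals_distant", True)))


# --- packaged default curves ---------------------------------------------
# Association: published slope −0.4; intercept anchored so p(7) = 0.97
# (which also gives p(1..3) > 0.99, matching the near-constant association
# observed through the dependency phase).
_ASSOC = LogisticCurve(intercept=float(logit(0.97) + 0.4 * 7.0), slope_age=-0.4)

# Close association given association: p(0) = 0.975, slope −0.339
# (validated downstream against 83.8% at age 6 and 25.5% at age 14).
_CLOSE = LogisticCurve(intercept=float(logit(0.975)), slope_age=-0.339)

# Exploration after peering: published slope +0.12; intercept anchored so
# the curve passes through the pooled after-peering rate 67.7% at the
# approximate mid-dependency mean event age of 4.5 years.
_AFTER_PEER = LogisticCurve(
    intercept=float(logit(0.677) - 0.12 * 4.5), slope_age=0.12
)

#: Peak age (years) of the exploration hump; exploration in the wild
#: peaks between ages 1 and 3.
EXPLORATION_PEAK_AGE = 2.0

# The three free magnitudes, tuned against the three published treatment
# means at the independence milestone (224 / 213 / 152 items at 9 years;
# analysis/03_tune_exploration.py re-derives them).
TUNED_EXPLORE_DISTANT_PEAK = 0.080282
TUNED_EXPLORE_CLOSE_PEAK = 0.222279
TUNED_PEER_INTERCEPT = -2.410455


def default_calibration() -> CalibrationSet:
    """The packaged default curve set (idempotent)."""
    return CalibrationSet(
        assoc=_ASSOC,
        close_given_assoc=_CLOSE,
        peer_given_close=LogisticCurve(TUNED_PEER_INTERCEPT, -0.12),
        explore_distant=ExplorationCurve(EXPLORATION_PEAK_AGE, TUNED_EXPLORE_DISTANT_PEAK),
        explore_close=ExplorationCurve(EXPLORATION_PEAK_AGE, TUNED_EXPLORE_CLOSE_PEAK),
        explore_after_peer=_AFTER_PEER,
    )


# --- fitters ---------------------------------------------------------------

def fit_logistic_age_curve(
    ages, successes, trials, warn_on_separation: bool = True
) -> LogisticCurve:
    """Trial-weighted binomial logistic fit of success probability on age.

    ``ages``, ``successes`` and ``trials`` are aligned 1-D sequences
    (e.g. one row per focal follow).  Returns the fitted curve; complete
    separation triggers a warning, a single distinct age an error.
    """
    import statsmodels.api as sm

    ages = np.asarray(ages, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if ages.shape != successes.shape or ages.shape != trials.shape:
        raise ValueError("ages, successes and trials must be aligned")
    if np.unique(ages).size < 2:
        raise FitFailureError("need at least two distinct ages (rank-deficient fit)")
    if np.any(trials < 1):
        raise ValueError("all trial counts must be >= 1")
    if np.any(successes > trials) or np.any(successes < 0):
        raise ValueError("successes must lie in [0, trials]")

    endog = np.column_stack([successes, trials - successes])
    exog = sm.add_constant(ages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    intercept, slope = result.params
    if warn_on_separation and (abs(slope) > 50 or abs(intercept) > 50):
        warnings.warn(
            "possible complete separation: fitted coefficients are extreme",
            stacklevel=2,
        )
    return LogisticCurve(intercept=float(intercept), slope_age=float(slope))


@dataclass(frozen=True)
class MMFit:
    """Michaelis–Menten saturation fit V(n) = vmax * n / (k + n)."""

    vmax: float
    k: float

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.k <= 0:
            raise ValueError("vmax and k must be positive")


def mm_eval(fit: MMFit, n_scans) -> float | np.ndarray:
    """Expected cumulative unique items after ``n_scans`` scans."""
    n = np.asarray(n_scans, dtype=float)
    return fit.vmax * n / (fit.k + n)


def fit_mm(data: pd.DataFrame | None = None, n_scans=None, unique_items=None) -> MMFit:
    """Pooled nonlinear least-squares Michaelis–Menten fit.

    Accepts either a DataFrame with ``n_scans`` and ``unique_items``
    columns (rows pooled across individuals — a fixed-effects
    approximation of the random-intercept model) or the two arrays
    directly.  Starting values: vmax0 = max observed count, k0 = median n.
    """
    if data is not None:
        n_scans = data["n_scans"].to_numpy(dtype=float)
        unique_items = data["unique_items"].to_numpy(dtype=float)
    n = np.asarray(n_scans, dtype=float)
    y = np.asarray(unique_items, dtype=float)
    if n.size < 3 or np.unique(n).size < 3:
        raise ValueError("need at least three distinct sampling-effort points")
    p0 = (max(y.max(), 1.0), max(float(np.median(n)), 1.0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda x, vmax, k: vmax * x / (k + x),
                n,
                y,
                p0=p0,
                bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitFailureError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    return MMFit(vmax=float(popt[0]), k=float(popt[1]))


def adult_like_threshold(vmax: float, fraction: float = 0.9) -> int:
    """Item count defining an adult-like repertoire: floor(fraction * vmax)."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    return int(math.floor(fraction * vmax))


def _logit_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI on the logit scale, back-transformed."""
    from scipy.stats import norm

    if k == 0 or k == n:
        # fall back to +/- half a count to keep the logit finite
        k = min(max(k, 0.5), n - 0.5)
    p = k / n
    se = math.sqrt(1.0 / k + 1.0 / (n - k))
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = logit(p) - z * se, logit(p) + z * se
    return float(expit(lo)), float(expit(hi))


@dataclass(frozen=True)
class PeeringEffect:
    """Before/after peering exploration probabilities and the age trend."""

    p_before: float
    ci_before: tuple[float, float]
    n_before: int
    p_after: float
    ci_after: tuple[float, float]
    n_after: int
    age_curve: LogisticCurve


def estimate_peering_effect(events: pd.DataFrame) -> PeeringEffect:
    """Estimate the effect of peering on exploration from event records.

    ``events`` has one row per peering event with columns ``age``,
    ``explored_before_1h`` and ``explored_after_1h``.  The before-peering
    rate is estimated over all events; the after-peering rate and its age
    trend only over events where the item had not already been explored
    in the hour before peering.
    """
    required = {"age", "explored_before_1h", "explored_after_1h"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events missing columns: {sorted(missing)}")
    n_before = len(events)
    if n_before == 0:
        raise FitFailureError("no peering events: before-rate undefined")
    k_before = int(events["explored_before_1h"].sum())

    fresh = events.loc[~events["explored_before_1h"].astype(bool)]
    n_after = len(fresh)
    if n_after == 0:
        raise FitFailureError(
            "no peering events without prior exploration: after-rate undefined"
        )
    k_after = int(fresh["explored_after_1h"].sum())

    age_curve = fit_logistic_age_curve(
        fresh["age"].to_numpy(dtype=float),
        fresh["explored_after_1h"].to_numpy(dtype=float),
        np.ones(n_after),
    )
    return PeeringEffect(
        p_before=k_before / n_before,
        ci_before=_logit_ci(k_before, n_before),
        n_before=n_before,
        p_after=k_after / n_after,
        ci_after=_logit_ci(k_after, n_after),
        n_after=n_after,
        age_curve=age_curve,
    )


# --- free-parameter tuning -------------------------------------------------

@dataclass(frozen=True)
class TuningResult:
    calibration: CalibrationSet
    achieved: tuple[float, float, float]
    targets: tuple[float, float, float]
    identifiable: tuple[bool, bool, bool] = (True, True, True)

    @property
    def residuals(self) -> tuple[float, float, float]:
        return tuple(a - t for a, t in zip(self.achieved, self.targets))


def tune_free_parameters(
    env,
    base: CalibrationSet,
    targets: tuple[float, float, float] = (224.0, 213.0, 152.0),
    treatments=None,
    cohort_size: int = 150,
    master_seed: int = 0,
    milestone_age: float = 9.0,
    xtol: float = 1e-4,
    max_residual: float = 10.0,
) -> TuningResult:
    """Tune the three unpublished curve magnitudes against the three
    treatment mean repertoire sizes at the independence milestone.

    ``targets`` are the mean repertoires at ``milestone_age`` for (full,
    no-peering, exposure-only).  The parameters have a triangular
    identification structure — the exposure-only mean responds only to
    the distant-exploration peak, the no-peering mean additionally to the
    close-exploration peak, and the full mean additionally to the peering
    intercept — so each is solved by a monotone 1-D bisection in turn,
    with common random numbers (fixed ``master_seed``) across candidate
    evaluations.

    If a target is insensitive to its parameter (e.g. peering disabled in
    every treatment), that parameter is flagged non-identifiable and left
    at its ``base`` value.  A residual above ``max_residual`` items on
    any target triggers a tuning-failure warning.
    """
    from .experiments import repertoire_at_age
    from .simulator import EXPOSURE_ONLY, FULL, NO_PEERING, SimulationConfig, run_cohort

    if treatments is None:
        treatments = (FULL, NO_PEERING, EXPOSURE_ONLY)
    if len(targets) != 3 or len(treatments) != 3:
        raise ValueError("need exactly three targets and three treatments")
    years = int(math.ceil(milestone_age))
    config = SimulationConfig(
        years=years,
        independence_age=min(9, years - 1) if years > 1 else 0,
        cohort_size=cohort_size,
    )

    def cohort_mean(calib: CalibrationSet, treatment) -> float:
        trajs = run_cohort(env, calib, treatment, config, master_seed)
        return float(np.mean([repertoire_at_age(t, milestone_age) for t in trajs]))

    calib = base
    identifiable = [True, True, True]

    def solve(setter, lo, hi, treatment, target, index):
        nonlocal calib
        f_lo = cohort_mean(setter(calib, lo), treatment) - target
        f_hi = cohort_mean(setter(calib, hi), treatment) - target
        if abs(f_hi - f_lo) < 1e-9:
            identifiable[index] = False
            warnings.warn(
                f"target {index} is insensitive to its parameter; leaving base value",
                stacklevel=3,
            )
            return
        if f_lo > 0 or f_hi < 0:
            # target outside the attainable range: clamp to the closer bound
            best = lo if abs(f_lo) < abs(f_hi) else hi
            calib = setter(calib, best)
            return
        root = brentq(
            lambda x: cohort_mean(setter(calib, x), treatment) - target,
            lo,
            hi,
            xtol=xtol,
        )
        calib = setter(calib, root)

    # 1. distant-exploration peak against the exposure-only mean
    solve(
        lambda c, x: replace(c, explore_distant=replace(c.explore_distant, peak_prob=x)),
        1e-4,
        0.5,
        treatments[2],
        targets[2],
        2,
    )
    # 2. close-exploration peak against the no-peering mean
    solve(
        lambda c, x: replace(c, explore_close=replace(c.explore_close, peak_prob=x)),
        max(calib.explore_distant.peak_prob, 1e-4),
        0.6,
        treatments[1],
        targets[1],
        1,
    )
    # 3. peering intercept against the full-model mean
    solve(
        lambda c, x: replace(c, peer_given_close=replace(c.peer_given_close, intercept=x)),
        -8.0,
        4.0,
        treatments[0],
        targets[0],
        0,
    )

    achieved = tuple(cohort_mean(calib, tr) for tr in treatments)
    for a, t in zip(achieved, targets):
        if abs(a - t) > max_residual:
            warnings.warn(
                f"tuning failure: achieved {a:.1f} vs target {t:.1f} "
                f"(|residual| > {max_residual})",
                stacklevel=2,
            )
    return TuningResult(
        calibration=calib,
        achieved=achieved,
        targets=tuple(float(t) for t in targets),
        identifiable=tuple(identifiable),
    )
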