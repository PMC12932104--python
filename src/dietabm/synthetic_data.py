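"""Synthetic observational datasets for testing the calibration fitters.

The long-term field dataset behind the model (2-minute instantaneous
scans from daily focal follows, all-occurrence peering records, and
per-adult diet accumulation curves) is deposited externally; this module
generates datasets with the same statistical structure from known truth
parameters, so every fitter can be validated by parameter recovery
without any download.

Heterogeneity between individuals is emulated by a log-odds perturbation
of each curve's intercept per individual (default s.d. 0.3) rather than
a full random-effects model; the fitters are fixed-effects, so recovery
tolerances absorb this.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .calibration import CalibrationSet, LogisticCurve

__all__ = [
    "generate_focal_follows",
    "generate_peering_events",
    "generate_accumulation_data",
    "aggregate_state_counts",
]


def _perturb(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift probabilities by ``delta`` on the log-odds scale (p=0 or 1
    are fixed points)."""
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    interior = (p > 0.0) & (p < 1.0)
    out[~interior] = p[~interior]
    out[interior] = expit(logit(p[interior]) + delta)
    return out


def generate_focal_follows(
    truth: CalibrationSet,
    n_individuals: int = 30,
    follows_per_individual: int = 12,
    scans_per_follow: int = 276,
    rng: np.random.Generator | None = None,
    heterogeneity_sd: float = 0.3,
    age_range: tuple[float, float] = (0.0, 15.0),
) -> pd.DataFrame:
    """Scan-level focal-follow records drawn from a known curve set.

    Each follow has a single age drawn uniformly from ``age_range``; each
    scan draws the social-state hierarchy (associated → close → peering)
    and then an exploration flag from the state-appropriate curve.  One
    log-odds offset per individual and curve emulates between-individual
    heterogeneity.

    Defaults give 30 individuals and ~99,000 scans, the scale of the
    field association dataset.
    """
    if min(n_individuals, follows_per_individual, scans_per_follow) < 1:
        raise ValueError("all counts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)

    frames = []
    for ind in range(n_individuals):
        d_assoc, d_close, d_peer, d_expl = rng.normal(0.0, heterogeneity_sd, 4)
        ages = rng.uniform(*age_range, follows_per_individual)
        for fol, age in enumerate(ages):
            n = scans_per_follow
            p_assoc = _perturb(truth.assoc.prob(age), d_assoc)
            p_close = _perturb(truth.close_given_assoc.prob(age), d_close)
            p_peer = _perturb(truth.peer_given_close.prob(age), d_peer)
            associated = rng.random(n) < p_assoc
            close = associated & (rng.random(n) < p_close)
            peering = close & (rng.random(n) < p_peer)
            p_expl = np.where(
                peering,
                _perturb(truth.explore_after_peer.prob(age), d_expl),
                np.where(
                    close,
                    _perturb(truth.explore_close.prob(age), d_expl),
                    _perturb(truth.explore_distant.prob(age), d_expl),
                ),
            )
            exploring = rng.random(n) < p_expl
            frames.append(
                pd.DataFrame(
                    {
                        "individual_id": ind,
                        "follow_id": ind * follows_per_individual + fol,
                        "age": age,
                        "scan": np.arange(n),
                        "associated": associated,
                        "close": close,
                        "peering": peering,
                        "exploring": exploring,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def aggregate_state_counts(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate scan records to per-follow (age, successes, trials)
    tables for each stage of the social-state hierarchy, the natural
    input for the trial-weighted logistic fitter."""
    def agg(frame: pd.DataFrame, flag: str) -> pd.DataFrame:
        g = frame.groupby("follow_id", as_index=False).agg(
            age=("age", "first"), successes=(flag, "sum"), trials=(flag, "size")
        )
        return g[g["trials"] >= 1]

    return {
        "assoc": agg(df, "associated"),
        "close_given_assoc": agg(df[df["associated"]], "close"),
        "peer_given_close": agg(df[df["close"]], "peering"),
    }


def generate_peering_events(
    p_before: float,
    after_curve: LogisticCurve,
    n_events: int = 367,
    rng: np.random.Generator | None = None,
    age_range: tuple[float, float] = (0.5, 8.0),
    n_individuals: int = 14,
) -> pd.DataFrame:
    """Peering-event records with explore-within-1-hour outcomes.

    Each event carries whether the item had already been explored in the
    hour before peering (Bernoulli ``p_before``) and whether it was
    explored in the hour after (Bernoulli of the age curve).  The
    after-flag is informative only on the no-prior-exploration subset,
    mirroring how the field analysis refines its sample.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not (0.0 <= p_before <= 1.0):
        raise ValueError("p_before must be a probability")
    if rng is None:
        rng = np.random.default_rng(0)
    ages = rng.uniform(*age_range, n_events)
    explored_before = rng.random(n_events) < p_before
    explored_after = rng.random(n_events) < after_curve.prob(ages)
    return pd.DataFrame(
        {
            "individual_id": np.arange(n_events) % n_individuals,
            "follow_id": np.arange(n_events),
            "age": ages,
            "explored_before_1h": explored_before,
            "explored_after_1h": explored_after,
        }
    )


def generate_accumulation_data(
    env,
    n_adults: int = 95,
    scans_per_adult: int = 4232,
    rng: np.random.Generator | None = None,
    n_checkpoints: int = 25,
) -> pd.DataFrame:
    """Per-adult cumulative unique-food curves at log-spaced checkpoints.

    Each adult makes ``scans_per_adult`` sequential item draws from the
    environment's encounter distribution; the running count of distinct
    items is recorded at a logarithmic grid of scan checkpoints (the
    input shape expected by the Michaelis–Menten fitter).  Defaults
    match the field effort: 95 adults, ~402,000 scans in total.
    """
    if n_adults < 1 or scans_per_adult < 1:
        raise ValueError("counts must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    checkpoints = np.unique(
        np.round(
            np.logspace(np.log10(min(10, scans_per_adult)), np.log10(scans_per_adult), n_checkpoints)
        ).astype(int)
    )
    rows = []
    for adult in range(n_adults):
        items = env.draw_items(rng, scans_per_adult)
        first_seen = np.zeros(scans_per_adult, dtype=bool)
        _, first_idx = np.unique(items, return_index=True)
        first_seen[first_idx] = True
        cum_unique = np.cumsum(first_seen)
        rows.append(
            pd.DataFrame(
                {
                    "adult_id": adult,
                    "n_scans": checkpoints,
                    "unique_items": cum_unique[checkpoints - 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
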