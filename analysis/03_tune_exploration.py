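"""Tune the three unpublished curve magnitudes against treatment means.

Three magnitudes driving the simulation are not published anywhere: the
peak exploration rates in distant and close association (the smooth-fit
heights) and the peering-rate intercept.  They are, however, jointly
pinned by the three published treatment means at the independence
milestone: 224 items (full model), 224-11 (no peering) and 224-72
(exposure only).  Identification is triangular — exposure-only responds
only to the distant peak, no-peering adds the close peak, the full model
adds the peering intercept — so each is solved by a monotone bisection
in turn on common-random-number cohorts of 150.

Finding: distant peak 0.0803, close peak 0.2223, peering intercept
-2.410 hit all three targets to well under one item; these values are
frozen as the package defaults (dietabm.calibration.TUNED_*).
"""
import json
from pathlib import Path

import dietabm as d
from dietabm.calibration import (
    TUNED_EXPLORE_CLOSE_PEAK,
    TUNED_EXPLORE_DISTANT_PEAK,
    TUNED_PEER_INTERCEPT,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    env = d.default_environment()
    result = d.tune_free_parameters(
        env, d.default_calibration(), cohort_size=150, master_seed=11
    )
    c = result.calibration
    print(f"targets  (full, no-peering, exposure-only): {result.targets}")
    print(f"achieved (same order, common random numbers): "
          f"{tuple(round(a, 2) for a in result.achieved)}")
    print(f"explore_distant peak: {c.explore_distant.peak_prob:.6f} "
          f"(packaged {TUNED_EXPLORE_DISTANT_PEAK})")
    print(f"explore_close peak:   {c.explore_close.peak_prob:.6f} "
          f"(packaged {TUNED_EXPLORE_CLOSE_PEAK})")
    print(f"peering intercept:    {c.peer_given_close.intercept:.6f} "
          f"(packaged {TUNED_PEER_INTERCEPT})")

    (OUT / "tuned_parameters.json").write_text(
        json.dumps(
            {
                "targets": list(result.targets),
                "achieved": list(result.achieved),
                "explore_distant_peak": c.explore_distant.peak_prob,
                "explore_close_peak": c.explore_close.peak_prob,
                "peer_given_close_intercept": c.peer_given_close.intercept,
                "cohort_size": 150,
                "master_seed": 11,
            },
            indent=2,
        )
    )
    print(f"wrote {OUT / 'tuned_parameters.json'}")


if __name__ == "__main__":
    main()
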