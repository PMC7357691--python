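"""Pseudo individual-patient data (pseudo-IPD) from digitized incidence curves.

Published trials often report only a cumulative-incidence figure.  Given
already-extracted (time, incidence) coordinates and the arm size, this
module rebuilds a subject-level dataset whose Kaplan-Meier refit reproduces
the curve, so model-based analyses (Cox, cure model, bootstrap projection)
can be run on published figures.

Because the source figures carry no at-risk table, every non-event is
censored at the follow-up horizon — consistent with the trials' day-28
administrative censoring.  Event counts per step are allocated by
largest-remainder rounding so the arm size is conserved bit-exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import DigitizedCurve


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of `total` proportional to `quotas` (sum ~ total).

    Floors every quota, then hands the remaining units to the largest
    fractional parts; ties break toward earlier entries, deterministically.
    """
    floors = np.floor(quotas + 1e-12).astype(int)
    remainder = int(total) - int(floors.sum())
    if remainder < 0:  # guard against accumulated floating excess
        order = np.argsort(-(quotas - floors), kind="stable")[::-1]
        for idx in order:
            if remainder == 0:
                break
            if floors[idx] > 0:
                floors[idx] -= 1
                remainder += 1
    elif remainder > 0:
        frac = quotas - floors
        order = np.argsort(-frac, kind="stable")
        floors[order[:remainder]] += 1
    return floors


def reconstruct_ipd(curve: DigitizedCurve, arm: str | None = None) -> pd.DataFrame:
    """Convert one digitized cumulative-incidence curve into subject records.

    The number of events at each curve time is ``arm_size`` times the
    incidence increment, rounded by largest remainder so that the total
    event count equals ``round(arm_size * final_incidence)``; all remaining
    subjects are censored at the horizon.  A Kaplan-Meier refit of the
    output reproduces the input incidence at every curve time to within
    1/arm_size.
    """
    label = arm if arm is not None else (curve.arm or "arm")
    n = int(curve.arm_size)
    inc = np.asarray(curve.incidence, dtype=float)
    if np.any(np.diff(inc) < -1e-12):
        raise ValidationError("cumulative incidence must be nondecreasing")
    increments = np.diff(np.concatenate([[0.0], np.minimum(inc, 1.0)]))
    total_events = int(round(n * float(inc[-1])))
    counts = _largest_remainder(n * increments, total_events)
    if counts.sum() != total_events:  # pragma: no cover - defensive
        raise ValidationError("event apportionment failed to conserve the event total")

    times = np.repeat(curve.times, counts)
    events = np.ones(total_events, dtype=int)
    n_censored = n - total_events
    if n_censored < 0:
        raise ValidationError("final incidence implies more events than subjects")
    frame = pd.DataFrame(
        {
            "time": np.concatenate([times, np.full(n_censored, float(curve.horizon))]),
            "event": np.concatenate([events, np.zeros(n_censored, dtype=int)]),
            "arm": label,
        }
    )
    return frame.sort_values(["time", "event"], ascending=[True, False], ignore_index=True)


def reconstruct_trial(curves: dict[str, DigitizedCurve]) -> pd.DataFrame:
    """Pseudo-IPD for a whole trial from one curve per arm."""
    frames = [reconstruct_ipd(curve, arm=arm) for arm, curve in sorted(curves.items())]
    return pd.concat(frames, ignore_index=True)
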