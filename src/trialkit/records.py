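"""Subject-level records: the common two-arm time-to-event container.

Every analysis in the package consumes a :class:`pandas.DataFrame` with
columns ``time`` (days, nonnegative), ``event`` (1 = end point observed,
0 = right censored) and ``arm`` (group label).  Synthetic datasets carry an
extra ``truth_eta`` column with the latent terminal-group label; analysis
code never reads it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError

REQUIRED_COLUMNS = ("time", "event", "arm")

#: arm labels treated as the reference (baseline) group when none is given
_REFERENCE_ALIASES = ("control", "standard care", "placebo")


def validate_records(records: pd.DataFrame, require_two_arms: bool = False) -> pd.DataFrame:
    """Check the subject-record contract and return the frame unchanged.

    Raises
    ------
    EmptyInputError
        if there are no rows.
    ValidationError
        if columns are missing, times are negative, or event flags are
        outside {0, 1}.
    """
    if records is None or len(records) == 0:
        raise EmptyInputError("no subject records provided")
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records missing required columns: {missing}")
    time = np.asarray(records["time"], dtype=float)
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValidationError("times must be finite and nonnegative")
    event = np.asarray(records["event"])
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event indicator must be 0 or 1")
    if require_two_arms and records["arm"].nunique() != 2:
        raise ValidationError(
            f"expected exactly two arms, found {sorted(records['arm'].unique())}"
        )
    return records


def arm_labels(records: pd.DataFrame) -> list[str]:
    """Arm labels in deterministic (sorted) order."""
    return sorted(str(a) for a in records["arm"].unique())


def encode_arms(records: pd.DataFrame, reference: str | None = None) -> tuple[np.ndarray, str, str]:
    """Binary arm covariate for a two-arm trial.

    Returns ``(x, treatment_label, reference_label)`` where ``x`` is 1 for
    the non-reference (treatment) arm.  When ``reference`` is not supplied,
    a conventional control-arm name (control / standard care / placebo) is
    used if present, otherwise the lexicographically larger label.
    """
    labels = arm_labels(records)
    if len(labels) != 2:
        raise ValidationError(f"expected exactly two arms, found {labels}")
    if reference is None:
        lowered = {lab.lower(): lab for lab in labels}
        for alias in _REFERENCE_ALIASES:
            if alias in lowered:
                reference = lowered[alias]
                break
        else:
            reference = labels[-1]
    reference = str(reference)
    if reference not in labels:
        raise ValidationError(f"reference arm {reference!r} not among arms {labels}")
    treatment = labels[0] if labels[1] == reference else labels[1]
    x = (records["arm"].astype(str) == treatment).to_numpy(dtype=float)
    return x, treatment, reference


def read_records(path) -> pd.DataFrame:
    """Read a subject-record CSV (columns time, event, arm[, truth_eta])."""
    frame = pd.read_csv(path)
    return validate_records(frame)


def write_records(records: pd.DataFrame, path) -> None:
    validate_records(records)
    records.to_csv(path, index=False)


def subset_arm(records: pd.DataFrame, arm: str) -> pd.DataFrame:
    sub = records[records["arm"].astype(str) == str(arm)]
    if len(sub) == 0:
        raise EmptyInputError(f"no records for arm {arm!r}")
    return sub


def make_records(
    time: Sequence[float], event: Sequence[int], arm: Sequence[str] | str
) -> pd.DataFrame:
    """Convenience constructor used heavily in tests and examples."""
    time = np.asarray(time, dtype=float)
    if isinstance(arm, str):
        arm = [arm] * len(time)
    frame = pd.DataFrame(
        {"time": time, "event": np.asarray(event, dtype=int), "arm": list(arm)}
    )
    return validate_records(frame)
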