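"""Kaplan-Meier estimation with Greenwood variance.

The product-limit estimator is the shared substrate for the restricted-mean,
cure-model and reconstruction modules.  Fitting is delegated to
:class:`lifelines.KaplanMeierFitter`; this module exposes the risk-set
bookkeeping (``n_j``, ``d_j``) and the Greenwood variance in a plain
array-based container that the downstream numerics consume directly.

Ties between events and censorings at the same time are resolved
events-first (the standard convention: censored subjects at time t are still
at risk for an event at t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import EmptyInputError, ValidationError
from .records import validate_records


@dataclass(frozen=True)
class KMEstimate:
    """Kaplan-Meier survival step function over the distinct event times.

    Attributes
    ----------
    times : distinct event times (strictly increasing)
    n_risk : number at risk just before each event time
    n_event : number of events at each event time
    survival : S(t) immediately after each event time
    variance : Greenwood variance of S at each event time
    n_subjects : total subjects the curve was fitted on
    max_time : largest observed time (event or censoring)
    """

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    n_subjects: int
    max_time: float

    def survival_at(self, t) -> np.ndarray:
        """S(t) as a right-continuous step function; S(t) = 1 for t < first event."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]

    def cumulative_incidence_at(self, t) -> np.ndarray:
        """F(t) = 1 - S(t): the cumulative incidence of the end point."""
        return 1.0 - self.survival_at(t)

    def variance_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.variance])
        return padded[idx]


def km_fit(records: pd.DataFrame) -> KMEstimate:
    """Fit the product-limit estimator to one arm's subject records.

    Greenwood's formula gives the pointwise variance
    ``Var[S(t)] = S(t)^2 * sum_{t_j <= t} d_j / (n_j (n_j - d_j))``;
    the sum term is taken as 0 where ``n_j == d_j`` exhausts the risk set
    (S has reached zero and its variance is degenerate there).
    """
    validate_records(records)
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=int)

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    observed = table["observed"].to_numpy()
    mask = observed > 0
    times = table.index.to_numpy(dtype=float)[mask]
    d = observed[mask].astype(int)
    n = table["at_risk"].to_numpy()[mask].astype(int)

    surv = kmf.survival_function_at_times(times).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * np.maximum(n - d, 1)), 0.0)
    variance = surv**2 * np.cumsum(terms)

    return KMEstimate(
        times=times,
        n_risk=n,
        n_event=d,
        survival=surv,
        variance=variance,
        n_subjects=len(time),
        max_time=float(time.max()),
    )


def km_fit_by_arm(records: pd.DataFrame) -> dict[str, KMEstimate]:
    """Per-arm Kaplan-Meier fits keyed by arm label."""
    validate_records(records)
    out: dict[str, KMEstimate] = {}
    for arm, sub in records.groupby(records["arm"].astype(str)):
        out[str(arm)] = km_fit(sub)
    if not out:
        raise EmptyInputError("no arms present")
    return out
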