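"""Bootstrap prediction of an under-enrolled trial's outcome at its target size.

A trial stopped at N0 subjects short of its planned N can ask what the
primary analysis would likely have shown at full enrollment.  Two
resampling schemes are provided, both stratified by arm so the target
allocation is met exactly:

* unconditional — each replicate redraws all N subjects with replacement
  from the observed data;
* conditional — each replicate keeps the observed N0 subjects intact and
  draws only the N - N0 additional subjects with replacement.

Each replicate refits a two-arm Cox proportional-hazards model (Breslow
ties).  The predicted log hazard ratio is the mean replicate log-HR; the
interval is a Wald interval built from the mean replicate model standard
error, so its width shrinks as the target size grows.  A percentile
interval over replicates is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._cox import fit_cox_binary
from .errors import IdentifiabilityError, ValidationError
from .records import encode_arms, validate_records


@dataclass(frozen=True)
class CoxSummary:
    """Plain two-arm Cox fit: HR, Wald CI and P."""

    hazard_ratio: float
    log_hr: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    treatment: str
    reference: str

    def to_dict(self) -> dict:
        return {
            "hazard_ratio": self.hazard_ratio,
            "log_hr": self.log_hr,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "treatment": self.treatment,
            "reference": self.reference,
        }


@dataclass
class PredictionResult:
    """Predicted trial outcome at the target sample size."""

    mode: str
    n_target: dict[str, int]
    n_observed: dict[str, int]
    hr_predicted: float
    ci_low: float
    ci_high: float
    p_value: float
    log_hr: float
    se: float
    n_boot: int
    n_failed: int
    flagged: bool            # True when >10% of replicates failed to fit
    seed: int
    treatment: str
    reference: str
    replicate_log_hrs: np.ndarray | None = None  # raw replicate draws (not serialized)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_target": self.n_target,
            "n_observed": self.n_observed,
            "hr_predicted": self.hr_predicted,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "log_hr": self.log_hr,
            "se": self.se,
            "n_boot": self.n_boot,
            "n_failed": self.n_failed,
            "flagged": self.flagged,
            "seed": self.seed,
            "treatment": self.treatment,
            "reference": self.reference,
        }


def cox_hr(records: pd.DataFrame, reference: str | None = None,
           ci_level: float = 0.95) -> CoxSummary:
    """Two-arm Cox proportional-hazards fit (treatment vs reference)."""
    validate_records(records, require_two_arms=True)
    x, treatment, ref = encode_arms(records, reference)
    fit = fit_cox_binary(
        np.asarray(records["time"], float), np.asarray(records["event"], float), x
    )
    z = norm.ppf(0.5 + ci_level / 2.0)
    return CoxSummary(
        hazard_ratio=float(np.exp(fit.beta)),
        log_hr=fit.beta,
        se=fit.se,
        ci_low=float(np.exp(fit.beta - z * fit.se)),
        ci_high=float(np.exp(fit.beta + z * fit.se)),
        p_value=2.0 * float(norm.sf(abs(fit.beta) / fit.se)) if fit.se > 0 else float("nan"),
        treatment=treatment,
        reference=ref,
    )


def _largest_remainder_split(total: int, sizes: dict[str, int]) -> dict[str, int]:
    arms = sorted(sizes)
    n_obs = sum(sizes.values())
    quotas = np.array([total * sizes[a] / n_obs for a in arms])
    floors = np.floor(quotas).astype(int)
    frac = quotas - floors
    for idx in np.argsort(-frac, kind="stable")[: total - floors.sum()]:
        floors[idx] += 1
    return {a: int(n) for a, n in zip(arms, floors)}


def predict_completion(
    records: pd.DataFrame,
    n_target: int | Mapping[str, int] | tuple[int, int],
    mode: str = "conditional",
    n_boot: int = 50_000,
    seed: int = 0,
    reference: str | None = None,
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> PredictionResult:
    """Predict the completed trial's hazard ratio by stratified bootstrap.

    Parameters
    ----------
    records : observed (under-enrolled) two-arm trial
    n_target : target size — a mapping arm -> n, a (treatment, reference)
        pair, or a total split proportionally to the observed allocation
    mode : 'conditional' (keep the observed subjects, draw only the
        shortfall; requires target >= observed in every arm) or
        'unconditional' (redraw everything)
    ci_method : 'wald' (mean replicate SE) or 'percentile' (over replicates)

    Replicates whose Cox fit fails (an arm without events, or a boundary
    estimate) are dropped and counted; the result is flagged when more
    than 10% fail.
    """
    validate_records(records, require_two_arms=True)
    if mode not in ("conditional", "unconditional"):
        raise ValidationError(f"unknown mode {mode!r}")
    x, treatment, ref = encode_arms(records, reference)
    time = np.asarray(records["time"], float)
    event = np.asarray(records["event"], float)
    arms = {treatment: np.flatnonzero(x == 1.0), ref: np.flatnonzero(x == 0.0)}
    n_observed = {a: len(idx) for a, idx in arms.items()}

    if isinstance(n_target, Mapping):
        target = {str(a): int(n) for a, n in n_target.items()}
        if set(target) != set(arms):
            raise ValidationError(f"target arms {sorted(target)} != {sorted(arms)}")
    elif isinstance(n_target, (tuple, list)):
        target = {treatment: int(n_target[0]), ref: int(n_target[1])}
    else:
        target = _largest_remainder_split(int(n_target), n_observed)
    if mode == "conditional":
        for a in arms:
            if target[a] < n_observed[a]:
                raise ValidationError(
                    f"conditional mode needs target >= observed in arm {a!r} "
                    f"({target[a]} < {n_observed[a]})"
                )

    z = norm.ppf(0.5 + ci_level / 2.0)

    # degenerate conditional projection: nothing to draw, return the plain fit
    if mode == "conditional" and all(target[a] == n_observed[a] for a in arms):
        plain = cox_hr(records, reference=ref, ci_level=ci_level)
        return PredictionResult(
            mode=mode, n_target=target, n_observed=n_observed,
            hr_predicted=plain.hazard_ratio, ci_low=plain.ci_low, ci_high=plain.ci_high,
            p_value=plain.p_value, log_hr=plain.log_hr, se=plain.se,
            n_boot=0, n_failed=0, flagged=False, seed=int(seed),
            treatment=treatment, reference=ref,
        )

    rng = np.random.default_rng(seed)
    log_hrs, ses = [], []
    n_failed = 0
    for _ in range(int(n_boot)):
        parts = []
        for a, idx in arms.items():
            if mode == "unconditional":
                parts.append(rng.choice(idx, size=target[a], replace=True))
            else:
                extra = target[a] - len(idx)
                parts.append(idx)
                if extra:
                    parts.append(rng.choice(idx, size=extra, replace=True))
        take = np.concatenate(parts)
        try:
            fit = fit_cox_binary(time[take], event[take], x[take])
        except IdentifiabilityError:
            n_failed += 1
            continue
        if not fit.converged or not np.isfinite(fit.se):
            n_failed += 1
            continue
        log_hrs.append(fit.beta)
        ses.append(fit.se)

    if not log_hrs:
        raise IdentifiabilityError("every bootstrap replicate failed to fit")
    log_hrs = np.asarray(log_hrs)
    ses = np.asarray(ses)
    mean_log_hr = float(log_hrs.mean())
    mean_se = float(ses.mean())
    if ci_method == "percentile":
        lo, hi = np.exp(np.quantile(log_hrs, [(1 - ci_level) / 2, (1 + ci_level) / 2]))
    elif ci_method == "wald":
        lo, hi = np.exp(mean_log_hr - z * mean_se), np.exp(mean_log_hr + z * mean_se)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    p = 2.0 * float(norm.sf(abs(mean_log_hr) / mean_se)) if mean_se > 0 else float("nan")

    return PredictionResult(
        mode=mode, n_target=target, n_observed=n_observed,
        hr_predicted=float(np.exp(mean_log_hr)), ci_low=float(lo), ci_high=float(hi),
        p_value=p, log_hr=mean_log_hr, se=mean_se,
        n_boot=int(n_boot), n_failed=n_failed,
        flagged=n_failed > 0.1 * int(n_boot), seed=int(seed),
        treatment=treatment, reference=ref,
        replicate_log_hrs=log_hrs,
    )
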