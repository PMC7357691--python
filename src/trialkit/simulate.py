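"""Synthetic two-arm trials with a terminal (cure) fraction.

The generator realizes the mixture event-time model

    T = (1 - eta) T* + eta * infinity,

where ``eta ~ Bernoulli(gamma)`` marks the terminal group (subjects who can
never experience the end point, e.g. deaths when the end point is clinical
improvement) and ``T*`` is a proper latency time.  Follow-up is
administratively censored at a fixed horizon (day 28 by default), and
terminal subjects are recorded as censored at that horizon — the convention
of the source trials, where deaths before day 28 were right-censored at
day 28.  The latent ``eta`` is stored in a ``truth_eta`` side column for
parameter-recovery tests; analysis modules never read it.

Defaults emulate an improvement-type end point under the structure the
analyses assume: terminal fractions (0.25, 0.40), exponential latency with
rate 0.2/day in both arms (latency hazard ratio 1; essentially every
non-terminal subject improves within the 28-day window, i.e. the cure
model's sufficient-follow-up condition holds), day-28 horizon, 1:1
allocation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError
from .km import km_fit
from .records import subset_arm, validate_records

DEFAULT_ARM_LABELS = ("treatment", "control")


@dataclass(frozen=True)
class SyntheticConfig:
    """Data-generating configuration for a two-arm mixture-terminal trial.

    Parameters
    ----------
    n_per_arm : subjects per arm, ordered as ``arm_labels``
    gamma_per_arm : terminal (cure) fraction per arm, each in [0, 1)
    latency_family : 'exponential' (params ``(rate,)`` per arm) or
        'weibull' (params ``(shape, scale)`` per arm)
    latency_params_per_arm : distribution parameters per arm, all > 0
    admin_censor_time : administrative censoring horizon in days
    allocation : randomization ratio, bookkeeping only (must match
        ``n_per_arm`` proportions when given)
    seed : root seed; per-arm child streams are spawned deterministically
    """

    n_per_arm: tuple[int, int] = (1000, 1000)
    gamma_per_arm: tuple[float, float] = (0.25, 0.40)
    latency_family: str = "exponential"
    latency_params_per_arm: tuple[tuple[float, ...], tuple[float, ...]] = ((0.2,), (0.2,))
    admin_censor_time: float = 28.0
    allocation: tuple[int, int] | None = None
    arm_labels: tuple[str, str] = DEFAULT_ARM_LABELS
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_arm) != 2 or any(int(n) <= 0 for n in self.n_per_arm):
            raise ConfigurationError("n_per_arm must be two positive integers")
        if any(not (0.0 <= g < 1.0) for g in self.gamma_per_arm):
            raise ConfigurationError("terminal fractions must satisfy 0 <= gamma < 1")
        if self.latency_family not in ("exponential", "weibull"):
            raise ConfigurationError(f"unknown latency family {self.latency_family!r}")
        n_params = 1 if self.latency_family == "exponential" else 2
        for params in self.latency_params_per_arm:
            if len(params) != n_params or any(p <= 0 for p in params):
                raise ConfigurationError(
                    f"{self.latency_family} latency needs {n_params} strictly "
                    f"positive parameter(s) per arm, got {params}"
                )
        if not (self.admin_censor_time > 0):
            raise ConfigurationError("admin_censor_time must be positive")
        if self.allocation is not None:
            a, b = self.allocation
            n0, n1 = self.n_per_arm
            if a <= 0 or b <= 0 or n0 * b != n1 * a:
                raise ConfigurationError(
                    f"arm sizes {self.n_per_arm} do not match allocation {a}:{b}"
                )

    def to_json(self) -> str:
        payload = {
            "n_per_arm": list(self.n_per_arm),
            "gamma_per_arm": list(self.gamma_per_arm),
            "latency_family": self.latency_family,
            "latency_params_per_arm": [list(p) for p in self.latency_params_per_arm],
            "admin_censor_time": self.admin_censor_time,
            "allocation": list(self.allocation) if self.allocation else None,
            "arm_labels": list(self.arm_labels),
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticConfig":
        raw = json.loads(text)
        return cls(
            n_per_arm=tuple(raw["n_per_arm"]),
            gamma_per_arm=tuple(raw["gamma_per_arm"]),
            latency_family=raw["latency_family"],
            latency_params_per_arm=tuple(tuple(p) for p in raw["latency_params_per_arm"]),
            admin_censor_time=raw["admin_censor_time"],
            allocation=tuple(raw["allocation"]) if raw.get("allocation") else None,
            arm_labels=tuple(raw.get("arm_labels", DEFAULT_ARM_LABELS)),
            seed=raw["seed"],
        )


def latency_survival(config: SyntheticConfig, arm_index: int, t) -> np.ndarray:
    """True latency survival S*(t) for one arm — closed form, used by oracles."""
    t = np.asarray(t, dtype=float)
    params = config.latency_params_per_arm[arm_index]
    if config.latency_family == "exponential":
        return np.exp(-params[0] * t)
    shape, scale = params
    return np.exp(-((t / scale) ** shape))


def _draw_latency(rng: np.random.Generator, config: SyntheticConfig, arm_index: int, n: int):
    params = config.latency_params_per_arm[arm_index]
    if config.latency_family == "exponential":
        return rng.exponential(scale=1.0 / params[0], size=n)
    shape, scale = params
    return scale * rng.weibull(shape, size=n)


def generate_trial(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate one trial; returns columns time, event, arm, truth_eta.

    Per arm each subject is terminal with probability gamma (time =
    ``admin_censor_time``, event = 0, eta = 1) or non-terminal with a
    latency draw censored at the horizon.  Identical config + seed yields
    byte-identical CSV output.
    """
    children = np.random.SeedSequence(config.seed).spawn(2)
    frames = []
    for k, (label, n, gamma) in enumerate(
        zip(config.arm_labels, config.n_per_arm, config.gamma_per_arm)
    ):
        rng = np.random.default_rng(children[k])
        n = int(n)
        eta = rng.random(n) < gamma
        latency = _draw_latency(rng, config, k, n)
        time = np.where(eta, config.admin_censor_time, np.minimum(latency, config.admin_censor_time))
        event = (~eta) & (latency <= config.admin_censor_time)
        frames.append(
            pd.DataFrame(
                {
                    "time": time,
                    "event": event.astype(int),
                    "arm": label,
                    "truth_eta": eta.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized cumulative-incidence step curve with its arm size.

    Emulates coordinates extracted from a published cumulative-incidence
    figure: ordered (time, incidence) pairs, the arm's sample size, and the
    administrative follow-up horizon.
    """

    times: np.ndarray
    incidence: np.ndarray
    arm_size: int
    horizon: float
    arm: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        inc = np.asarray(self.incidence, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "incidence", inc)
        if times.ndim != 1 or times.shape != inc.shape or len(times) == 0:
            raise ConfigurationError("curve needs matching nonempty time/incidence arrays")
        if np.any(np.diff(times) <= 0):
            raise ConfigurationError("curve times must be strictly increasing")
        if np.any(np.diff(inc) < -1e-12):
            raise ConfigurationError("cumulative incidence must be nondecreasing")
        if inc[0] < -1e-12 or inc[-1] > 1 + 1e-12:
            raise ConfigurationError("incidence must lie in [0, 1]")
        if int(self.arm_size) <= 0:
            raise ConfigurationError("arm_size must be positive")
        if not (self.horizon >= times[-1]):
            raise ConfigurationError("horizon must not precede the last curve time")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "incidence": self.incidence}).to_csv(
            path, index=False
        )
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"arm_size": int(self.arm_size), "horizon": float(self.horizon), "arm": self.arm},
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_csv(cls, path) -> "DigitizedCurve":
        frame = pd.read_csv(path)
        meta = json.loads(Path(path).with_suffix(".json").read_text())
        return cls(
            times=frame["time"].to_numpy(),
            incidence=frame["incidence"].to_numpy(),
            arm_size=meta["arm_size"],
            horizon=meta["horizon"],
            arm=meta.get("arm", ""),
        )


def emit_digitized_curve(
    records: pd.DataFrame, arm: str, grid: Sequence[float]
) -> DigitizedCurve:
    """Cumulative incidence 1 - KM for one arm, sampled on a time grid.

    This is the in-silico counterpart of digitizing a published figure:
    downstream code sees only (time, incidence) coordinates plus the arm
    size, exactly what plot extraction yields.
    """
    validate_records(records)
    sub = subset_arm(records, arm)
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) == 0:
        raise EmptyInputError("empty time grid")
    est = km_fit(sub)
    incidence = est.cumulative_incidence_at(grid)
    return DigitizedCurve(
        times=grid,
        incidence=incidence,
        arm_size=len(sub),
        horizon=float(max(est.max_time, grid[-1])),
        arm=str(arm),
    )
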