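"""Mixture terminal (cure) rate model for two-arm trials, fitted by EM.

The event time is modelled as a two-component mixture

    T = (1 - eta) T* + eta * infinity,

with ``eta ~ Bernoulli(gamma_arm)`` the latent terminal-group label (the
fraction of subjects, e.g. deaths, who can never reach the good end point)
and ``T*`` a proper latency time following a proportional-hazards model
with the arm indicator as covariate.  The population cumulative incidence
is ``F_T(t) = (1 - gamma) F_T*(t)``, plateauing at ``1 - gamma < 1``.

Fitting alternates an E-step (posterior susceptibility weights for censored
subjects) with an M-step (closed-form arm-wise incidence update — the exact
MLE of the saturated logistic model with arm as covariate — plus a
case-weighted latency update: Cox partial likelihood with Breslow baseline,
or Weibull MLE).  The observed-data log-likelihood is recorded every
iteration; it is nondecreasing up to numerical tolerance, a property the
test suite asserts.

Confidence intervals and P values come from a nonparametric bootstrap,
resampling subjects within arm (percentile intervals; P values from a
normal approximation on the bootstrap standard error).

Identifiability caveat: with administrative censoring at the horizon, the
terminal fraction is confounded with latency mass beyond follow-up.  The
semiparametric fit uses the usual zero-tail constraint (latency survival
set to 0 beyond the last event time), so "sufficient follow-up" — nearly
all non-terminal subjects reaching the end point within the window — is
assumed, not verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .errors import IdentifiabilityError, ValidationError
from .records import encode_arms, validate_records

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided confidence interval and optional P value."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float | None = None

    def to_dict(self) -> dict:
        out = {"estimate": self.estimate, "ci_low": self.ci_low, "ci_high": self.ci_high}
        if self.p_value is not None:
            out["p_value"] = self.p_value
        return out


@dataclass
class TerminalRateFit:
    """Fitted mixture terminal-rate model for a two-arm trial."""

    gamma: dict[str, IntervalEstimate]          # terminal fraction per arm (probability scale)
    gamma_difference: IntervalEstimate          # treatment - reference, percentage points
    latency_hr: IntervalEstimate                # hazard ratio among non-terminal subjects
    treatment: str
    reference: str
    latency: str
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    n_boot: int
    n_boot_failed: int
    seed: int
    _params: dict = field(default_factory=dict, repr=False)

    def latency_survival(self, t, arm: str) -> np.ndarray:
        """Fitted latency survival S*(t) for one arm."""
        xval = 1.0 if arm == self.treatment else 0.0
        return _latency_survival_from_params(self._params, np.asarray(t, float), xval)

    def population_incidence(self, t, arm: str) -> np.ndarray:
        """Fitted population cumulative incidence F_T(t) = (1 - gamma) F_T*(t)."""
        g = self.gamma[arm].estimate
        return (1.0 - g) * (1.0 - self.latency_survival(t, arm))

    def to_dict(self) -> dict:
        return {
            "gamma": {a: e.to_dict() for a, e in self.gamma.items()},
            "gamma_difference_pp": self.gamma_difference.to_dict(),
            "latency_hazard_ratio": self.latency_hr.to_dict(),
            "treatment": self.treatment,
            "reference": self.reference,
            "latency": self.latency,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
            "seed": self.seed,
        }


class _RiskSetEngine:
    """Pre-sorted sufficient statistics for repeated weighted two-group Cox fits.

    The EM refits the latency model with new case weights every iteration on
    unchanged (time, event, arm) data, so the sort order and tie structure
    are computed once.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray, x: np.ndarray):
        self.time = time
        self.event = event
        self.x = x
        self.ut, self.inv = np.unique(time, return_inverse=True)
        self.k = len(self.ut)
        d_tot = np.bincount(self.inv, weights=event, minlength=self.k)
        self.event_mask = d_tot > 0
        if not self.event_mask.any():
            raise IdentifiabilityError("no events: latency model is not identifiable")
        self.last_event_time = float(self.ut[self.event_mask][-1])

    def fit(self, weights: np.ndarray, beta_init: float = 0.0, tol: float = 1e-9,
            max_iter: int = 50):
        """Weighted Breslow partial-likelihood Newton fit; returns
        (beta, se, cumhaz at distinct event times, partial loglik)."""
        w = weights
        wsum0 = np.bincount(self.inv, weights=w * (1.0 - self.x), minlength=self.k)
        wsum1 = np.bincount(self.inv, weights=w * self.x, minlength=self.k)
        ed = np.bincount(self.inv, weights=w * self.event, minlength=self.k)
        edx = np.bincount(self.inv, weights=w * self.event * self.x, minlength=self.k)
        m = self.event_mask
        r0 = np.cumsum(wsum0[::-1])[::-1][m]
        r1 = np.cumsum(wsum1[::-1])[::-1][m]
        ed, edx = ed[m], edx[m]
        sum_edx = float(edx.sum())

        def loglik(b):
            return sum_edx * b - float(ed @ np.log(r0 + np.exp(b) * r1))

        beta = float(beta_init)
        ll = loglik(beta)
        for _ in range(max_iter):
            eb = np.exp(beta)
            denom = r0 + eb * r1
            p1 = eb * r1 / denom
            grad = sum_edx - float(ed @ p1)
            info = float(ed @ (p1 * (1.0 - p1)))
            if info <= 1e-300:
                break
            step = np.clip(grad / info, -2.0, 2.0)
            new_beta, new_ll = beta + step, loglik(beta + step)
            n_halve = 0
            while new_ll < ll - 1e-12 and n_halve < 30:
                step *= 0.5
                new_beta, new_ll = beta + step, loglik(beta + step)
                n_halve += 1
            beta, ll = new_beta, new_ll
            if abs(step) < tol or abs(grad) < tol:
                break
        eb = np.exp(beta)
        denom = r0 + eb * r1
        p1 = eb * r1 / denom
        info = float(ed @ (p1 * (1.0 - p1)))
        se = 1.0 / np.sqrt(info) if info > 0 else float("inf")
        cumhaz = np.cumsum(ed / denom)
        return beta, se, cumhaz, ll

    def cumhaz_at_subjects(self, cumhaz: np.ndarray) -> np.ndarray:
        """Baseline cumulative hazard evaluated at every subject's time."""
        event_times = self.ut[self.event_mask]
        idx = np.searchsorted(event_times, self.time, side="right")
        padded = np.concatenate([[0.0], cumhaz])
        return padded[idx]


def _latency_survival_from_params(params: dict, t: np.ndarray, xval: float) -> np.ndarray:
    if params["latency"] == "cox_ph":
        event_times, cumhaz = params["event_times"], params["cumhaz"]
        idx = np.searchsorted(event_times, t, side="right")
        padded = np.concatenate([[0.0], cumhaz])
        surv = np.exp(-padded[idx] * np.exp(params["beta"] * xval))
        return np.where(t > params["last_event_time"], 0.0, surv)
    shape, scale, beta = params["shape"], params["scale"], params["beta"]
    return np.exp(-((t / scale) ** shape) * np.exp(beta * xval))


def _em_cox(time, event, x, tol: float, max_iter: int):
    engine = _RiskSetEngine(time, event, x)
    beta = 0.0
    weights = np.where(event > 0, 1.0, 0.5)  # neutral start for censored subjects
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # M-step: saturated incidence model (closed-form per-arm weighted mean)
        n0, n1 = float(np.sum(x == 0)), float(np.sum(x == 1))
        g0 = float(np.sum((1.0 - weights)[x == 0]) / n0)
        g1 = float(np.sum((1.0 - weights)[x == 1]) / n1)
        g0, g1 = np.clip([g0, g1], 0.0, 1.0 - 1e-12)
        gamma_i = np.where(x > 0, g1, g0)
        beta, se, cumhaz, _ = engine.fit(weights, beta_init=beta)

        # latency survival at each subject's time, zero-tail beyond last event
        lam = engine.cumhaz_at_subjects(cumhaz)
        s_star = np.exp(-lam * np.exp(beta * x))
        s_star = np.where(time > engine.last_event_time, 0.0, s_star)

        # observed-data log-likelihood with the Breslow discrete hazard
        dlam = np.concatenate([[cumhaz[0]], np.diff(cumhaz)])
        dlam_at = np.zeros_like(time)
        ev = event > 0
        pos = np.searchsorted(engine.ut[engine.event_mask], time[ev])
        dlam_at[ev] = dlam[pos]
        ll_event = np.log(np.maximum((1.0 - gamma_i[ev]) * dlam_at[ev], _LOG_FLOOR)) \
            + beta * x[ev] - lam[ev] * np.exp(beta * x[ev])
        mix = gamma_i[~ev] + (1.0 - gamma_i[~ev]) * s_star[~ev]
        ll_cens = np.log(np.maximum(mix, _LOG_FLOOR))
        trace.append(float(ll_event.sum() + ll_cens.sum()))

        # E-step: posterior susceptibility weights for censored subjects
        num = (1.0 - gamma_i) * s_star
        denom = gamma_i + num
        with np.errstate(invalid="ignore", divide="ignore"):
            w_cens = np.where(denom > 0, num / denom, 0.0)
        new_weights = np.where(ev, 1.0, w_cens)

        delta = max(
            abs(float(np.sum((1.0 - new_weights)[x == 0]) / n0) - g0),
            abs(float(np.sum((1.0 - new_weights)[x == 1]) / n1) - g1),
        )
        param_shift = max(delta, float(np.max(np.abs(new_weights - weights))))
        weights = new_weights
        if param_shift < tol:
            converged = True
            break

    params = {
        "latency": "cox_ph",
        "beta": beta,
        "event_times": engine.ut[engine.event_mask],
        "cumhaz": cumhaz,
        "last_event_time": engine.last_event_time,
    }
    return {
        "gamma0": g0, "gamma1": g1, "beta": beta, "beta_se": se,
        "params": params, "loglik_trace": np.asarray(trace),
        "converged": converged, "n_iterations": n_iter, "weights": weights,
    }


def _weibull_neg_loglik(theta, time, event, x, weights):
    log_shape, log_scale, beta = theta
    shape, scale = np.exp(log_shape), np.exp(log_scale)
    h_cum = (time / scale) ** shape
    log_h = np.log(shape / scale) + (shape - 1.0) * np.log(np.maximum(time / scale, _LOG_FLOOR))
    lin = beta * x
    ll = weights * (event * (log_h + lin) - np.exp(lin) * h_cum)
    return -float(ll.sum())


def _em_weibull(time, event, x, tol: float, max_iter: int):
    theta = np.array([0.0, np.log(np.maximum(np.mean(time[event > 0]), 1e-6)), 0.0])
    weights = np.where(event > 0, 1.0, 0.5)
    trace = []
    converged = False
    n_iter = 0
    ev = event > 0
    for n_iter in range(1, max_iter + 1):
        n0, n1 = float(np.sum(x == 0)), float(np.sum(x == 1))
        g0 = float(np.sum((1.0 - weights)[x == 0]) / n0)
        g1 = float(np.sum((1.0 - weights)[x == 1]) / n1)
        g0, g1 = np.clip([g0, g1], 0.0, 1.0 - 1e-12)
        gamma_i = np.where(x > 0, g1, g0)
        res = optimize.minimize(
            _weibull_neg_loglik, theta, args=(time, event, x, weights), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        theta = res.x
        shape, scale, beta = np.exp(theta[0]), np.exp(theta[1]), theta[2]
        h_cum = (time / scale) ** shape
        s_star = np.exp(-h_cum * np.exp(beta * x))
        log_h = np.log(shape / scale) + (shape - 1.0) * np.log(np.maximum(time / scale, _LOG_FLOOR))
        ll_event = np.log(np.maximum(1.0 - gamma_i[ev], _LOG_FLOOR)) + log_h[ev] \
            + beta * x[ev] - h_cum[ev] * np.exp(beta * x[ev])
        mix = gamma_i[~ev] + (1.0 - gamma_i[~ev]) * s_star[~ev]
        trace.append(float(ll_event.sum() + np.log(np.maximum(mix, _LOG_FLOOR)).sum()))

        num = (1.0 - gamma_i) * s_star
        denom = gamma_i + num
        with np.errstate(invalid="ignore", divide="ignore"):
            w_cens = np.where(denom > 0, num / denom, 0.0)
        new_weights = np.where(ev, 1.0, w_cens)
        param_shift = float(np.max(np.abs(new_weights - weights)))
        weights = new_weights
        if param_shift < tol:
            converged = True
            break

    params = {"latency": "weibull", "shape": float(shape), "scale": float(scale),
              "beta": float(beta)}
    return {
        "gamma0": g0, "gamma1": g1, "beta": float(beta), "beta_se": float("nan"),
        "params": params, "loglik_trace": np.asarray(trace),
        "converged": converged, "n_iterations": n_iter, "weights": weights,
    }


def _em_dispatch(time, event, x, latency, tol, max_iter):
    if latency == "cox_ph":
        return _em_cox(time, event, x, tol, max_iter)
    if latency == "weibull":
        return _em_weibull(time, event, x, tol, max_iter)
    raise ValidationError(f"unknown latency model {latency!r}")


def fit_terminal_rate_model(
    records: pd.DataFrame,
    latency: str = "cox_ph",
    n_boot_ci: int = 1000,
    seed: int = 0,
    reference: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    ci_level: float = 0.95,
) -> TerminalRateFit:
    """Fit the mixture terminal-rate model to a two-arm trial.

    Parameters
    ----------
    records : subject records with columns time, event, arm (two arms)
    latency : 'cox_ph' (semiparametric, Breslow baseline) or 'weibull'
    n_boot_ci : bootstrap replicates for CIs and P values (0 disables them)
    seed : bootstrap seed
    reference : baseline arm label (defaults to a conventional control name)

    Returns a :class:`TerminalRateFit` with per-arm terminal fractions,
    their difference in percentage points, and the latency hazard ratio.
    Raises :class:`IdentifiabilityError` when an arm has no events.
    """
    validate_records(records, require_two_arms=True)
    x, treatment, ref = encode_arms(records, reference)
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=float)
    for xv, lab in ((0.0, ref), (1.0, treatment)):
        if event[x == xv].sum() == 0:
            raise IdentifiabilityError(f"arm {lab!r} has no events")

    main = _em_dispatch(time, event, x, latency, tol, max_iter)
    g_ref, g_trt, beta = main["gamma0"], main["gamma1"], main["beta"]

    rng = np.random.default_rng(seed)
    idx_ref = np.flatnonzero(x == 0.0)
    idx_trt = np.flatnonzero(x == 1.0)
    boot = {"g0": [], "g1": [], "beta": []}
    n_failed = 0
    for _ in range(int(n_boot_ci)):
        take = np.concatenate([
            rng.choice(idx_ref, size=len(idx_ref), replace=True),
            rng.choice(idx_trt, size=len(idx_trt), replace=True),
        ])
        tb, eb, xb = time[take], event[take], x[take]
        if eb[xb == 0].sum() == 0 or eb[xb == 1].sum() == 0:
            n_failed += 1
            continue
        try:
            rep = _em_dispatch(tb, eb, xb, latency, tol, max_iter)
        except IdentifiabilityError:
            n_failed += 1
            continue
        boot["g0"].append(rep["gamma0"])
        boot["g1"].append(rep["gamma1"])
        boot["beta"].append(rep["beta"])

    z = norm.ppf(0.5 + ci_level / 2.0)
    lo_q, hi_q = (1.0 - ci_level) / 2.0, (1.0 + ci_level) / 2.0

    def interval(est, draws, p_from=None):
        if len(draws) == 0:
            return IntervalEstimate(est, float("nan"), float("nan"), None)
        draws = np.asarray(draws, dtype=float)
        lo, hi = np.quantile(draws, [lo_q, hi_q])
        p = None
        if p_from is not None:
            se = float(draws.std(ddof=1)) if len(draws) > 1 else float("nan")
            p = 2.0 * float(norm.sf(abs(p_from) / se)) if se > 0 else float("nan")
        return IntervalEstimate(float(est), float(lo), float(hi), p)

    gamma = {
        ref: interval(g_ref, boot["g0"]),
        treatment: interval(g_trt, boot["g1"]),
    }
    diff_pp = 100.0 * (g_trt - g_ref)
    diff_draws = [100.0 * (b - a) for a, b in zip(boot["g0"], boot["g1"])]
    gamma_difference = interval(diff_pp, diff_draws, p_from=diff_pp)

    hr_draws = np.exp(np.asarray(boot["beta"], dtype=float)) if boot["beta"] else []
    latency_hr = interval(float(np.exp(beta)), hr_draws)
    if len(boot["beta"]):
        se_b = float(np.asarray(boot["beta"]).std(ddof=1))
        p_hr = 2.0 * float(norm.sf(abs(beta) / se_b)) if se_b > 0 else float("nan")
        latency_hr = IntervalEstimate(latency_hr.estimate, latency_hr.ci_low,
                                      latency_hr.ci_high, p_hr)

    return TerminalRateFit(
        gamma=gamma,
        gamma_difference=gamma_difference,
        latency_hr=latency_hr,
        treatment=treatment,
        reference=ref,
        latency=latency,
        n_iterations=main["n_iterations"],
        converged=main["converged"],
        loglik_trace=main["loglik_trace"],
        n_boot=int(n_boot_ci),
        n_boot_failed=n_failed,
        seed=int(seed),
        _params=main["params"],
    )


def posterior_terminal_weights(records: pd.DataFrame, latency: str = "cox_ph",
                               reference: str | None = None,
                               tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Posterior probability of terminal-group membership per subject (events: 0)."""
    validate_records(records, require_two_arms=True)
    x, _, _ = encode_arms(records, reference)
    time = np.asarray(records["time"], dtype=float)
    event = np.asarray(records["event"], dtype=float)
    main = _em_dispatch(time, event, x, latency, tol, max_iter)
    return 1.0 - main["weights"]
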