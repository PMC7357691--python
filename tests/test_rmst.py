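"""Restricted means and incidence percentiles."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.utils import restricted_mean_survival_time

from trialkit import (
    SyntheticConfig,
    generate_trial,
    km_fit,
    make_records,
    percentile_at,
    rmst_at,
)
from trialkit.errors import ExtrapolationError, ValidationError
from trialkit.rmst import rmst_from_km


def _two_arm(records_a, records_b):
    return pd.concat([records_a, records_b], ignore_index=True)


def _step_integral_oracle(est, tau, n_grid=10_000):
    """Exact integral of the KM step function via knots = grid U event times."""
    knots = np.unique(np.concatenate([np.linspace(0, tau, n_grid), est.times, [tau]]))
    knots = knots[knots <= tau]
    widths = np.diff(np.concatenate([knots, [tau]]))
    return float(np.sum(est.survival_at(knots) * widths))


class TestRMSTPoint:
    def test_single_event_day5(self):
        est = km_fit(make_records([5.0], [1], "a"))
        area, _ = rmst_from_km(est, 10.0)
        assert area == pytest.approx(5.0)

    def test_no_events_by_tau_gives_tau_with_zero_se(self):
        est = km_fit(make_records([20, 20, 20], [0, 0, 0], "a"))
        area, se = rmst_from_km(est, 15.0)
        assert area == pytest.approx(15.0) and se == 0.0

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(77)
        latent = rng.exponential(scale=10.0, size=5000)
        censor = rng.uniform(30, 60, size=5000)  # heavy follow-up
        time = np.minimum(latent, censor)
        event = (latent <= censor).astype(int)
        est = km_fit(make_records(time, event, "a"))
        area, se = rmst_from_km(est, 28.0)
        assert abs(area - (1 - np.exp(-2.8)) / 0.1) < 3 * se

    def test_tau_beyond_follow_up_rejected(self):
        est = km_fit(make_records([5, 8], [1, 0], "a"))
        with pytest.raises(ExtrapolationError):
            rmst_from_km(est, 9.0)

    def test_agrees_with_lifelines_restricted_mean(self, mixture_trial):
        sub = mixture_trial[mixture_trial["arm"] == "control"]
        est = km_fit(sub)
        ours, _ = rmst_from_km(est, 28.0)
        kmf = KaplanMeierFitter().fit(sub["time"], sub["event"])
        theirs = restricted_mean_survival_time(kmf, t=28.0)
        assert ours == pytest.approx(float(theirs), abs=1e-8)

    @pytest.mark.parametrize("tau", [7.0, 14.0, 28.0])
    def test_step_integration_oracle_and_incidence_identity(self, mixture_trial, tau):
        for arm in ("treatment", "control"):
            est = km_fit(mixture_trial[mixture_trial["arm"] == arm])
            area, _ = rmst_from_km(est, tau)
            assert area == pytest.approx(_step_integral_oracle(est, tau), abs=1e-9)
            # area under the incidence curve + RMST = tau exactly
            knots = np.unique(np.concatenate([[0.0], est.times[est.times <= tau], [tau]]))
            widths = np.diff(np.concatenate([knots, [tau]]))
            area_inc = float(np.sum(est.cumulative_incidence_at(knots) * widths))
            assert area + area_inc == pytest.approx(tau, abs=1e-9)


class TestRMSTDifference:
    def test_monotone_in_tau(self, mixture_trial):
        estimates = [
            rmst_at(mixture_trial, tau).per_arm["treatment"].estimate
            for tau in (7, 14, 21, 28)
        ]
        assert np.all(np.diff(estimates) > 0)

    def test_difference_is_treatment_minus_reference(self, mixture_trial):
        res = rmst_at(mixture_trial, 28.0)
        assert res.arms == ("treatment", "control")
        expected = res.per_arm["treatment"].estimate - res.per_arm["control"].estimate
        assert res.difference == pytest.approx(expected)
        assert res.diff_ci[0] < res.difference < res.diff_ci[1]


class TestPercentiles:
    def test_empirical_median(self):
        trial = _two_arm(
            make_records([1, 2, 3, 4], [1, 1, 1, 1], "t"),
            make_records([2, 3, 4, 5], [1, 1, 1, 1], "control"),
        )
        res = percentile_at(trial, 0.5, n_boot=50, seed=0)
        assert res.per_arm["t"].time == 2.0
        assert res.per_arm["control"].time == 3.0
        assert res.difference == pytest.approx(-1.0)

    def test_unattained_percentile_flagged_undefined(self):
        trial = _two_arm(
            make_records([1, 28, 28, 28], [1, 0, 0, 0], "t"),
            make_records([1, 2, 3, 4], [1, 1, 1, 1], "control"),
        )
        res = percentile_at(trial, 0.6, n_boot=20, seed=0)
        assert not res.defined
        assert not res.per_arm["t"].defined
        assert res.difference is None and res.p_value is None

    def test_invalid_p_rejected(self, mixture_trial):
        with pytest.raises(ValidationError):
            percentile_at(mixture_trial, 1.5)

    def test_null_calibration_ci_covers_zero(self):
        # identical arms: the difference CI should cover 0 in >= 90% of runs
        covered = 0
        n_runs = 30
        for seed in range(n_runs):
            config = SyntheticConfig(
                n_per_arm=(120, 120), gamma_per_arm=(0.25, 0.25), seed=1000 + seed
            )
            trial = generate_trial(config)
            res = percentile_at(trial, 0.5, n_boot=120, seed=seed)
            if res.defined and res.diff_ci[0] <= 0.0 <= res.diff_ci[1]:
                covered += 1
        assert covered >= 0.9 * n_runs
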