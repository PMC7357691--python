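"""Mixture terminal-rate model: recovery, degeneracy, EM monotonicity."""

import numpy as np
import pytest

from trialkit import (
    SyntheticConfig,
    cox_hr,
    fit_terminal_rate_model,
    generate_trial,
    make_records,
)
from trialkit.cure import posterior_terminal_weights
from trialkit.errors import IdentifiabilityError
import pandas as pd


@pytest.fixture(scope="module")
def recovery_fit():
    config = SyntheticConfig(n_per_arm=(2000, 2000), seed=314)
    records = generate_trial(config)
    fit = fit_terminal_rate_model(records, n_boot_ci=120, seed=9)
    return config, records, fit


class TestParameterRecovery:
    def test_gamma_recovered_within_bootstrap_uncertainty(self, recovery_fit):
        config, _, fit = recovery_fit
        truth = dict(zip(config.arm_labels, config.gamma_per_arm))
        for arm, est in fit.gamma.items():
            half_width = (est.ci_high - est.ci_low) / 2.0
            se = half_width / 1.96
            assert abs(est.estimate - truth[arm]) < 3 * se, arm

    def test_null_latency_hr_ci_covers_one(self, recovery_fit):
        _, _, fit = recovery_fit
        assert fit.latency_hr.ci_low <= 1.0 <= fit.latency_hr.ci_high

    def test_loglik_nondecreasing_every_iteration(self, recovery_fit):
        _, _, fit = recovery_fit
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-7 * np.abs(trace[:-1]))
        assert fit.converged

    def test_fitted_incidence_plateaus_below_one(self, recovery_fit):
        _, _, fit = recovery_fit
        for arm in fit.gamma:
            plateau = float(fit.population_incidence(1e9, arm))
            assert plateau == pytest.approx(1.0 - fit.gamma[arm].estimate, abs=1e-9)
            assert plateau < 1.0


class TestDegenerateNoCure:
    def test_gamma_near_zero_and_hr_matches_plain_cox(self, no_cure_trial):
        fit = fit_terminal_rate_model(no_cure_trial, n_boot_ci=0)
        for est in fit.gamma.values():
            assert est.estimate < 0.01
        plain = cox_hr(no_cure_trial)
        assert fit.latency_hr.estimate == pytest.approx(plain.hazard_ratio, abs=1e-3)


class TestEdgeCases:
    def test_arm_without_events_raises(self):
        records = pd.concat(
            [
                make_records([1, 2, 3, 28], [1, 1, 1, 0], "t"),
                make_records([28, 28, 28], [0, 0, 0], "control"),
            ],
            ignore_index=True,
        )
        with pytest.raises(IdentifiabilityError):
            fit_terminal_rate_model(records, n_boot_ci=0)

    def test_late_censored_subjects_have_highest_terminal_weight(self, mixture_trial):
        weights = posterior_terminal_weights(mixture_trial)
        time = mixture_trial["time"].to_numpy()
        event = mixture_trial["event"].to_numpy()
        for arm in ("treatment", "control"):
            sel = (mixture_trial["arm"] == arm).to_numpy()
            last_event = time[sel & (event == 1)].max()
            late = sel & (event == 0) & (time > last_event)
            others = sel & ~late
            assert late.any()
            assert weights[late].min() >= weights[others].max() - 1e-12

    def test_bootstrap_seed_reproducible(self, mixture_trial):
        a = fit_terminal_rate_model(mixture_trial, n_boot_ci=40, seed=5)
        b = fit_terminal_rate_model(mixture_trial, n_boot_ci=40, seed=5)
        assert a.to_dict() == b.to_dict()


class TestWeibullLatency:
    def test_weibull_latency_recovers_gamma(self):
        config = SyntheticConfig(
            n_per_arm=(500, 500),
            gamma_per_arm=(0.3, 0.3),
            latency_family="weibull",
            latency_params_per_arm=((1.3, 6.0), (1.3, 6.0)),
            seed=21,
        )
        records = generate_trial(config)
        fit = fit_terminal_rate_model(records, latency="weibull", n_boot_ci=0)
        for est in fit.gamma.values():
            assert abs(est.estimate - 0.3) < 0.05
        trace = fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))
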