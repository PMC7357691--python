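"""Synthetic-data generator: mixture structure, bookkeeping, reproducibility."""

import io

import numpy as np
import pytest

from trialkit import (
    SyntheticConfig,
    emit_digitized_curve,
    generate_trial,
    km_fit,
    latency_survival,
    make_records,
)
from trialkit.errors import ConfigurationError, EmptyInputError


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gamma_per_arm": (1.0, 0.2)},
            {"gamma_per_arm": (-0.1, 0.2)},
            {"latency_params_per_arm": ((0.0,), (0.1,))},
            {"latency_params_per_arm": ((-1.0,), (0.1,))},
            {"admin_censor_time": 0.0},
            {"n_per_arm": (0, 10)},
            {"n_per_arm": (158, 80), "allocation": (2, 1)},
            {"latency_family": "gamma"},
            {"latency_family": "weibull", "latency_params_per_arm": ((1.0,), (1.0,))},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(**kwargs)

    def test_json_round_trip(self):
        config = SyntheticConfig(n_per_arm=(158, 79), allocation=(2, 1), seed=11)
        assert SyntheticConfig.from_json(config.to_json()) == config


class TestGenerateTrial:
    def test_no_cure_no_censoring_gives_all_events(self):
        config = SyntheticConfig(
            n_per_arm=(50, 50), gamma_per_arm=(0.0, 0.0), admin_censor_time=1e9, seed=3
        )
        records = generate_trial(config)
        assert (records["event"] == 1).all()

    def test_allocation_bookkeeping(self):
        config = SyntheticConfig(n_per_arm=(158, 79), allocation=(2, 1), seed=5)
        records = generate_trial(config)
        sizes = records.groupby("arm").size()
        assert sizes["treatment"] == 158 and sizes["control"] == 79

    def test_event_free_proportion_matches_mixture_closed_form(self):
        # P(no event by tau) = gamma + (1 - gamma) S*(tau)
        config = SyntheticConfig(
            n_per_arm=(20000, 20000), gamma_per_arm=(0.3, 0.3), seed=99
        )
        records = generate_trial(config)
        tau = config.admin_censor_time
        for k, arm in enumerate(config.arm_labels):
            sub = records[records["arm"] == arm]
            expected = config.gamma_per_arm[k] + (
                1 - config.gamma_per_arm[k]
            ) * float(latency_survival(config, k, tau))
            observed = float((sub["event"] == 0).mean())
            mc_se = np.sqrt(expected * (1 - expected) / len(sub))
            assert abs(observed - expected) < 3 * mc_se

    def test_seed_reproducibility_byte_identical(self):
        config = SyntheticConfig(n_per_arm=(100, 100), seed=42)
        buffers = []
        for _ in range(2):
            buf = io.StringIO()
            generate_trial(config).to_csv(buf, index=False)
            buffers.append(buf.getvalue())
        assert buffers[0] == buffers[1]

    def test_terminal_subjects_censored_at_horizon(self):
        config = SyntheticConfig(n_per_arm=(200, 200), gamma_per_arm=(0.5, 0.5), seed=1)
        records = generate_trial(config)
        terminal = records[records["truth_eta"] == 1]
        assert (terminal["event"] == 0).all()
        assert (terminal["time"] == config.admin_censor_time).all()


class TestEmitDigitizedCurve:
    def test_single_event_step(self):
        records = make_records([5.0], [1], "a")
        curve = emit_digitized_curve(records, "a", grid=range(1, 11))
        expected = np.where(np.arange(1, 11) >= 5, 1.0, 0.0)
        np.testing.assert_allclose(curve.incidence, expected)

    def test_all_censored_identically_zero(self):
        records = make_records([10.0] * 8, [0] * 8, "a")
        curve = emit_digitized_curve(records, "a", grid=[2, 4, 6, 8])
        np.testing.assert_allclose(curve.incidence, 0.0)

    def test_matches_km_complement(self, mixture_trial):
        grid = np.arange(1.0, 29.0)
        curve = emit_digitized_curve(mixture_trial, "treatment", grid)
        est = km_fit(mixture_trial[mixture_trial["arm"] == "treatment"])
        np.testing.assert_allclose(curve.incidence, 1.0 - est.survival_at(grid), atol=1e-12)
        assert np.all(np.diff(curve.incidence) >= 0)
        assert curve.arm_size == 500

    def test_empty_arm_rejected(self, mixture_trial):
        with pytest.raises(EmptyInputError):
            emit_digitized_curve(mixture_trial, "no-such-arm", grid=[1, 2])
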