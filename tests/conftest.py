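import numpy as np
import pandas as pd
import pytest

from trialkit import SyntheticConfig, generate_trial, make_records


@pytest.fixture(scope="session")
def mixture_trial():
    """Default-condition mixture trial, 500/arm, fixed seed."""
    return generate_trial(SyntheticConfig(n_per_arm=(500, 500), seed=20260919))


@pytest.fixture(scope="session")
def no_cure_trial():
    """Two-arm trial without a terminal fraction and negligible censoring."""
    config = SyntheticConfig(
        n_per_arm=(400, 400),
        gamma_per_arm=(0.0, 0.0),
        latency_params_per_arm=((0.2,), (0.25,)),
        admin_censor_time=500.0,
        seed=7,
    )
    return generate_trial(config)


@pytest.fixture
def four_event_arm():
    """Four subjects, events at days 1..4, no censoring."""
    return make_records([1, 2, 3, 4], [1, 1, 1, 1], "a")
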