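import numpy as np
import pandas as pd
import pytest

from speechrsa.epochs import Epochs
from speechrsa.synthgen import SynthConfig, make_ground_truth, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, fs=500.0, t0_ms=-1000.0, conditions=None, **meta):
    """Small helper to build an Epochs container around a raw array."""
    n_trials, n_channels, n_samples = data.shape
    times = t0_ms + np.arange(n_samples) * 1000.0 / fs
    if conditions is None:
        conditions = ["a"] * n_trials
    trials = pd.DataFrame({"condition": conditions})
    return Epochs(
        data=np.asarray(data, dtype=float),
        fs=fs,
        times=times,
        ch_names=[f"E{c + 1:03d}" for c in range(n_channels)],
        trials=trials,
        **meta,
    )


@pytest.fixture
def small_config():
    """Reduced-scale study used across tests: fast but structurally complete."""
    return SynthConfig(
        n_subjects_per_group=2,
        n_channels=16,
        trials_per_condition=8,
        effect_scale=2.0,
        noise_white_sd=1.0,
        ears_implanted=("non-CI",),
        seed=42,
    )


@pytest.fixture
def small_subject(small_config):
    truth = make_ground_truth(small_config)
    return generate_subject(
        small_config, truth, "control", 0, "reference", "earphone"
    )
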