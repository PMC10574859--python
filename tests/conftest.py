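import numpy as np
import pytest

from wmeeg.recording import DEFAULT_CHANNELS, Montage, Recording
from wmeeg.synth import SynthConfig, generate_dataset


@pytest.fixture
def montage():
    return Montage()


@pytest.fixture
def make_recording():
    """Factory for sinusoidal multichannel recordings."""

    def _make(
        n_channels=10,
        n_samples=1000,
        fs=1000.0,
        freq=10.0,
        amplitude=20.0,
        state="task",
        channel_names=None,
        seed=0,
    ):
        rng = np.random.default_rng(seed)
        t = np.arange(n_samples) / fs
        data = np.vstack(
            [
                amplitude * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
                for _ in range(n_channels)
            ]
        )
        names = channel_names or list(DEFAULT_CHANNELS[:n_channels])
        return Recording(
            subject_id="s001",
            trial_id="t001",
            state=state,
            fs=fs,
            channel_names=names,
            data=data,
        )

    return _make


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic study (20 subjects x 2 sessions x 3 trials),
    shared across tests that only read it."""
    return generate_dataset(SynthConfig(seed=7))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_dataset(
        SynthConfig(seed=7, noise_sd=0.0, label_noise_sd=0.0)
    )
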