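import numpy as np
import pytest

from eegpotato.synth import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def artifact_fixture():
    """Standard artifact-contaminated recording: 500 epochs, 5% artifact
    rate at 20x gain, no seizures, seed 1."""
    cfg = SynthConfig(duration=1000.0, artifact_rate=5.0, artifact_gain=20.0,
                      seed=1)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def seizure_fixture():
    """Standard seizure recording: 400 s with one 60 s seizure at 4x ictal
    gain plus sparse artifacts, seed 1."""
    cfg = SynthConfig(duration=400.0, seizure_intervals=((100.0, 160.0),),
                      ictal_gain=4.0, artifact_rate=5.0, artifact_gain=20.0,
                      seed=1)
    rec, truth = generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    """A well-conditioned random SPD matrix."""
    a = rng.standard_normal((n, 2 * n))
    return a @ a.T / (2 * n) + 0.5 * np.eye(n)
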