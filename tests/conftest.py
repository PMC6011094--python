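import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecgsqi.io import AnalysisConfig
from ecgsqi.synthetic import SynthesisSpec, generate, generate_clean

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def clean_labeled():
    """30 s clean synthetic ECG at 60 bpm with slight RR jitter."""
    return generate_clean(SynthesisSpec(fs=300.0, duration_s=30.0,
                                        heart_rate_bpm=60.0,
                                        hr_jitter_frac=0.02, seed=123))


@pytest.fixture(scope="session")
def clean_record(clean_labeled):
    return clean_labeled.record


@pytest.fixture(scope="session")
def emg_heavy_labeled():
    """Clean template drowned in 20-40 Hz muscle-band noise (RMS 1.5x R)."""
    return generate(SynthesisSpec(fs=300.0, duration_s=30.0, heart_rate_bpm=60.0,
                                  noise_amplitudes={"emg": 1.5}, seed=29))


def sensitivity(detected: np.ndarray, truth: np.ndarray, fs: float,
                tol_s: float = 0.05) -> float:
    """Fraction of true beats with a detection within +-tol_s."""
    if len(truth) == 0:
        return float("nan")
    if len(detected) == 0:
        return 0.0
    d = np.asarray(detected) / fs
    return float(np.mean([np.min(np.abs(d - t)) <= tol_s
                          for t in np.asarray(truth) / fs]))


@pytest.fixture(scope="session")
def sens():
    return sensitivity
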