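import numpy as np
import pytest
from hypothesis import settings

from nirscreen.synth import CohortConfig, NuisanceAmplitudes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def narrowband(n, fs=8.138, band=(0.01, 0.1), seed=0, n_series=1):
    """Unit-variance band-limited Gaussian noise for estimator tests."""
    from scipy import signal

    rng = np.random.default_rng(seed)
    x = signal.sosfiltfilt(
        signal.butter(3, band, btype="bandpass", fs=fs, output="sos"),
        rng.standard_normal((n, n_series)),
        axis=0,
    )
    x /= x.std(axis=0, ddof=0)
    return x[:, 0] if n_series == 1 else x


@pytest.fixture(scope="session")
def fs():
    return 8.138


@pytest.fixture
def short_cohort_config():
    """Small, fast cohort: 2-minute recordings, light nuisance."""
    return CohortConfig(
        group_sizes={"NC": 3, "SCD": 3, "MCI": 3},
        duration_s=120.0,
        seed=11,
    )


@pytest.fixture
def clean_config():
    """Generator settings with nuisance, noise and artifacts disabled."""
    return CohortConfig(
        duration_s=300.0,
        nuisance=NuisanceAmplitudes(cardiac=0, respiratory=0, mayer=0, drift=0),
        artifact_rate_per_min=0.0,
        noise_sd=0.0,
    )
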