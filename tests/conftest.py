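import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from actimetry.io import RawRecording
from actimetry.synthetic import CohortSpec, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_recording(samples, fs=30.0, site="non_dominant_wrist",
                   participant="P01", start="2019-01-07", calibrated=True):
    return RawRecording(
        participant_id=participant,
        site=site,
        start_time=pd.Timestamp(start),
        sampling_rate=fs,
        samples=np.asarray(samples, dtype=float),
        calibrated=calibrated,
    )


def constant_recording(vec, seconds, fs=30.0, noise_sd_mg=0.0, seed=0, **kw):
    n = int(round(seconds * fs))
    samples = np.tile(np.asarray(vec, dtype=float), (n, 1))
    if noise_sd_mg:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0, noise_sd_mg / 1000.0, samples.shape)
    return make_recording(samples, fs=fs, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """3 participants x 2 days x 3 sites at 30 Hz with guaranteed non-wear."""
    spec = CohortSpec(n_participants=3, n_days=2, seed=42, nonwear_rate=1.0)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def clean_cohort():
    """2 participants x 2 days, wrists only, no non-wear (sleep-detection tests)."""
    spec = CohortSpec(
        n_participants=2, n_days=2, seed=7, nonwear_rate=0.0,
        sites=("dominant_wrist", "non_dominant_wrist"),
    )
    return spec, generate_cohort(spec)
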