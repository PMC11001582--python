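import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_recording():
    """Tiny high-SNR synthetic recording for fast end-to-end checks."""
    from neurophen import synthdata

    rec, truth = synthdata.gen_calcium(
        n_rois=20, duration_s=120.0, frac_hyper=0.2, rate_hyper=8.0, rate_base=1.0,
        snr=15.0, seed=42,
    )
    return rec, truth
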