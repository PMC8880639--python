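import numpy as np
import pytest

from lastkit.pipeline import process_scan
from lastkit.synthetic import SyntheticSpec, render_series


def clean_spec(**overrides) -> SyntheticSpec:
    """A noise-free, jitter-free rendering spec: exact, reproducible geometry."""
    base = dict(noise_sd=0.0, speckle_rate=0.0, char_width_sd=0.0,
                char_height_sd=0.0, p_perseveration=0.0, skew_sd=0.0, seed=0)
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def clean_scan():
    """One noise-free rendered scan: (GrayImage, LabelOverlay, SyntheticTruth)."""
    return render_series(clean_spec())


@pytest.fixture(scope="session")
def clean_result(clean_scan):
    """Pipeline output for the noise-free scan (shared across tests)."""
    gray, _, truth = clean_scan
    return process_scan(gray, examiner_n=truth.examiner_n)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
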