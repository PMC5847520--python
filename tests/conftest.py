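import numpy as np
import pytest

from vulturedyn import cjs_survival as cjs
from vulturedyn import synthetic_data as sd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture()
def tiny_histories():
    """Four birds, four occasions, mixed covariates."""
    hist = np.array(
        [
            [1, 1, 0, 1],
            [1, 0, 0, 0],
            [0, 1, 1, 0],
            [0, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return cjs.CaptureHistorySet(
        histories=hist,
        region=np.array(["Kruger", "Kruger", "KZN", "KZN"]),
        age_at_release=np.array(["juvenile", "adult", "subadult", "juvenile"]),
        release_occasion=np.array([0, 0, 1, 2]),
    )


@pytest.fixture(scope="session")
def medium_synthetic():
    """A moderately sized simulated study reused by several fitting tests."""
    spec = sd.study_like_spec(seed=4, n_scale=8.0)
    return sd.generate_capture_histories(spec)
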