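import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import confdepth as cd

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_instance(seed: int, shape=(16, 20), noise_sd=0.05):
    """A (pred, supervision) pair with mixed confidences, no gross outliers."""
    r = np.random.default_rng(seed)
    truth = r.uniform(0.3, 1.0, shape)
    pred = cd.InverseDepthMap(2.0 * truth + 0.5 + r.normal(0, noise_sd, shape))
    conf = r.uniform(0.05, 1.0, shape)
    conf[:, 0] = 0.0  # occlusion column
    disp = truth.copy()
    disp[:, 0] = np.nan
    frame = cd.SupervisionFrame(
        cd.InverseDepthMap(disp), cd.ConfidenceMap(conf)
    )
    return pred, frame


@pytest.fixture
def small_pair():
    return make_instance(7)
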