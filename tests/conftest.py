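import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from depnet import headmodel, inverse

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rois():
    return inverse.load_roi_table()


@pytest.fixture(scope="session")
def grid50(rois):
    """50-node source grid: the 18 ROI centres plus 32 random interior nodes."""
    return headmodel.build_source_grid(inverse.roi_positions(rois), n_extra=32, seed=7)


@pytest.fixture(scope="session")
def leadfield50(grid50):
    return headmodel.gen_leadfield(grid50)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
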