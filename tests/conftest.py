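import numpy as np
import pytest
from hypothesis import settings

from topoquant.simulate import GelGeometry, NoiseModel, make_topoisomer_distribution

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

#: densitometry settings used by the end-to-end checks (match RunConfig defaults)
QUANTIFY_KW = dict(
    background_window_px=180,
    min_prominence_frac=0.02,
    min_separation_px=20.0,
    smoothing_sigma_px=4.0,
    min_width_px=14.0,
)


@pytest.fixture(scope="session")
def geometry() -> GelGeometry:
    return GelGeometry()


@pytest.fixture
def seven_band_dist():
    """A ladder whose 7 bands all sit above the 5% prominence threshold."""
    return make_topoisomer_distribution(3.0, 1.4, 3)


@pytest.fixture
def quiet_noise():
    return NoiseModel()
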