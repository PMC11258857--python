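import numpy as np
import pytest
from hypothesis import settings

import redoxscreen as rs
from redoxscreen.synthetic import intensities_for_orr, random_cell_mask
from redoxscreen.widefield import WidefieldConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def irf() -> rs.IRF:
    """Default instrument response: 240 ps FWHM Gaussian, 256 x 48.8 ps bins."""
    return rs.make_irf()


@pytest.fixture(scope="session")
def decay_truth() -> rs.DecayGroundTruth:
    """Typical NAD(P)H decay: 400 ps free / 2500 ps bound, 70 % free."""
    return rs.DecayGroundTruth(tau1=400.0, tau2=2500.0, a1=0.7,
                               photons_target=1000.0)


@pytest.fixture(scope="session")
def small_cube(decay_truth, irf) -> rs.DecayCube:
    return rs.simulate_decay_cube(decay_truth, irf, shape=(8, 8), seed=11)


@pytest.fixture(scope="session")
def fov_config() -> WidefieldConfig:
    """FOV pipeline knobs scaled to the 192 px synthetic field geometry."""
    return WidefieldConfig(rolling_ball_radius=24, roi_size=24,
                           background_margin=6)


def make_field_truth(orr: float = 0.6, seed: int = 3, vignette: float = 0.15,
                     shape=(192, 192)) -> rs.FieldGroundTruth:
    mask = random_cell_mask(shape, rng=seed)
    return rs.FieldGroundTruth(mask, vignette_strength=vignette,
                               **intensities_for_orr(orr))


@pytest.fixture
def field_truth() -> rs.FieldGroundTruth:
    return make_field_truth()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
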