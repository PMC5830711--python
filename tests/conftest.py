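import numpy as np
import pytest

from countershade.body_geometry import EllipsoidSpec, make_ellipsoid
from countershade.countershading import (
    compute_irradiance_field,
    matched_uniform_level,
    optimal_pattern,
    uniform_pattern,
)
from countershade.sky_irradiance import SkyModel
from countershade.synthetic_observer import simulate_experiment


@pytest.fixture(scope="session")
def cloudy_sky():
    return SkyModel("overcast")


@pytest.fixture(scope="session")
def sunny_sky():
    return SkyModel("clear_sun")


@pytest.fixture(scope="session")
def ellipsoid():
    return make_ellipsoid(EllipsoidSpec())


@pytest.fixture(scope="session")
def fields(ellipsoid, cloudy_sky, sunny_sky):
    return {
        "cloudy": compute_irradiance_field(ellipsoid, cloudy_sky),
        "sunny": compute_irradiance_field(ellipsoid, sunny_sky),
    }


@pytest.fixture(scope="session")
def patterns(ellipsoid, fields):
    out = {
        "cloudy_CS": optimal_pattern(fields["cloudy"], "cloudy_CS"),
        "sunny_CS": optimal_pattern(fields["sunny"], "sunny_CS"),
    }
    level = matched_uniform_level([out["cloudy_CS"], out["sunny_CS"]])
    out["no_CS"] = uniform_pattern(ellipsoid, level, "no_CS")
    return out


@pytest.fixture(scope="session")
def default_records():
    """One full simulated experiment (9 participants x 2 sessions)."""
    return simulate_experiment(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
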