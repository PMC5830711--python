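"""Sky luminance models and hemispheric irradiance quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countershade.sky_irradiance import (
    SkyModel,
    diffuse_irradiance,
    sky_luminance,
    sun_direction,
    total_irradiance,
)

# Monte-Carlo hemisphere-sampling oracle values (10^6 uniform-cosine-free
# samples, seed 0) for the default clear sky, frozen as (mean, SE):
MC_CLEAR = {
    (0.0, 0.0, 1.0): (4.850051, 0.004441),
    (0.0, -0.7071, 0.7071): (6.183142, 0.007928),
    (1.0, 0.0, 0.0): (2.446890, 0.003378),
}


class TestSkyLuminance:
    def test_overcast_azimuthal_symmetry(self, cloudy_sky):
        elev = np.deg2rad(30.0)
        d1 = [np.cos(elev), 0.0, np.sin(elev)]
        d2 = [0.0, -np.cos(elev), np.sin(elev)]
        assert sky_luminance(cloudy_sky, d1) == pytest.approx(
            sky_luminance(cloudy_sky, d2), rel=1e-12
        )

    def test_overcast_gradation_at_zenith(self):
        sky = SkyModel("overcast", zenith_luminance=3.7)
        assert sky_luminance(sky, [0, 0, 1]) == pytest.approx(3.7)
        # horizon falls to one third of the zenith value
        assert sky_luminance(sky, [1, 0, 0]) == pytest.approx(3.7 / 3.0)

    def test_clear_sky_brightest_toward_sun(self, sunny_sky):
        s = sun_direction(sunny_sky)
        anti = np.array([-s[0], -s[1], s[2]])  # same altitude, opposite azimuth
        assert sky_luminance(sunny_sky, s) > sky_luminance(sunny_sky, anti)

    def test_below_horizon_rejected(self, cloudy_sky):
        with pytest.raises(ValueError):
            sky_luminance(cloudy_sky, [0.0, 0.6, -0.8])

    def test_isotropic_constant(self):
        sky = SkyModel("isotropic", zenith_luminance=2.0)
        for d in ([0, 0, 1], [1, 0, 0], [0, 0.6, 0.8]):
            assert sky_luminance(sky, d) == pytest.approx(2.0)


class TestSunDirection:
    def test_zenith_sun(self):
        sky = SkyModel("clear_sun", sun_altitude=90.0)
        assert sun_direction(sky) == pytest.approx([0.0, 0.0, 1.0])

    def test_default_altitude_component(self, sunny_sky):
        assert sun_direction(sunny_sky)[2] == pytest.approx(
            np.sin(np.deg2rad(45.0))
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        az=st.floats(0.0, 359.999),
        alt=st.floats(0.0, 90.0),
    )
    def test_unit_norm(self, az, alt):
        sky = SkyModel("clear_sun", sun_azimuth=az, sun_altitude=alt)
        assert np.linalg.norm(sun_direction(sky)) == pytest.approx(1.0)

    def test_overcast_has_no_sun(self, cloudy_sky):
        with pytest.raises(ValueError):
            sun_direction(cloudy_sky)


class TestIrradiance:
    def test_downward_normal_gets_nothing(self, cloudy_sky, sunny_sky):
        for sky in (cloudy_sky, sunny_sky):
            assert diffuse_irradiance([0, 0, -1], sky) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_overcast_closed_form(self):
        """Upward irradiance under the overcast gradation is 7*pi*Lz/9."""
        sky = SkyModel("overcast", zenith_luminance=2.0)
        expected = 7.0 * np.pi * 2.0 / 9.0
        assert diffuse_irradiance([0, 0, 1], sky) == pytest.approx(
            expected, rel=1e-4
        )

    @pytest.mark.parametrize("normal", list(MC_CLEAR))
    def test_matches_monte_carlo_oracle(self, sunny_sky, normal):
        mean, se = MC_CLEAR[normal]
        assert abs(diffuse_irradiance(list(normal), sunny_sky) - mean) < 3 * se

    def test_overcast_total_equals_diffuse(self, cloudy_sky):
        n = [0.3, 0.4, np.sqrt(1 - 0.25)]
        assert total_irradiance(n, cloudy_sky) == pytest.approx(
            diffuse_irradiance(n, cloudy_sky), rel=1e-14
        )

    def test_sun_term_vanishes_perpendicular(self, sunny_sky):
        s = sun_direction(sunny_sky)
        perp = np.cross(s, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        assert total_irradiance(perp, sunny_sky) == pytest.approx(
            diffuse_irradiance(perp, sunny_sky), rel=1e-12
        )

    def test_directional_sky_has_stronger_gradient(self, cloudy_sky, sunny_sky, rng):
        normals = rng.normal(size=(100, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        ratios = {}
        for sky in (cloudy_sky, sunny_sky):
            e = total_irradiance(normals, sky)
            e = e[e > 1e-9]
            ratios[sky.sky_type] = e.max() / e.min()
        assert ratios["clear_sun"] > ratios["overcast"]

    def test_isotropic_irradiance_is_uniform_pi(self, rng):
        sky = SkyModel("isotropic", zenith_luminance=1.5)
        normals = rng.normal(size=(10, 3))
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        assert total_irradiance(normals, sky) == pytest.approx(
            np.full(10, np.pi * 1.5)
        )


class TestInvariants:
    def test_linearity_in_zenith_luminance(self):
        n = [0.6, 0.0, 0.8]
        for sky_type in ("overcast", "clear_sun"):
            e1 = total_irradiance(n, SkyModel(sky_type, zenith_luminance=1.0))
            e5 = total_irradiance(n, SkyModel(sky_type, zenith_luminance=5.0))
            assert e5 == pytest.approx(5.0 * e1, rel=1e-12)

    @pytest.mark.parametrize(
        ("angle", "rel_tol"),
        [
            # a multiple of the azimuthal node spacing maps the quadrature
            # grid onto itself: exact symmetry
            (45.0, 1e-9),
            # off-grid rotations differ only by the quadrature error
            (73.0, 1e-5),
        ],
    )
    def test_rotational_equivariance_about_vertical(self, angle, rel_tol):
        """Rotating both the surface normal and the sun azimuth by the same
        angle leaves the irradiance unchanged."""
        phi = np.deg2rad(angle)
        rot = np.array(
            [[np.cos(phi), -np.sin(phi), 0], [np.sin(phi), np.cos(phi), 0],
             [0, 0, 1]]
        )
        n = np.array([0.48, -0.6, 0.64])
        n /= np.linalg.norm(n)
        e1 = total_irradiance(n, SkyModel("clear_sun", sun_azimuth=270.0))
        e2 = total_irradiance(
            rot @ n, SkyModel("clear_sun", sun_azimuth=(270.0 + angle) % 360)
        )
        assert e2 == pytest.approx(e1, rel=rel_tol)

    def test_quadrature_convergence(self, sunny_sky):
        n = [0.3, 0.5, np.sqrt(1 - 0.34)]
        e = total_irradiance(n, sunny_sky, 64)
        e2 = total_irradiance(n, sunny_sky, 128)
        assert abs(e2 / e - 1.0) < 1e-3

    def test_config_round_trip(self, sunny_sky):
        assert SkyModel.from_config(sunny_sky.to_config()) == sunny_sky


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sun_altitude": 95.0},
            {"sun_azimuth": 360.0},
            {"zenith_luminance": 0.0},
            {"sun_irradiance_ratio": -1.0},
            {"sky_type": "overcast", "sun_irradiance_ratio": 2.0},
            {"sky_type": "weird"},
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        kwargs.setdefault("sky_type", "clear_sun")
        with pytest.raises(ValueError):
            SkyModel(**kwargs)
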