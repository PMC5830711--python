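"""Parametric sky luminance models and irradiance on Lambertian surface elements.

Two skies from the CIE standard family are provided:

* ``overcast`` — the azimuth-symmetric overcast gradation
  ``L(Z) = Lz * (1 + 2 cos Z) / 3`` (Moon–Spencer), purely diffuse.
* ``clear_sun`` — the CIE clear-sky relative luminance (gradation times
  scattering indicatrix) plus a separate direct-solar delta term, giving the
  strongly directional "sunny" regime.

A degenerate ``isotropic`` sky (constant luminance over the *full* sphere,
so every surface element receives the same irradiance pi * Lz) is included
as the all-round-uniform reference condition under which a body shows no
self-shadowing at all.

Irradiance on an oriented element is the cosine-weighted integral of sky
luminance over the upper hemisphere, evaluated on a product quadrature grid
(Gauss–Legendre in cos(zenith), uniform-trapezoid in azimuth, which is
spectrally accurate for the periodic azimuthal factor). Ground-reflected
light is ignored: the lower hemisphere contributes nothing.

Coordinate convention (used across the whole package): right-handed, z up,
x to the viewer's right, y into the scene (the viewing direction). Azimuth
is measured in the horizontal plane from +x toward +y, so azimuth 90° points
into the scene and the default sun azimuth 270° places the sun behind the
viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SkyModel",
    "sky_luminance",
    "sun_direction",
    "diffuse_irradiance",
    "total_irradiance",
]

# CIE clear-sky (standard general sky, clear/low-turbidity) coefficients:
# gradation phi(Z) = 1 + a*exp(b/cos Z), indicatrix
# f(chi) = 1 + c*(exp(d*chi) - exp(d*pi/2)) + e*cos^2(chi).
_CLEAR_A = -1.0
_CLEAR_B = -0.32
_CLEAR_C = 10.0
_CLEAR_D = -3.0
_CLEAR_E = 0.45

DEFAULT_QUADRATURE_RESOLUTION = 64  # zenith nodes; azimuth uses 2x this


@dataclass(frozen=True)
class SkyModel:
    """Parametric sky: type, sun position and relative radiometric scale.

    Parameters
    ----------
    sky_type : {"overcast", "clear_sun"}
    sun_azimuth : float
        Degrees in the horizontal plane (270 = behind the viewer).
    sun_altitude : float
        Degrees above the horizon, in [0, 90].
    zenith_luminance : float
        Relative luminance at the zenith (> 0); the overall scale.
    sun_irradiance_ratio : float
        Direct-solar irradiance on a sun-facing plane as a multiple of the
        diffuse horizontal irradiance. Must be 0 for an overcast sky.
    """

    sky_type: str = "overcast"
    sun_azimuth: float = 270.0
    sun_altitude: float = 45.0
    zenith_luminance: float = 1.0
    sun_irradiance_ratio: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sky_type not in ("overcast", "clear_sun", "isotropic"):
            raise ValueError(f"unknown sky_type {self.sky_type!r}")
        if self.sun_irradiance_ratio is None:
            ratio = 5.0 if self.sky_type == "clear_sun" else 0.0
            object.__setattr__(self, "sun_irradiance_ratio", ratio)
        if not 0.0 <= self.sun_altitude <= 90.0:
            raise ValueError("sun_altitude must lie in [0, 90] degrees")
        if not 0.0 <= self.sun_azimuth < 360.0:
            raise ValueError("sun_azimuth must lie in [0, 360) degrees")
        if self.zenith_luminance <= 0.0:
            raise ValueError("zenith_luminance must be positive")
        if self.sun_irradiance_ratio < 0.0:
            raise ValueError("sun_irradiance_ratio must be >= 0")
        if self.sky_type != "clear_sun" and self.sun_irradiance_ratio != 0.0:
            raise ValueError(
                f"{self.sky_type} sky has no direct-solar component"
            )

    # -- serialization ---------------------------------------------------
    def to_config(self) -> dict:
        return {
            "type": self.sky_type,
            "sun_azimuth_deg": float(self.sun_azimuth),
            "sun_altitude_deg": float(self.sun_altitude),
            "zenith_luminance": float(self.zenith_luminance),
            "sun_irradiance_ratio": float(self.sun_irradiance_ratio),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "SkyModel":
        return cls(
            sky_type=cfg["type"],
            sun_azimuth=float(cfg.get("sun_azimuth_deg", 270.0)),
            sun_altitude=float(cfg.get("sun_altitude_deg", 45.0)),
            zenith_luminance=float(cfg.get("zenith_luminance", 1.0)),
            sun_irradiance_ratio=(
                float(cfg["sun_irradiance_ratio"])
                if "sun_irradiance_ratio" in cfg
                else None
            ),
        )


def sun_direction(sky: SkyModel) -> np.ndarray:
    """Unit vector toward the sun. Only defined for a clear sky."""
    if sky.sky_type != "clear_sun":
        raise ValueError("overcast sky has no point sun")
    az = np.deg2rad(sky.sun_azimuth)
    alt = np.deg2rad(sky.sun_altitude)
    return np.array(
        [np.cos(alt) * np.cos(az), np.cos(alt) * np.sin(az), np.sin(alt)]
    )


def _relative_luminance(sky: SkyModel, directions: np.ndarray) -> np.ndarray:
    """Sky luminance for unit direction(s) with nonnegative z; vectorized."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    cos_z = np.clip(d[:, 2], 0.0, 1.0)
    if sky.sky_type == "isotropic":
        lum = np.full(len(d), sky.zenith_luminance)
    elif sky.sky_type == "overcast":
        lum = sky.zenith_luminance * (1.0 + 2.0 * cos_z) / 3.0
    else:
        s = sun_direction(sky)
        cos_chi = np.clip(d @ s, -1.0, 1.0)
        chi = np.arccos(cos_chi)
        # gradation: avoid overflow at the horizon where cos Z -> 0
        with np.errstate(over="ignore"):
            grad = 1.0 + _CLEAR_A * np.exp(_CLEAR_B / np.maximum(cos_z, 1e-9))
        indic = (
            1.0
            + _CLEAR_C * (np.exp(_CLEAR_D * chi) - np.exp(_CLEAR_D * np.pi / 2.0))
            + _CLEAR_E * cos_chi**2
        )
        z_sun = np.deg2rad(90.0 - sky.sun_altitude)
        grad_zenith = 1.0 + _CLEAR_A * np.exp(_CLEAR_B)
        indic_sun = (
            1.0
            + _CLEAR_C * (np.exp(_CLEAR_D * z_sun) - np.exp(_CLEAR_D * np.pi / 2.0))
            + _CLEAR_E * np.cos(z_sun) ** 2
        )
        lum = sky.zenith_luminance * grad * indic / (grad_zenith * indic_sun)
    lum = np.maximum(lum, 0.0)
    return lum if np.asarray(directions).ndim > 1 else float(lum[0])


def sky_luminance(sky: SkyModel, direction) -> float:
    """Luminance of the sky dome in a given upper-hemisphere unit direction.

    Raises ``ValueError`` for directions below the horizon.
    """
    d = np.asarray(direction, dtype=float)
    if d.ndim == 1:
        if d[2] < -1e-12:
            raise ValueError("direction points below the horizon")
        return float(_relative_luminance(sky, d))
    if np.any(d[:, 2] < -1e-12):
        raise ValueError("direction points below the horizon")
    return _relative_luminance(sky, d)


@lru_cache(maxsize=32)
def _hemisphere_grid(n_theta: int, n_phi: int):
    """Quadrature nodes/weights over the upper hemisphere in dw = du dphi.

    Gauss–Legendre in u = cos(zenith) on (0, 1]; uniform midpoint rule in
    azimuth (exact trapezoid for periodic integrands).
    """
    u, wu = np.polynomial.legendre.leggauss(n_theta)
    u = 0.5 * (u + 1.0)  # map [-1,1] -> [0,1]
    wu = 0.5 * wu
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    wphi = 2.0 * np.pi / n_phi
    uu, pp = np.meshgrid(u, phi, indexing="ij")
    sin_t = np.sqrt(1.0 - uu**2)
    dirs = np.stack(
        [sin_t * np.cos(pp), sin_t * np.sin(pp), uu], axis=-1
    ).reshape(-1, 3)
    w = (wu[:, None] * np.full(n_phi, wphi)[None, :]).reshape(-1)
    return dirs, w


def _diffuse_field(normals: np.ndarray, sky: SkyModel, n_theta: int) -> np.ndarray:
    if sky.sky_type == "isotropic":
        # constant luminance over the full sphere: E = pi * L, any normal
        n = len(np.atleast_2d(normals))
        return np.full(n, np.pi * sky.zenith_luminance)
    dirs, w = _hemisphere_grid(n_theta, 2 * n_theta)
    lum = _relative_luminance(sky, dirs)
    cosines = np.maximum(dirs @ np.atleast_2d(normals).T, 0.0)
    return (w * lum) @ cosines


def diffuse_irradiance(
    normal,
    sky: SkyModel,
    quadrature_resolution: int = DEFAULT_QUADRATURE_RESOLUTION,
) -> float:
    """Sky (diffuse) irradiance on a Lambertian element with the given normal.

    E = ∫_{ω·n>0, ω above horizon} L(ω) (ω·n) dω, in the sky's relative
    units. Deterministic for fixed resolution.
    """
    n = np.asarray(normal, dtype=float)
    if n.ndim == 1:
        return float(_diffuse_field(n, sky, quadrature_resolution)[0])
    return _diffuse_field(n, sky, quadrature_resolution)


def _sun_strength(sky: SkyModel, n_theta: int) -> float:
    """Direct-solar irradiance on a sun-facing plane, from the ratio."""
    if sky.sky_type != "clear_sun" or sky.sun_irradiance_ratio == 0.0:
        return 0.0
    e_dh = float(_diffuse_field(np.array([0.0, 0.0, 1.0]), sky, n_theta)[0])
    return sky.sun_irradiance_ratio * e_dh


def total_irradiance(
    normal,
    sky: SkyModel,
    quadrature_resolution: int = DEFAULT_QUADRATURE_RESOLUTION,
) -> float:
    """Diffuse plus direct-solar irradiance; equals the diffuse term for
    an overcast sky."""
    n = np.asarray(normal, dtype=float)
    e = _diffuse_field(n, sky, quadrature_resolution)
    if sky.sky_type == "clear_sun" and sky.sun_irradiance_ratio > 0.0:
        s = sun_direction(sky)
        strength = _sun_strength(sky, quadrature_resolution)
        e = e + strength * np.maximum(np.atleast_2d(n) @ s, 0.0)
    return float(e[0]) if n.ndim == 1 else e
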