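"""Irradiance fields, optimal countershading patterns and shading metrics.

For a convex Lambertian body under a given sky, each face receives
irradiance E from its local upper hemisphere. The outgoing radiance of a
face with reflectance rho is rho * E / pi. The *optimal* countershading
pattern for that sky inverts the irradiance field, rho_i = k / E_i with
k = min_i E_i, so that rho <= 1 everywhere and rho * E — hence the apparent
radiance — is constant: the body shows no shading at all under the lighting
it was optimized for. Under any other lighting the cancellation fails, and
the residual gradient (including the inverted, concave-looking gradient of
a sun-optimized pattern under a diffuse sky) is what the shading metrics
quantify.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .body_geometry import Mesh
from .sky_irradiance import (
    DEFAULT_QUADRATURE_RESOLUTION,
    SkyModel,
    total_irradiance,
)

__all__ = [
    "PatternLabel",
    "IrradianceField",
    "ReflectancePattern",
    "RadianceField",
    "compute_irradiance_field",
    "optimal_pattern",
    "uniform_pattern",
    "apparent_radiance",
    "shading_metrics",
]


class PatternLabel(str, Enum):
    NO_CS = "no_CS"
    CLOUDY_CS = "cloudy_CS"
    SUNNY_CS = "sunny_CS"


@dataclass
class IrradianceField:
    """Per-face irradiance on a mesh under one sky (relative units)."""

    values: np.ndarray
    mesh: Mesh
    sky: SkyModel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_faces:
            raise ValueError("irradiance length != face count")
        if np.any(self.values < 0):
            raise ValueError("negative irradiance")


@dataclass
class ReflectancePattern:
    """Per-face reflectance in (0, 1]."""

    values: np.ndarray
    label: PatternLabel | str
    mesh: Mesh

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_faces:
            raise ValueError("reflectance length != face count")
        if np.any(self.values <= 0) or np.any(self.values > 1.0 + 1e-12):
            raise ValueError("reflectance must lie in (0, 1]")
        self.label = PatternLabel(self.label)

    def export_ply(self, path: str) -> None:
        """Write the mesh with the reflectance as a per-face grey level
        (PLY with face colors) for external inspection."""
        tm = self.mesh.to_trimesh()
        grey = np.clip(self.values / self.values.max() * 255, 0, 255)
        tm.visual.face_colors = np.column_stack(
            [grey, grey, grey, np.full(len(grey), 255)]
        ).astype(np.uint8)
        tm.export(path)

    def to_texture_map(self, height: int = 128):
        """Equirectangular reflectance map: rows span normal elevation
        (top row = straight up), columns span azimuth. Nearest-face
        sampling of the per-face values."""
        width = 2 * height
        elev = np.linspace(np.pi / 2, -np.pi / 2, height)
        azim = np.linspace(-np.pi, np.pi, width, endpoint=False)
        ee, aa = np.meshgrid(elev, azim, indexing="ij")
        dirs = np.stack(
            [np.cos(ee) * np.cos(aa), np.cos(ee) * np.sin(aa), np.sin(ee)],
            axis=-1,
        ).reshape(-1, 3)
        nearest = np.argmax(dirs @ self.mesh.face_normals.T, axis=1)
        return self.values[nearest].reshape(height, width)

    def export_texture_png(self, path: str, height: int = 128) -> None:
        from PIL import Image

        tex = self.to_texture_map(height)
        arr = (np.clip(tex / tex.max(), 0, 1) * 255).round().astype(np.uint8)
        Image.fromarray(arr).save(path)

    def top_bottom_ratio(self, cap_angle_deg: float = 30.0) -> float:
        """Depth of the dorsoventral gradient: area-weighted mean
        reflectance of the belly strip over the back strip (>1 =
        countershaded, darker back and lighter belly).

        The strips are the faces whose normals lie within ``cap_angle_deg``
        of straight down / straight up. Polar caps rather than whole
        hemispheres are compared because under directional light the
        optimal pattern also has an azimuthal (sun-facing vs sun-averted)
        gradient that would otherwise dilute the dorsoventral one.
        """
        cos_cap = np.cos(np.deg2rad(cap_angle_deg))
        nz = self.mesh.face_normals[:, 2]
        w = self.mesh.face_areas
        up, down = nz > cos_cap, nz < -cos_cap
        if not up.any() or not down.any():
            raise ValueError("no faces inside the polar caps")
        mean_up = np.average(self.values[up], weights=w[up])
        mean_down = np.average(self.values[down], weights=w[down])
        return float(mean_down / mean_up)


@dataclass
class RadianceField:
    """Per-face outgoing radiance rho * E / pi."""

    values: np.ndarray
    mesh: Mesh

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_faces:
            raise ValueError("radiance length != face count")
        if np.any(self.values < 0):
            raise ValueError("negative radiance")


def compute_irradiance_field(
    mesh: Mesh,
    sky: SkyModel,
    quadrature_resolution: int = DEFAULT_QUADRATURE_RESOLUTION,
) -> IrradianceField:
    """Per-face irradiance, treating the body as convex (each face sees its
    full local hemisphere; no self-occlusion)."""
    e = total_irradiance(mesh.face_normals, sky, quadrature_resolution)
    return IrradianceField(np.asarray(e), mesh, sky)


def optimal_pattern(
    field: IrradianceField,
    label: PatternLabel | str = PatternLabel.CLOUDY_CS,
    mean_reflectance: float | None = None,
) -> ReflectancePattern:
    """Shading-cancelling reflectance rho_i = k / E_i.

    By default k = min(E), so the brightest admissible pattern (max
    rho = 1) results. ``mean_reflectance`` instead chooses k so the
    area-weighted mean reflectance matches a prescribed level (useful for
    background-matching designs); it raises if that would push any face
    above 1. Requires strictly positive irradiance on every face; a face
    with E = 0 would need unbounded reflectance and raises instead.
    """
    e = field.values
    if np.any(e <= 0):
        raise ValueError(
            "optimal pattern undefined: some faces receive zero irradiance"
        )
    rho = e.min() / e
    if mean_reflectance is not None:
        current = np.average(rho, weights=field.mesh.face_areas)
        rho = rho * (mean_reflectance / current)
        if np.any(rho > 1.0 + 1e-12):
            raise ValueError(
                "requested mean reflectance is not physically realizable "
                "(some faces would exceed 1)"
            )
    return ReflectancePattern(rho, label, field.mesh)


def uniform_pattern(
    mesh: Mesh, level: float, label: PatternLabel | str = PatternLabel.NO_CS
) -> ReflectancePattern:
    """Uniform (non-countershaded) reflectance at the given level."""
    return ReflectancePattern(np.full(mesh.n_faces, float(level)), label, mesh)


def matched_uniform_level(patterns) -> float:
    """Mean of the optimal patterns' area-weighted mean reflectances, the
    default level for the uniform target so all three targets have
    comparable overall reflectance."""
    means = [
        np.average(p.values, weights=p.mesh.face_areas) for p in patterns
    ]
    return float(np.mean(means))


def apparent_radiance(
    pattern: ReflectancePattern, field: IrradianceField
) -> RadianceField:
    """Outgoing radiance rho * E / pi of a pattern under a (possibly
    mismatched) lighting field on the same mesh."""
    if pattern.mesh is not field.mesh and not (
        pattern.mesh.n_faces == field.mesh.n_faces
        and np.array_equal(pattern.mesh.faces, field.mesh.faces)
        and np.allclose(pattern.mesh.vertices, field.mesh.vertices)
    ):
        raise ValueError("pattern and irradiance field use different meshes")
    return RadianceField(pattern.values * field.values / np.pi, field.mesh)


def shading_metrics(radiance: RadianceField, mesh: Mesh | None = None) -> dict:
    """Residual-shading diagnostics of a radiance field.

    Returns ``cv``, the area-weighted coefficient of variation of radiance
    (0 = perfectly flat appearance), and ``vertical_gradient``, the
    area-weighted Pearson correlation between radiance and the vertical
    component of the face normal (positive = lit-from-above convex
    appearance, negative = inverted, concave-looking shading).
    """
    mesh = mesh or radiance.mesh
    w = mesh.face_areas
    if w.sum() <= 0:
        raise ValueError("zero-area mesh")
    r = radiance.values
    if len(r) == 0:
        raise ValueError("empty radiance field")
    w = w / w.sum()
    mean = float(np.sum(w * r))
    var = float(np.sum(w * (r - mean) ** 2))
    cv = np.sqrt(var) / mean if mean > 0 else 0.0
    nz = mesh.face_normals[:, 2]
    nz_mean = float(np.sum(w * nz))
    cov = float(np.sum(w * (r - mean) * (nz - nz_mean)))
    nz_var = float(np.sum(w * (nz - nz_mean) ** 2))
    if var <= 1e-24 * mean**2 or nz_var <= 0:
        grad = 0.0
    else:
        grad = cov / np.sqrt(var * nz_var)
    return {"cv": float(cv), "vertical_gradient": float(grad)}
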