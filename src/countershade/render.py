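"""Software rendering of search scenes and display rescaling.

A pinhole camera at the origin looks along +y (into the scene) with +z up
and +x to the viewer's right. Items sit in the fronto-parallel plane at the
item-plane distance, the uniform backdrop behind them. Each triangle is
flat-shaded with its face's Lambertian radiance (reflectance x irradiance /
pi) under the scene's sky; visibility is resolved with a z-buffer. Cast
shadows are off by default: with the sun high and behind the viewer they
fall on the backdrop outside the field of view, and item-on-item shadows
are rare and condition-independent.

``rescale_for_display`` reproduces the high-dynamic-range to screen
mapping: divide by the 99th-percentile pixel value and clip the brightest
remaining pixels to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .body_geometry import Mesh, SceneSpec
from .countershading import ReflectancePattern
from .sky_irradiance import SkyModel, total_irradiance

__all__ = ["CameraSpec", "RenderedImage", "render_scene", "rescale_for_display"]

BACKGROUND = -1


@dataclass(frozen=True)
class CameraSpec:
    """Pinhole camera; eye at the origin, looking along +y."""

    field_of_view: float = 43.6  # degrees, frames the placement square at 2 m
    image_size: int = 512
    display_field_of_view: float = 10.58  # degrees the image spans on screen

    def __post_init__(self) -> None:
        if not 0.0 < self.field_of_view < 90.0:
            raise ValueError("field_of_view must lie in (0, 90) degrees")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")

    @classmethod
    def for_layout(cls, layout, image_size: int = 512) -> "CameraSpec":
        """Camera whose frustum exactly frames the layout's placement
        square at the item-plane distance."""
        half = layout.field_side_mm / 2.0
        dist = layout.item_plane_distance * 1000.0
        fov = 2.0 * np.degrees(np.arctan(half / dist))
        return cls(field_of_view=fov, image_size=image_size)


@dataclass
class RenderedImage:
    """Pixel luminance (relative units) plus per-pixel item-id mask."""

    luminance: np.ndarray  # (H, W) float
    mask: np.ndarray  # (H, W) int, BACKGROUND where no item

    def __post_init__(self) -> None:
        if self.luminance.shape != self.mask.shape:
            raise ValueError("luminance/mask shape mismatch")
        if np.any(self.luminance < 0):
            raise ValueError("negative luminance")

    def item_pixels(self, item_index: int) -> np.ndarray:
        return self.luminance[self.mask == item_index]

    def item_angular_width(self, item_index: int) -> float:
        """Horizontal extent of an item's mask in displayed degrees."""
        cols = np.where((self.mask == item_index).any(axis=0))[0]
        if len(cols) == 0:
            raise ValueError(f"item {item_index} not visible")
        frac = (cols.max() - cols.min() + 1) / self.mask.shape[1]
        return float(frac * self._display_fov)

    _display_fov: float = 10.58

    def mask_to_png(self, path: str) -> None:
        """Item-id mask as an 8-bit PNG (0 = background, id + 1 else)."""
        from PIL import Image

        Image.fromarray((self.mask + 1).astype(np.uint8)).save(path)

    def to_png(self, path: str, bit_depth: int = 8) -> None:
        from PIL import Image

        arr = np.clip(self.luminance, 0.0, 1.0)
        if bit_depth == 8:
            img = Image.fromarray((arr * 255).round().astype(np.uint8))
        elif bit_depth == 16:
            img = Image.fromarray((arr * 65535).round().astype(np.uint16))
        else:
            raise ValueError("bit_depth must be 8 or 16")
        img.save(path)


@numba.njit(cache=True)
def _raster_triangles(tri_px, tri_depth, tri_value, tri_item, size,
                      luminance, mask, depth):  # pragma: no cover - jitted
    """Z-buffered flat rasterization of projected triangles (in place)."""
    for t in range(tri_px.shape[0]):
        x0, y0 = tri_px[t, 0, 0], tri_px[t, 0, 1]
        x1, y1 = tri_px[t, 1, 0], tri_px[t, 1, 1]
        x2, y2 = tri_px[t, 2, 0], tri_px[t, 2, 1]
        xmin = max(int(np.floor(min(x0, x1, x2))), 0)
        xmax = min(int(np.ceil(max(x0, x1, x2))) + 1, size)
        ymin = max(int(np.floor(min(y0, y1, y2))), 0)
        ymax = min(int(np.ceil(max(y0, y1, y2))) + 1, size)
        if xmin >= xmax or ymin >= ymax:
            continue
        denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(denom) < 1e-12:
            continue
        d0, d1, d2 = tri_depth[t, 0], tri_depth[t, 1], tri_depth[t, 2]
        for py in range(ymin, ymax):
            gy = py + 0.5
            for px in range(xmin, xmax):
                gx = px + 0.5
                l0 = ((y1 - y2) * (gx - x2) + (x2 - x1) * (gy - y2)) / denom
                if l0 < 0.0:
                    continue
                l1 = ((y2 - y0) * (gx - x2) + (x0 - x2) * (gy - y2)) / denom
                if l1 < 0.0:
                    continue
                l2 = 1.0 - l0 - l1
                if l2 < 0.0:
                    continue
                d = l0 * d0 + l1 * d1 + l2 * d2
                if d < depth[py, px]:
                    depth[py, px] = d
                    luminance[py, px] = tri_value[t]
                    mask[py, px] = tri_item[t]


def render_scene(
    scene: SceneSpec,
    sky: SkyModel,
    patterns: list[ReflectancePattern],
    camera: CameraSpec | None = None,
    backdrop_reflectance: float | None = None,
    quadrature_resolution: int = 32,
) -> RenderedImage:
    """Render one scene under one sky.

    ``patterns[i]`` carries item *i*'s body-frame mesh and per-face
    reflectance; the item is posed with ``scene.item_orientations[i]`` and
    placed at its layout position before per-face irradiance is evaluated
    on the world-frame normals. If ``backdrop_reflectance`` is None the
    backdrop's radiance is set to the mean item radiance, emulating the
    brightness-matched background.
    """
    if len(patterns) == 0 or scene.n_items == 0:
        raise ValueError("empty scene")
    if len(patterns) != scene.n_items:
        raise ValueError("one reflectance pattern required per scene item")
    camera = camera or CameraSpec.for_layout(scene.layout)
    size = camera.image_size
    tan_half = np.tan(np.deg2rad(camera.field_of_view / 2.0))
    plane_y = scene.layout.item_plane_distance * 1000.0
    backdrop_y = scene.layout.backdrop_distance * 1000.0

    all_px, all_depth, all_val, all_item = [], [], [], []
    item_means = []
    for i, (pattern, orient) in enumerate(
        zip(patterns, scene.item_orientations)
    ):
        x, z = scene.item_positions[i]
        world = pattern.mesh.transformed(
            rotation=orient.rotation(), translation=(x, plane_y, z)
        )
        # surfaces are two-sided Lambertian sheets: the side seen from the
        # eye (origin) is shaded with its own outward normal. Back faces of
        # a closed convex body always lose the depth test, so no explicit
        # culling is needed.
        away = (
            np.einsum("ij,ij->i", world.face_normals, world.face_centroids)
            > 0
        )
        normals = np.where(away[:, None], -world.face_normals,
                           world.face_normals)
        e = total_irradiance(normals, sky, quadrature_resolution)
        radiance = pattern.values * np.asarray(e) / np.pi
        item_means.append(
            float(np.average(radiance, weights=world.face_areas))
        )
        tri = world.vertices[world.faces]  # (m, 3, 3)
        y = tri[:, :, 1]
        if np.any(y <= 1.0):
            raise ValueError("geometry behind the camera")
        u = tri[:, :, 0] / y / tan_half  # [-1, 1] across the frustum
        v = tri[:, :, 2] / y / tan_half
        px = np.empty_like(tri[:, :, :2])
        px[:, :, 0] = (u + 1.0) / 2.0 * size
        px[:, :, 1] = (1.0 - v) / 2.0 * size
        all_px.append(px)
        all_depth.append(y)
        all_val.append(radiance)
        all_item.append(np.full(len(tri), i, dtype=int))

    if backdrop_reflectance is None:
        backdrop_value = float(np.mean(item_means))
    else:
        e_back = total_irradiance(
            np.array([0.0, -1.0, 0.0]), sky, quadrature_resolution
        )
        backdrop_value = backdrop_reflectance * float(e_back) / np.pi

    luminance = np.full((size, size), backdrop_value)
    mask = np.full((size, size), BACKGROUND, dtype=int)
    depth = np.full((size, size), backdrop_y)
    _raster_triangles(
        np.concatenate(all_px),
        np.concatenate(all_depth),
        np.concatenate(all_val),
        np.concatenate(all_item),
        size,
        luminance,
        mask,
        depth,
    )
    img = RenderedImage(luminance, mask)
    img._display_fov = camera.display_field_of_view
    return img


def rescale_for_display(image: RenderedImage) -> RenderedImage:
    """Map to the display range: divide by the 99th-percentile luminance
    and clip the brighter remainder to 1 (at most ~1% of pixels clip)."""
    lum = image.luminance
    if lum.size == 0 or not np.any(lum > 0):
        raise ValueError("cannot rescale an all-zero image")
    q99 = float(np.percentile(lum, 99.0))
    out = RenderedImage(np.minimum(lum / q99, 1.0), image.mask.copy())
    out._display_fov = image._display_fov
    return out
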