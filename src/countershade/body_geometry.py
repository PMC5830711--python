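"""Target ellipsoid, leaf distractors and scene layout.

The search target is a prolate ellipsoid ("caterpillar") whose long axis is
horizontal at the reference orientation. Distractors are virtual "leaves":
flat ellipses with the same 2D outline as the target, folded inward by a
dihedral half-angle about their long axis and curved along it by a random
cosine bump, so that they present a wide range of surface normals while
keeping an elliptical profile.

Body-local frame: long axis along local x, width along local y, local z up.
Orientation angles: yaw about the vertical z, pitch about the transverse
horizontal y, roll about the long axis x (intrinsic, applied yaw-pitch-roll).
Scene item centres live in the fronto-parallel plane at the item-plane
distance; positions are (horizontal, vertical) in model millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Orientation",
    "EllipsoidSpec",
    "LeafSpec",
    "Mesh",
    "LayoutParams",
    "SceneSpec",
    "make_ellipsoid",
    "make_leaf",
    "draw_curvature_amplitude",
    "sample_distractor_orientation",
    "layout_scene",
    "LayoutInfeasibleError",
]

# Long:short axis ratio of the target (and hence of the leaf outline),
# from the on-screen 1.27deg x 0.4deg item proportions.
ASPECT_RATIO = 1.27 / 0.4


@dataclass(frozen=True)
class Orientation:
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0

    def rotation(self) -> Rotation:
        """Intrinsic yaw (z), then pitch (y), then roll (x)."""
        return Rotation.from_euler(
            "zyx", [self.yaw, self.pitch, self.roll], degrees=True
        )


REFERENCE_ORIENTATION = Orientation(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class EllipsoidSpec:
    semi_major: float = 60.0  # mm, half the 120 mm body length
    semi_minor: float = 60.0 / ASPECT_RATIO
    mesh_resolution: int = 32  # latitudinal bands

    def __post_init__(self) -> None:
        if not self.semi_major >= self.semi_minor > 0:
            raise ValueError("require semi_major >= semi_minor > 0")


@dataclass(frozen=True)
class LeafSpec:
    length_l: float = 120.0  # mm, major axis
    fold_angle: float = 15.0  # degrees each half rotates inward
    curvature_amplitude_c: float | None = None  # mm; None -> draw from rng
    rng_seed: int | None = None
    mesh_resolution: int = 24  # radial rings in the sheet triangulation

    def __post_init__(self) -> None:
        if self.length_l <= 0:
            raise ValueError("length_l must be positive")
        if not 0.0 <= self.fold_angle < 90.0:
            raise ValueError("fold_angle must lie in [0, 90)")


def draw_curvature_amplitude(spec: LeafSpec, rng: np.random.Generator) -> float:
    """Random cosine-bump amplitude c ~ Normal(l/6, (l/6)^2) in mm."""
    scale = spec.length_l / 6.0
    return float(rng.normal(loc=scale, scale=scale))


@dataclass
class Mesh:
    """Triangle mesh with derived per-face quantities (mm units)."""

    vertices: np.ndarray  # (n, 3)
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")
        self._update_derived()

    def _update_derived(self) -> None:
        tri = self.vertices[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(cross, axis=1)
        if np.any(norms <= 0):
            raise ValueError("degenerate (zero-area) face")
        self.face_normals = cross / norms[:, None]
        self.face_areas = 0.5 * norms
        self.face_centroids = tri.mean(axis=1)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def transformed(self, rotation: Rotation | None = None,
                    translation=None) -> "Mesh":
        v = self.vertices
        if rotation is not None:
            v = rotation.apply(v)
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return Mesh(v, self.faces.copy())

    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export(self, path: str) -> None:
        """Write OBJ/PLY (chosen by extension) for external inspection."""
        self.to_trimesh().export(path)


def make_ellipsoid(spec: EllipsoidSpec,
                   orientation: Orientation = REFERENCE_ORIENTATION) -> Mesh:
    """Watertight UV triangulation of the target ellipsoid, outward normals.

    Semi-axes are (semi_major, semi_minor, semi_minor) along the body-local
    (x, y, z): the long axis is horizontal at the reference orientation.
    """
    res = spec.mesh_resolution
    if res < 3:
        raise ValueError("mesh_resolution must be >= 3")
    n_lat, n_lon = res, 2 * res
    # poles along the long (local x) axis
    theta = np.linspace(0.0, np.pi, n_lat + 1)[1:-1]
    phi = np.arange(n_lon) * (2.0 * np.pi / n_lon)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    a, b = spec.semi_major, spec.semi_minor
    ring = np.stack(
        [a * np.cos(tt), b * np.sin(tt) * np.cos(pp), b * np.sin(tt) * np.sin(pp)],
        axis=-1,
    ).reshape(-1, 3)
    verts = np.vstack([[[a, 0.0, 0.0]], ring, [[-a, 0.0, 0.0]]])
    top, bottom = 0, len(verts) - 1

    faces = []
    def ring_idx(i, j):
        return 1 + i * n_lon + (j % n_lon)

    for j in range(n_lon):  # pole fans
        faces.append([top, ring_idx(0, j), ring_idx(0, j + 1)])
        faces.append([bottom, ring_idx(n_lat - 2, j + 1), ring_idx(n_lat - 2, j)])
    for i in range(n_lat - 2):  # quad strips
        for j in range(n_lon):
            p00, p01 = ring_idx(i, j), ring_idx(i, j + 1)
            p10, p11 = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([p00, p10, p11])
            faces.append([p00, p11, p01])
    mesh = Mesh(verts, np.array(faces))
    # orient all normals outward from the centre
    flip = np.einsum("ij,ij->i", mesh.face_normals, mesh.face_centroids) < 0
    mesh.faces[flip] = mesh.faces[flip][:, ::-1]
    mesh._update_derived()
    return mesh.transformed(orientation.rotation())


def make_leaf(spec: LeafSpec, rng: np.random.Generator | None = None) -> Mesh:
    """Leaf distractor: elliptical sheet, folded then curved.

    The flat ellipse has the target's outline (major axis ``length_l`` along
    local x, minor axis ``length_l / ASPECT_RATIO``). Each half (local y > 0
    and y < 0) is rotated inward (upward) about the long axis by
    ``fold_angle``; the sheet is then displaced vertically by
    ``c * cos(x / l)`` along the major axis, with x in mm and the cosine
    argument in radians.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    c = spec.curvature_amplitude_c
    if c is None:
        c = draw_curvature_amplitude(spec, rng)

    a = spec.length_l / 2.0
    b = a / ASPECT_RATIO
    n_r, n_t = spec.mesh_resolution, 4 * spec.mesh_resolution
    # polar parameterization of the unit disk mapped to the ellipse
    r = np.linspace(0.0, 1.0, n_r + 1)[1:]
    t = np.arange(n_t) * (2.0 * np.pi / n_t)
    rr, tt = np.meshgrid(r, t, indexing="ij")
    x = a * rr * np.cos(tt)
    y = b * rr * np.sin(tt)
    verts = np.stack([x, y, np.zeros_like(x)], axis=-1).reshape(-1, 3)
    verts = np.vstack([[[0.0, 0.0, 0.0]], verts])
    centre = 0

    def idx(i, j):
        return 1 + i * n_t + (j % n_t)

    faces = []
    for j in range(n_t):
        faces.append([centre, idx(0, j), idx(0, j + 1)])
    for i in range(n_r - 1):
        for j in range(n_t):
            p00, p01 = idx(i, j), idx(i, j + 1)
            p10, p11 = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append([p00, p10, p11])
            faces.append([p00, p11, p01])

    # fold: both halves rotate inward/upward about the long (x) axis
    alpha = np.deg2rad(spec.fold_angle)
    yy, zz = verts[:, 1].copy(), verts[:, 2].copy()
    verts[:, 1] = yy * np.cos(alpha)
    verts[:, 2] = zz + np.abs(yy) * np.sin(alpha)
    # curvature along the major axis
    verts[:, 2] += c * np.cos(verts[:, 0] / spec.length_l)
    return Mesh(verts, np.array(faces))


@dataclass(frozen=True)
class LayoutParams:
    """Scene layout parameters (model units: mm; distances in m)."""

    n_distractors: int = 20
    min_separation_factor: float = 1.3
    item_length_mm: float = 120.0
    item_plane_distance: float = 2.0  # m from the observer
    backdrop_distance: float = 4.0  # m
    field_extent: float = 10.58  # displayed visual angle of the square scene
    field_side_mm: float = 1600.0  # model-space placement square
    distractor_roll_sd: float = 50.0  # degrees
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_distractors <= 0:
            raise ValueError("n_distractors must be positive")
        if self.min_separation_factor < 1.0:
            raise ValueError("min_separation_factor must be >= 1")

    @property
    def min_separation_mm(self) -> float:
        return self.min_separation_factor * self.item_length_mm


class LayoutInfeasibleError(RuntimeError):
    """Raised when no admissible layout is found within the retry budget."""


@dataclass
class SceneSpec:
    """Placement of one target and the distractors in the item plane."""

    item_positions: np.ndarray  # (n_items, 2) mm, (horizontal, vertical)
    item_orientations: list[Orientation]
    target_index: int
    layout: LayoutParams

    def __post_init__(self) -> None:
        self.item_positions = np.asarray(self.item_positions, dtype=float)
        n = len(self.item_positions)
        if not 0 <= self.target_index < n:
            raise ValueError("target_index out of range")
        if len(self.item_orientations) != n:
            raise ValueError("orientation list length mismatch")

    @property
    def n_items(self) -> int:
        return len(self.item_positions)

    def pairwise_min_distance(self) -> float:
        from scipy.spatial.distance import pdist

        return float(pdist(self.item_positions).min())

    def to_json(self) -> str:
        payload = {
            "item_positions_mm": self.item_positions.tolist(),
            "item_orientations_deg": [asdict(o) for o in self.item_orientations],
            "target_index": int(self.target_index),
            "layout": asdict(self.layout),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        return cls(
            item_positions=np.array(d["item_positions_mm"], dtype=float),
            item_orientations=[
                Orientation(**o) for o in d["item_orientations_deg"]
            ],
            target_index=d["target_index"],
            layout=LayoutParams(**d["layout"]),
        )


def sample_distractor_orientation(
    params: LayoutParams, rng: np.random.Generator
) -> Orientation:
    """Distractor pose: pitch = yaw = 0; roll ~ Normal(0, roll_sd^2) deg."""
    return Orientation(pitch=0.0, yaw=0.0,
                       roll=float(rng.normal(0.0, params.distractor_roll_sd)))


def layout_scene(
    params: LayoutParams,
    rng: np.random.Generator | None = None,
    max_scene_attempts: int = 10_000,
    max_point_attempts: int = 2_000,
) -> SceneSpec:
    """Rejection-sample item centres uniformly in the placement square,
    keeping every pairwise centre distance >= 1.3 x the distractor length.

    Points are dart-thrown sequentially (each candidate uniform, rejected on
    a separation violation); a scene that cannot be completed restarts, up
    to ``max_scene_attempts``. The target slot is chosen uniformly among the
    placed items and keeps the reference orientation.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n_items = params.n_distractors + 1
    half = params.field_side_mm / 2.0
    min_d2 = params.min_separation_mm**2

    for _ in range(max_scene_attempts):
        pts = np.empty((n_items, 2))
        placed = 0
        attempts = 0
        while placed < n_items and attempts < max_point_attempts:
            cand = rng.uniform(-half, half, size=2)
            attempts += 1
            if placed == 0 or np.min(
                np.sum((pts[:placed] - cand) ** 2, axis=1)
            ) >= min_d2:
                pts[placed] = cand
                placed += 1
        if placed == n_items:
            target_index = int(rng.integers(n_items))
            orients = [
                sample_distractor_orientation(params, rng)
                for _ in range(n_items)
            ]
            orients[target_index] = REFERENCE_ORIENTATION
            return SceneSpec(pts, orients, target_index, params)
    raise LayoutInfeasibleError(
        f"could not place {n_items} items with separation "
        f"{params.min_separation_mm:.0f} mm in a "
        f"{params.field_side_mm:.0f} mm square"
    )
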