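"""Voxelized cell geometries from analytic implicit shape functions.

A cell shape is described by a signed distance function (negative inside).
Two families are supported: the wild-type "pill" (a capsule: cylinder with
hemispherical end caps) and flattened "pancake" bodies, which are the set of
points within ``thickness/2`` of a 2D region lying in the mid-plane -- this
construction gives flat top/bottom faces and an exactly semicircular rim.

Conventions: cell-centered voxels, the long axis along y (axis 1), the axis
normal to the flattened plane along z (axis 2).  The membrane delta-function
coupling of the reaction equations is discretized onto boundary voxels: a
membrane area ``a_i`` (from a triangulation of the implicit surface) is
assigned to each boundary voxel, and a term ``delta(d_w) * X`` becomes
``X * a_i / v_i`` in voxel i, which preserves the total exchange flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
from shapely.geometry import Polygon
from skimage import measure

__all__ = [
    "ShapeSpec",
    "CellGeometry",
    "build_pill",
    "build_flattened",
    "match_stadium",
    "stadium_polygon",
    "stadium_volume",
]

#: boundary voxels whose interior volume fraction is below this fraction of
#: dx^3 are merged into their largest interior neighbor (numerical stability:
#: tiny volumes make the membrane exchange terms stiff).
MIN_VOLUME_FRACTION = 0.10

_SUBSAMPLE = 4  # per-axis sub-sampling for boundary-voxel volume fractions


@dataclass(frozen=True)
class ShapeSpec:
    """Analytic description of a cell shape.

    ``kind`` is "pill" (parameters: length, radius) or "flattened"
    (parameters: outline polygon + thickness).  ``dx`` is the grid spacing.
    """

    kind: str
    dx: float
    length: float | None = None
    radius: float | None = None
    outline: Polygon | None = None
    thickness: float | None = None

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("grid spacing dx must be positive")
        if self.kind == "pill":
            if self.length is None or self.radius is None:
                raise ValueError("pill requires length and radius")
            if self.length < 2 * self.radius:
                raise ValueError(
                    "degenerate pill: end-to-end length "
                    f"{self.length} is less than the diameter {2 * self.radius} "
                    "(length >= 2*radius is required)"
                )
        elif self.kind == "flattened":
            if self.outline is None or self.thickness is None:
                raise ValueError("flattened shape requires outline and thickness")
            if self.thickness <= 0:
                raise ValueError("thickness must be positive")
        else:
            raise ValueError(f"unknown shape kind {self.kind!r}")

    def build(self) -> "CellGeometry":
        if self.kind == "pill":
            return build_pill(self.length, self.radius, self.dx)
        return build_flattened(self.outline, self.thickness, self.dx)


@dataclass
class CellGeometry:
    """Voxelized cell: interior mask, per-voxel volumes, membrane areas.

    Arrays are defined on a bounding grid of shape ``mask.shape``; ``origin``
    is the coordinate of the center of voxel (0,0,0).  ``volume`` holds the
    interior volume of each voxel (um^3; zero outside), ``area`` the membrane
    area assigned to each boundary voxel (um^2), ``wall_distance`` the
    distance to the nearest wall (um; zero outside the cell).
    """

    dx: float
    origin: np.ndarray
    mask: np.ndarray
    volume: np.ndarray
    area: np.ndarray
    wall_distance: np.ndarray
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    spec: ShapeSpec | None = None

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())

    @property
    def total_area(self) -> float:
        return float(self.area.sum())

    @property
    def boundary_mask(self) -> np.ndarray:
        return self.area > 0

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) coordinates of interior voxel centers, C-order of mask."""
        idx = np.argwhere(self.mask)
        return self.origin + idx * self.dx

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["dx"] = self.dx
            f.attrs["long_axis"] = self.long_axis
            f.create_dataset("origin", data=self.origin)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset("volume", data=self.volume)
            f.create_dataset("area", data=self.area)
            f.create_dataset("wall_distance", data=self.wall_distance)

    @classmethod
    def load(cls, path) -> "CellGeometry":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                dx=float(f.attrs["dx"]),
                origin=f["origin"][...],
                mask=f["mask"][...].astype(bool),
                volume=f["volume"][...],
                area=f["area"][...],
                wall_distance=f["wall_distance"][...],
                long_axis=np.asarray(f.attrs["long_axis"]),
            )


# ---------------------------------------------------------------------------
# signed distance functions
# ---------------------------------------------------------------------------


def _capsule_sdf(length: float, radius: float) -> Callable[[np.ndarray], np.ndarray]:
    half = length / 2 - radius  # half-length of the cylindrical segment

    def sdf(pts: np.ndarray) -> np.ndarray:
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        yc = np.clip(y, -half, half)
        return np.sqrt(x * x + (y - yc) ** 2 + z * z) - radius

    return sdf


def _pancake_sdf(outline: Polygon, thickness: float) -> Callable[[np.ndarray], np.ndarray]:
    r = thickness / 2
    eroded = outline.buffer(-r)
    if eroded.is_empty:
        raise ValueError(
            f"outline interior width is smaller than the thickness {thickness}"
        )

    def sdf(pts: np.ndarray) -> np.ndarray:
        p2 = shapely.points(pts[:, 0], pts[:, 1])
        d2 = shapely.distance(p2, eroded)  # 0 inside the eroded region
        return np.hypot(d2, pts[:, 2]) - r

    return sdf


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def _symmetric_axis(lo: float, hi: float, dx: float) -> np.ndarray:
    """Voxel-center coordinates covering [lo, hi] symmetrically about their
    midpoint, so that mirror-symmetric shapes produce mirror-symmetric masks."""
    center = 0.5 * (lo + hi)
    half_n = int(np.ceil((hi - center) / dx + 1.5))
    i = np.arange(-half_n, half_n)  # even count, centers at +-(k+1/2)dx
    return center + (i + 0.5) * dx


def _voxelize(
    sdf: Callable[[np.ndarray], np.ndarray],
    bbox: tuple[tuple[float, float], ...],
    dx: float,
    spec: ShapeSpec | None = None,
) -> CellGeometry:
    axes = [_symmetric_axis(lo, hi, dx) for lo, hi in bbox]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    shape = X.shape
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    d = sdf(pts).reshape(shape)

    mask = d < 0

    # interior volume per voxel: full for deep-interior voxels, sub-sampled
    # near the surface (on both sides: voxels whose center lies just outside
    # can still hold interior volume, which is pushed to an inside neighbor
    # below so the voxel-summed volume is unbiased)
    volume = np.where(mask, dx**3, 0.0)
    near = np.abs(d) < dx
    if near.any():
        offs = (np.arange(_SUBSAMPLE) + 0.5) / _SUBSAMPLE - 0.5
        ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
        sub = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * dx
        centers = pts[near.ravel()]
        inside = np.zeros(len(centers))
        for off in sub:
            inside += sdf(centers + off) < 0
        frac = inside / len(sub)
        volume[near] = frac * dx**3
    volume[(~mask) & (np.abs(d) >= dx)] = 0.0
    _push_volume_inside(volume, mask)

    # membrane triangulation
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    verts, faces, _, _ = measure.marching_cubes(d, level=0.0, spacing=(dx, dx, dx))
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    centroid = tri.mean(axis=1)
    vox = np.clip(
        np.round(centroid / dx).astype(int),
        0,
        np.array(shape) - 1,
    )
    area = np.zeros(shape)
    np.add.at(area, (vox[:, 0], vox[:, 1], vox[:, 2]), tri_area)

    # move area sitting on exterior voxels onto an adjacent interior voxel
    _push_area_inside(area, mask)

    # merge tiny boundary voxels into their largest interior neighbor
    _merge_slivers(mask, volume, area, dx)

    # voxels grazed by the surface at a corner can carry area without having
    # an exterior face-neighbor; hand their area to one that does
    _enforce_boundary_adjacency(area, mask)

    wall = np.where(mask, -d, 0.0)
    geom = CellGeometry(
        dx=dx,
        origin=origin,
        mask=mask,
        volume=volume,
        area=area,
        wall_distance=wall,
        spec=spec,
    )
    return geom


def _neighbors6(idx: tuple[int, int, int], shape) -> list[tuple[int, int, int]]:
    out = []
    for ax in range(3):
        for s in (-1, 1):
            j = list(idx)
            j[ax] += s
            if 0 <= j[ax] < shape[ax]:
                out.append(tuple(j))
    return out


def _push_volume_inside(volume: np.ndarray, mask: np.ndarray) -> None:
    # split equally among interior neighbors so that mirror-symmetric shapes
    # stay mirror-symmetric after reassignment
    outside = np.argwhere((volume > 0) & ~mask)
    moved = np.zeros_like(volume)
    for idx in map(tuple, outside):
        nbrs = [j for j in _neighbors6(idx, mask.shape) if mask[j]]
        for j in nbrs:
            moved[j] += volume[idx] / len(nbrs)
        volume[idx] = 0.0
    volume += moved


def _push_area_inside(area: np.ndarray, mask: np.ndarray) -> None:
    bad = np.argwhere((area > 0) & ~mask)
    for idx in map(tuple, bad):
        nbrs = [j for j in _neighbors6(idx, mask.shape) if mask[j]]
        if not nbrs:
            # corner triangle: find any interior voxel in the 3x3x3 block
            sl = tuple(slice(max(i - 1, 0), i + 2) for i in idx)
            block = np.argwhere(mask[sl])
            if len(block) == 0:
                area[idx] = 0.0
                continue
            off = np.array([s.start for s in sl])
            nbrs = [tuple(off + block[0])]
        area[nbrs[0]] += area[idx]
        area[idx] = 0.0


def _enforce_boundary_adjacency(area: np.ndarray, mask: np.ndarray) -> None:
    from scipy import ndimage

    touches = ndimage.binary_dilation(
        ~mask, structure=ndimage.generate_binary_structure(3, 1)
    ) & mask
    bad = np.argwhere((area > 0) & ~touches)
    for idx in map(tuple, bad):
        sl = tuple(slice(max(i - 1, 0), i + 2) for i in idx)
        block = np.argwhere(touches[sl])
        if len(block) == 0:
            continue
        off = np.array([s.start for s in sl])
        target = tuple(off + block[0])
        area[target] += area[idx]
        area[idx] = 0.0


def _merge_slivers(mask, volume, area, dx) -> None:
    thresh = MIN_VOLUME_FRACTION * dx**3
    sliver = np.argwhere(mask & (volume < thresh))
    for idx in map(tuple, sliver):
        nbrs = [j for j in _neighbors6(idx, mask.shape) if mask[j] and j != idx]
        nbrs = [j for j in nbrs if volume[j] >= thresh]
        if not nbrs:
            continue  # keep: isolated thin feature
        for j in nbrs:  # equal split keeps mirror symmetry exact
            volume[j] += volume[idx] / len(nbrs)
            area[j] += area[idx] / len(nbrs)
        mask[idx] = False
        volume[idx] = 0.0
        area[idx] = 0.0


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_pill(length: float, radius: float, dx: float) -> CellGeometry:
    """Capsule cell: cylinder of the given end-to-end ``length`` with
    hemispherical caps of the given ``radius``, long axis along y."""
    spec = ShapeSpec(kind="pill", dx=dx, length=length, radius=radius)
    if dx > radius / 3:
        raise ValueError(f"dx={dx} too coarse: must be <= radius/3 = {radius / 3}")
    pad = 2 * dx
    bbox = (
        (-radius - pad, radius + pad),
        (-length / 2 - pad, length / 2 + pad),
        (-radius - pad, radius + pad),
    )
    return _voxelize(_capsule_sdf(length, radius), bbox, dx, spec)


def build_flattened(outline: Polygon, thickness: float, dx: float) -> CellGeometry:
    """Flattened "pancake" cell: the set of points within ``thickness/2`` of
    the inward-offset outline region in the z=0 plane (flat faces plus a
    semicircular rim)."""
    spec = ShapeSpec(kind="flattened", dx=dx, outline=outline, thickness=thickness)
    sdf = _pancake_sdf(outline, thickness)  # validates the width
    pad = 2 * dx
    x0, y0, x1, y1 = outline.bounds
    bbox = (
        (x0 - pad, x1 + pad),
        (y0 - pad, y1 + pad),
        (-thickness / 2 - pad, thickness / 2 + pad),
    )
    return _voxelize(sdf, bbox, dx, spec)


# ---------------------------------------------------------------------------
# stadium shapes
# ---------------------------------------------------------------------------


def stadium_polygon(length: float, width: float, resolution: int = 128) -> Polygon:
    """Discorectangle outline: a rectangle with semicircular caps on the long
    (y) axis ends; ``length`` and ``width`` are outer bounding-box extents."""
    if length < width:
        raise ValueError("stadium length must be >= width")
    half_seg = (length - width) / 2
    seg = shapely.LineString([(0, -half_seg), (0, half_seg)])
    return seg.buffer(width / 2, quad_segs=resolution)


def stadium_volume(length: float, width: float, thickness: float) -> float:
    """Closed-form volume of the flattened stadium (Steiner formula for the
    r-neighborhood of the eroded planar outline, r = thickness/2)."""
    r = thickness / 2
    lp, wp = length - 2 * r, width - 2 * r  # eroded outline extents
    if wp <= 0:
        raise ValueError("stadium width must exceed the thickness")
    seg = lp - wp  # straight-segment length of the eroded stadium
    a = seg * wp + math.pi * (wp / 2) ** 2
    p = 2 * seg + math.pi * wp
    return 2 * r * a + math.pi * r**2 * (p / 2) + (4.0 / 3.0) * math.pi * r**3


def match_stadium(reference: CellGeometry, thickness: float) -> ShapeSpec:
    """Stadium ShapeSpec with the same outline aspect ratio (length/width of
    the 2D bounding box) and total volume as a reference flattened geometry.

    Solves for the outline width by 1D root-finding on the closed-form
    stadium volume.
    """
    from scipy.optimize import brentq

    if reference.spec is None or reference.spec.kind != "flattened":
        raise ValueError("reference must be a flattened geometry")
    x0, y0, x1, y1 = reference.spec.outline.bounds
    aspect = (y1 - y0) / (x1 - x0)
    if aspect < 1:
        raise ValueError("reference long axis must be y (aspect ratio >= 1)")
    v_target = reference.total_volume

    def f(width: float) -> float:
        return stadium_volume(aspect * width, width, thickness) - v_target

    w_lo = thickness * 1.001
    w_hi = 10 * max(1.0, v_target ** (1 / 3))
    if f(w_lo) > 0:
        raise ValueError(
            "no stadium of this thickness and aspect ratio can hold the volume"
        )
    width = brentq(f, w_lo, w_hi, xtol=1e-10)
    return ShapeSpec(
        kind="flattened",
        dx=reference.dx,
        outline=stadium_polygon(aspect * width, width),
        thickness=thickness,
    )


def outline_to_csv(outline: Polygon, path, n: int = 400) -> None:
    """Write the outline boundary as an (x, y) polygon in plain CSV."""
    t = np.linspace(0, outline.exterior.length, n, endpoint=False)
    pts = [outline.exterior.interpolate(s) for s in t]
    arr = np.array([(p.x, p.y) for p in pts])
    header = "x_um,y_um"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
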