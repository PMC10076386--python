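"""Region-of-interest geometry: containment, extreme points, sections.

These are the geometric primitives behind the metric modules: the user
(or the synthetic generator) places spherical ROIs over anatomical
landmarks, cuboid ROIs astride the rib prominence and a horizontal
section plane through the neck; everything downstream is extreme-point
extraction and exact mesh/plane intersection.

Determinism: extreme points are taken over mesh *vertices* inside the
ROI (adequate at scan resolution, and invariant to face order), with a
fixed tie-break — larger ``|x|``, then smaller ``z``, then larger ``x``
— so repeat runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import Polygon

from .exceptions import (
    DegenerateContourError,
    EmptyROIError,
    InsufficientOverlapError,
)
from .mesh_io import TorsoMesh

__all__ = [
    "SphericalROI",
    "CuboidROI",
    "SectionPlane",
    "Contour",
    "extreme_point",
    "cross_section",
    "contour_centroid",
    "slice_extremes",
]

log = logging.getLogger(__name__)

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class SphericalROI:
    """Spherical query volume (mm) around a single surface landmark."""

    center: tuple
    radius: float
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 3:
            raise ValueError("center must be a 3D point")
        if not self.radius > 0:
            raise ValueError("radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        d2 = ((np.asarray(points) - np.asarray(self.center)) ** 2).sum(axis=-1)
        return d2 <= self.radius ** 2

    def mirrored_x(self) -> "SphericalROI":
        c = self.center
        return SphericalROI((-c[0], c[1], c[2]), self.radius, self.label)


@dataclass(frozen=True)
class CuboidROI:
    """Axis-aligned box query volume (mm), e.g. one side of the ribcage."""

    center: tuple
    half_extents: tuple
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(
            self, "half_extents", tuple(float(h) for h in self.half_extents)
        )
        if len(self.center) != 3 or len(self.half_extents) != 3:
            raise ValueError("center and half_extents must be 3D")
        if not all(h > 0 for h in self.half_extents):
            raise ValueError("half_extents must be positive")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.half_extents)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.half_extents)

    @property
    def z_range(self) -> tuple:
        return (self.lo[2], self.hi[2])

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points)
        return ((p >= self.lo) & (p <= self.hi)).all(axis=-1)

    def mirrored_x(self) -> "CuboidROI":
        c = self.center
        return CuboidROI((-c[0], c[1], c[2]), self.half_extents, self.label)


@dataclass(frozen=True)
class SectionPlane:
    """A world XY plane at a fixed height (mm), e.g. through the neck."""

    z_height: float

    def __post_init__(self):
        if not np.isfinite(self.z_height):
            raise ValueError("z_height must be finite")


@dataclass(frozen=True)
class Contour:
    """Closed planar polyline from a mesh cross-section.

    ``chord_closed`` flags contours assembled from an open intersection
    chain (cropped scans may be open at top/bottom) that were closed by
    a straight chord between their endpoints.
    """

    points: np.ndarray  # (k, 3), first point not repeated at the end
    z_height: float
    chord_closed: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if len(pts) < 3:
            raise ValueError("a contour needs at least 3 points")

    def polygon(self) -> Polygon:
        return Polygon(self.points[:, :2])

    @property
    def area(self) -> float:
        """Enclosed (unsigned) area in the section plane, mm^2."""
        return self.polygon().area

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def _argmax_with_ties(points: np.ndarray, direction: np.ndarray) -> int:
    """Index of the point maximising dot(direction); deterministic ties.

    Ties are broken by larger ``|x|``, then smaller ``z``, then larger
    ``x`` (fully deterministic for any vertex set).
    """
    score = points @ direction
    # np.lexsort sorts ascending by last key first; take the last element
    order = np.lexsort((points[:, 0], -points[:, 2], np.abs(points[:, 0]), score))
    return int(order[-1])


def extreme_point(
    mesh: TorsoMesh,
    roi: "SphericalROI | CuboidROI",
    direction,
) -> np.ndarray:
    """Most extreme mesh vertex inside an ROI along ``direction``.

    Returns the contained vertex maximising the dot product with the
    (unit) direction — e.g. the most anterior point of a PSIS dimple for
    direction ``(0, -1, 0)``.
    """
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("direction must be non-zero")
    direction = direction / n
    inside = roi.contains(mesh.vertices)
    if not inside.any():
        label = f" {roi.label!r}" if getattr(roi, "label", "") else ""
        raise EmptyROIError(f"ROI{label} {roi} contains no mesh vertices")
    pts = mesh.vertices[inside]
    idx = _argmax_with_ties(pts, direction)
    point = pts[idx].copy()
    log.debug("extreme_point roi=%s dir=%s -> %s", roi.label or roi, direction, point)
    return point


def _assemble_chains(segments: np.ndarray):
    """Chain (n, 2, 3) intersection segments into polylines.

    Endpoints are matched after quantisation to 1e-6 mm.  Returns a list
    of ``(points, closed)`` with points as (k, 3) arrays.  Walks open
    chains first (from odd-degree nodes), then remaining cycles;
    iteration order is deterministic.
    """
    pts = segments.reshape(-1, 3)
    quant = np.round(pts * 1e6).astype(np.int64)
    uniq, first_idx, inverse = np.unique(
        quant, axis=0, return_index=True, return_inverse=True
    )
    coords = pts[first_idx]  # representative coordinate per node
    edges = inverse.reshape(-1, 2)
    edges = edges[edges[:, 0] != edges[:, 1]]  # drop zero-length
    # deduplicate coincident segments (plane through shared vertices)
    edges = np.unique(np.sort(edges, axis=1), axis=0)

    adjacency: dict = {}
    for e, (a, b) in enumerate(edges):
        adjacency.setdefault(int(a), []).append((e, int(b)))
        adjacency.setdefault(int(b), []).append((e, int(a)))

    used = np.zeros(len(edges), dtype=bool)

    def walk(start: int):
        chain = [start]
        node = start
        while True:
            step = next(
                ((e, nxt) for e, nxt in adjacency[node] if not used[e]), None
            )
            if step is None:
                return chain
            used[step[0]] = True
            node = step[1]
            chain.append(node)
            if node == start:
                return chain

    chains = []
    odd = sorted(n for n, nb in adjacency.items() if len(nb) % 2 == 1)
    for start in odd:
        if any(not used[e] for e, _ in adjacency[start]):
            chains.append(walk(start))
    for start in sorted(adjacency):
        while any(not used[e] for e, _ in adjacency[start]):
            chains.append(walk(start))

    out = []
    for chain in chains:
        closed = len(chain) > 3 and chain[0] == chain[-1]
        nodes = chain[:-1] if closed else chain
        out.append((coords[nodes].copy(), closed))
    return out


def cross_section(mesh: TorsoMesh, plane: SectionPlane) -> list:
    """Exact mesh/plane intersection assembled into closed contours.

    Returns contours sorted by enclosed area, largest first.  A plane
    that misses the mesh yields an empty list.  Open intersection chains
    (the plane crossing a mesh boundary) are closed by a chord and
    flagged via :attr:`Contour.chord_closed`, with a logged warning.
    Chains with fewer than 3 distinct points are discarded.
    """
    tm = mesh.to_trimesh()
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=_Z, plane_origin=np.array([0.0, 0.0, plane.z_height])
    )
    if len(segments) == 0:
        return []
    contours = []
    for pts, closed in _assemble_chains(segments):
        if len(pts) < 3:
            continue
        if not closed:
            log.warning(
                "open intersection chain at z=%.3f closed by chord (%d points)",
                plane.z_height, len(pts),
            )
        pts[:, 2] = plane.z_height  # snap off numerical fuzz
        contours.append(
            Contour(points=pts, z_height=plane.z_height, chord_closed=not closed)
        )
    contours.sort(key=lambda c: c.area, reverse=True)
    return contours


def contour_centroid(contour: Contour) -> np.ndarray:
    """Area centroid of the enclosed planar polygon (not the vertex mean)."""
    poly = contour.polygon()
    if poly.area <= 0:
        raise DegenerateContourError(
            f"contour at z={contour.z_height} encloses zero area"
        )
    c = poly.centroid
    return np.array([c.x, c.y, contour.z_height])


def _clip_segments_to_box(segments: np.ndarray, box: CuboidROI) -> np.ndarray:
    """Clip (n, 2, 3) segments to an axis-aligned box; drop empty results.

    Liang–Barsky style parametric clipping per axis; returns the clipped
    segments as an (m, 2, 3) array (endpoints may coincide when a
    segment only touches the box).
    """
    if len(segments) == 0:
        return segments.reshape(0, 2, 3)
    p0 = segments[:, 0, :]
    d = segments[:, 1, :] - p0
    t0 = np.zeros(len(segments))
    t1 = np.ones(len(segments))
    lo, hi = box.lo, box.hi
    valid = np.ones(len(segments), dtype=bool)
    for ax in range(3):
        da = d[:, ax]
        pa = p0[:, ax]
        with np.errstate(divide="ignore", invalid="ignore"):
            tlo = (lo[ax] - pa) / da
            thi = (hi[ax] - pa) / da
        near = np.where(da >= 0, tlo, thi)
        far = np.where(da >= 0, thi, tlo)
        parallel = da == 0
        inside_par = (pa >= lo[ax]) & (pa <= hi[ax])
        near = np.where(parallel, np.where(inside_par, 0.0, 1.0), near)
        far = np.where(parallel, np.where(inside_par, 1.0, 0.0), far)
        t0 = np.maximum(t0, near)
        t1 = np.minimum(t1, far)
        valid &= ~(parallel & ~inside_par)
    valid &= t0 <= t1
    if not valid.any():
        return np.zeros((0, 2, 3))
    p0v, dv = p0[valid], d[valid]
    a = p0v + t0[valid][:, None] * dv
    b = p0v + t1[valid][:, None] * dv
    return np.stack([a, b], axis=1)


def slice_extremes(
    mesh: TorsoMesh,
    left: CuboidROI,
    right: CuboidROI,
    step: float = 1.0,
    direction=(0.0, 1.0, 0.0),
) -> list:
    """Per-height extreme surface points inside two cuboid ROIs.

    For every z-level (spaced ``step`` mm over the intersection of the
    two boxes' Z-ranges) the mesh is intersected with the XY plane at
    that height, the intersection is clipped to each box, and the point
    maximising the dot product with ``direction`` (most posterior by
    default) is taken per side.  Levels where either side has no clipped
    geometry are skipped.

    Returns a list of ``(z, left_point, right_point)``.  Fewer than 3
    usable levels raises :class:`InsufficientOverlapError`.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)

    z_lo = max(left.z_range[0], right.z_range[0])
    z_hi = min(left.z_range[1], right.z_range[1])
    if z_lo > z_hi:
        raise InsufficientOverlapError(
            f"ROIs' Z-ranges do not overlap ({left.z_range} vs {right.z_range})"
        )
    levels = np.arange(z_lo, z_hi + 1e-9, step)

    tm = mesh.to_trimesh()
    out = []
    for z in levels:
        segments = trimesh.intersections.mesh_plane(
            tm, plane_normal=_Z, plane_origin=np.array([0.0, 0.0, z])
        )
        if len(segments) == 0:
            continue
        pair = []
        for box in (left, right):
            clipped = _clip_segments_to_box(segments, box)
            if len(clipped) == 0:
                pair = None
                break
            pts = clipped.reshape(-1, 3)
            pair.append(pts[_argmax_with_ties(pts, direction)].copy())
        if pair is not None:
            out.append((float(z), pair[0], pair[1]))
    if len(out) < 3:
        raise InsufficientOverlapError(
            f"only {len(out)} usable slice levels in [{z_lo}, {z_hi}] at "
            f"step {step} (need >= 3)"
        )
    return out
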