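"""Torso mesh I/O and minimal preprocessing.

Meshes are triangulated torso surfaces from handheld 3D scanners,
assumed to be expressed in millimetres and already aligned to the
anatomical world frame used throughout the package:

* +X = patient's left (lateral)
* +Y = posterior
* +Z = superior

so the coronal plane is world XZ, the transverse plane world XY and the
sagittal plane world YZ.  This is a convention: scanner exports carry no
axes, and the package never fits planes to the mesh — all angles are
measured against these fixed world planes.  Meshes are expected to be
pre-aligned upstream (e.g. a calibrated standing-board protocol); no
automatic alignment is attempted here.

Supported formats are binary/ASCII STL, PLY and OBJ (triangles only),
read and written through :mod:`trimesh`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import (
    EmptyCropError,
    EmptyMeshError,
    MeshParseError,
    UnsupportedFormatError,
)

__all__ = [
    "TorsoMesh",
    "SUPPORTED_FORMATS",
    "load_mesh",
    "save_mesh",
    "smooth_once",
    "crop_z",
]

log = logging.getLogger(__name__)

SUPPORTED_FORMATS = (".stl", ".ply", ".obj")

#: faces with area below this (mm^2) are treated as degenerate
_DEGENERATE_AREA = 1e-12


@dataclass(frozen=True)
class TorsoMesh:
    """A triangulated torso surface in the anatomical world frame (mm).

    Attributes
    ----------
    vertices : (n, 3) float64 array
        Vertex coordinates in millimetres.
    faces : (m, 3) int array
        Triangles as vertex index triplets.
    provenance : str
        Free-text source tag (file path, generator description, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face index out of range")
        if not np.isfinite(v).all():
            raise ValueError("non-finite vertex coordinates")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] vertex coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def to_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` (no cleaning applied)."""
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, provenance: str = "") -> "TorsoMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), provenance)

    def translated(self, offset) -> "TorsoMesh":
        return replace(self, vertices=self.vertices + np.asarray(offset, float))

    def scaled(self, s: float) -> "TorsoMesh":
        return replace(self, vertices=self.vertices * float(s))

    def mirrored_x(self) -> "TorsoMesh":
        """Reflect across the sagittal (YZ) plane, fixing face winding."""
        v = self.vertices * np.array([-1.0, 1.0, 1.0])
        f = self.faces[:, ::-1].copy()
        return TorsoMesh(v, f, self.provenance + " [mirrored]")


def _clean(tm: trimesh.Trimesh) -> trimesh.Trimesh:
    """Merge duplicate vertices, drop zero-area faces and unused vertices."""
    tm = tm.copy()
    tm.merge_vertices()
    if len(tm.faces):
        tm.update_faces(tm.area_faces > _DEGENERATE_AREA)
    tm.remove_unreferenced_vertices()
    return tm


def load_mesh(path, unit_scale: float = 1.0) -> TorsoMesh:
    """Load a torso mesh from STL/PLY/OBJ and clean it.

    Degenerate (zero-area) faces, duplicate vertices and unreferenced
    vertices are removed.  Coordinates are multiplied by ``unit_scale``
    (STL carries no units; scans are assumed mm, so the default is 1.0 —
    pass e.g. 1000 for a mesh exported in metres).

    Raises
    ------
    FileNotFoundError, UnsupportedFormatError, MeshParseError,
    EmptyMeshError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ext = path.suffix.lower()
    if ext not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(
            f"unsupported format {ext!r} for {path.name}; expected one of "
            + ", ".join(SUPPORTED_FORMATS)
        )
    if unit_scale <= 0:
        raise ValueError("unit_scale must be positive")
    try:
        tm = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshParseError(f"could not parse {path}: {exc}") from exc
    if tm is None or not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    tm = _clean(tm)
    if len(tm.faces) == 0:
        raise EmptyMeshError(f"{path} is empty after degenerate-face cleaning")
    mesh = TorsoMesh.from_trimesh(tm, provenance=str(path))
    if unit_scale != 1.0:
        mesh = mesh.scaled(unit_scale)
    return mesh


def save_mesh(mesh: TorsoMesh, path, file_format: str | None = None) -> None:
    """Write a mesh to STL/PLY/OBJ.

    The file extension decides the format; if ``file_format`` disagrees
    with the extension a warning is logged and the extension wins.
    Round-tripping through binary STL preserves coordinates to float32
    precision (~1e-3 mm at torso scale).
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in SUPPORTED_FORMATS:
        raise UnsupportedFormatError(f"unsupported format {ext!r} for {path.name}")
    if file_format is not None:
        wanted = "." + file_format.lower().lstrip(".")
        if wanted != ext:
            log.warning(
                "requested format %s disagrees with extension %s; using %s",
                file_format, ext, ext,
            )
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to save an empty mesh")
    mesh.to_trimesh().export(str(path))


def smooth_once(mesh: TorsoMesh, iterations: int = 1) -> TorsoMesh:
    """Uniform (umbrella) Laplacian smoothing; boundary vertices fixed.

    Each interior vertex is replaced by the unweighted mean of its edge
    neighbours, once per iteration.  Topology (faces, connectivity) is
    unchanged.  This is the package's analogue of a scanner suite's
    one-shot global smooth; the default is a single pass because repeated
    smoothing erodes the surface detail the metrics depend on.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if mesh.n_faces == 0:
        raise EmptyMeshError("cannot smooth an empty mesh")
    if iterations == 0:
        return mesh

    from scipy.sparse import coo_matrix

    f = mesh.faces
    n = mesh.n_vertices
    # undirected edge list from triangles
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    edges_unique, counts = np.unique(edges, axis=0, return_counts=True)
    # boundary = edges used by exactly one face
    boundary_vertices = np.unique(edges_unique[counts == 1])
    i = np.concatenate([edges_unique[:, 0], edges_unique[:, 1]])
    j = np.concatenate([edges_unique[:, 1], edges_unique[:, 0]])
    adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n)).tocsr()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    degree[degree == 0] = 1.0

    v = mesh.vertices.copy()
    interior = np.ones(n, dtype=bool)
    interior[boundary_vertices] = False
    for _ in range(iterations):
        mean = adj.dot(v) / degree[:, None]
        v[interior] = mean[interior]
    return replace(mesh, vertices=v)


def crop_z(mesh: TorsoMesh, z_min: float, z_max: float) -> TorsoMesh:
    """Keep faces intersecting the horizontal slab ``z_min <= z <= z_max``.

    Whole faces are kept (no triangle clipping), so the output Z-extent
    can overshoot the slab by up to one face diameter.  Metric
    computations are ROI-local, making that boundary roughness
    irrelevant.
    """
    if not z_min < z_max:
        raise ValueError("z_min must be < z_max")
    z = mesh.vertices[:, 2][mesh.faces]
    keep = (z.max(axis=1) >= z_min) & (z.min(axis=1) <= z_max)
    if not keep.any():
        raise EmptyCropError(
            f"crop slab [{z_min}, {z_max}] mm does not intersect mesh "
            f"(Z-range [{mesh.bounds[0, 2]:.1f}, {mesh.bounds[1, 2]:.1f}])"
        )
    tm = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces[keep], process=False)
    tm.remove_unreferenced_vertices()
    return TorsoMesh.from_trimesh(tm, mesh.provenance + " [cropped]")
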