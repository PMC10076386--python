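"""Parametric synthetic torso meshes with exact, known cosmesis metrics.

Patient scans cannot be shared, so testing needs a stand-in whose true
metric values are known by construction.  The generator builds an
extruded elliptical trunk (mm units, anatomical world frame) and adds
independently controllable deformities:

* a wavy top rim with two **shoulder** peaks realising the requested
  shoulder rotation/tilt exactly;
* two Gaussian posterior **scapula** prominences (per-side amplitude and
  a signed height offset);
* two **PSIS dimples** — local depressions of the posterior surface —
  whose floors realise the requested hip rotation/tilt;
* a **rib hump**: the posterior surface carries a flat panel, and within
  a vertical window the panel is sheared laterally (``y = B + m(z) x``)
  with a plateau where ``m = tan(rib_hump_deg)``, so the per-height
  left-right extreme line reaches the requested torso rotation exactly;
* a cylindrical **neck stub** whose cross-section centroid is displaced
  laterally by ``head_shift`` from the PSIS midpoint.

Every feature's apex/floor is snapped onto an exact grid vertex, so the
emitted :class:`GroundTruth` (metric values, landmark points and a
recommended ROI set) is exact up to floating point: metric tests isolate
*algorithm* error from ROI-placement error (which is what human
reliability studies measure).  The mesh is deterministic for fixed
parameters and seed; optional Gaussian vertex noise emulates scanner
roughness.

What this fixture does **not** emulate: realistic human shape variation,
breathing or clothing artefacts, scan holes, or non-axis-aligned
patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ROIConfig
from .exceptions import ResolutionError, SynthesisError
from .mesh_io import TorsoMesh
from .reliability import RatingsMatrix
from .roi import CuboidROI, SectionPlane, SphericalROI

__all__ = ["SynthParams", "GroundTruth", "generate_torso", "simulate_ratings"]

# feature geometry as fractions of the base dimensions ------------------
_X_FLAT = 0.733  # posterior flat panel half-width, x fraction of A
_X_SHOULDER = 0.8  # shoulder peak lateral position, fraction of A
_SHOULDER_SIGMA_U = 0.15  # rad, angular width of the shoulder peaks
_SHOULDER_BASE_H = 25.0  # mm, baseline shoulder peak height above the rim
_X_SCAPULA = 0.4  # fraction of A
_Z_SCAPULA = 0.78  # fraction of H
_SCAPULA_SIGMA = 0.133  # fraction of A (both lateral and vertical)
_SCAPULA_BASE_H = 5.0  # mm, baseline scapular protrusion
_PSIS_BASE_DEPTH = 2.0  # mm, minimum dimple depth
_X_PSIS = 0.267  # fraction of A
_Z_PSIS = 0.15  # fraction of H
_PSIS_SIGMA = 0.0933  # fraction of A
_NECK_RADIUS = 0.35  # fraction of B
_NECK_HEIGHT = 80.0  # mm
_NECK_RINGS = 9
_ROI_R_SHOULDER = 35.0  # mm at A = 150, scaled with A
_ROI_R_SCAPULA = 30.0
_ROI_R_PSIS = 25.0


@dataclass(frozen=True)
class SynthParams:
    """Generator parameters (mm / degrees).

    Defaults describe an adolescent-sized symmetric trunk: 500 mm tall,
    300 mm wide, 200 mm deep, with an 8 mm PSIS dimple depth and no
    deformity.  Angle parameters must lie in (-45, 45) degrees.
    """

    torso_height: float = 500.0
    base_half_width: float = 150.0
    base_half_depth: float = 100.0
    shoulder_tilt_deg: float = 0.0
    shoulder_rotation_deg: float = 0.0
    scapula_prominence_left: float = 0.0
    scapula_prominence_right: float = 0.0
    scapula_height_offset: float = 0.0
    psis_depth: float = 8.0
    psis_height_offset_deg: float = 0.0
    psis_rotation_deg: float = 0.0
    rib_hump_deg: float = 0.0
    rib_hump_z_center: float | None = None
    rib_hump_z_span: float | None = None
    head_shift: float = 0.0
    mesh_resolution: int = 144
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self):
        angles = {
            "shoulder_tilt_deg": self.shoulder_tilt_deg,
            "shoulder_rotation_deg": self.shoulder_rotation_deg,
            "psis_height_offset_deg": self.psis_height_offset_deg,
            "psis_rotation_deg": self.psis_rotation_deg,
            "rib_hump_deg": self.rib_hump_deg,
        }
        bad = [k for k, v in angles.items() if not -45.0 < v < 45.0]
        if bad:
            raise SynthesisError(
                f"angle parameters must lie in (-45, 45) deg: {', '.join(bad)}"
            )
        nonneg = {
            "torso_height": self.torso_height,
            "base_half_width": self.base_half_width,
            "base_half_depth": self.base_half_depth,
            "scapula_prominence_left": self.scapula_prominence_left,
            "scapula_prominence_right": self.scapula_prominence_right,
            "psis_depth": self.psis_depth,
            "noise_sd": self.noise_sd,
        }
        bad = [k for k, v in nonneg.items() if v < 0]
        if bad:
            raise SynthesisError(f"parameters must be >= 0: {', '.join(bad)}")
        if min(self.torso_height, self.base_half_width, self.base_half_depth) <= 0:
            raise SynthesisError("torso dimensions must be positive")
        if self.mesh_resolution < 36:
            raise SynthesisError("mesh_resolution must be >= 36 vertices per ring")
        if abs(self.head_shift) > 0.3 * self.base_half_width:
            raise SynthesisError(
                "head_shift too large for the neck to clear the shoulder ROIs "
                f"(|head_shift| <= {0.3 * self.base_half_width:.0f} mm)"
            )
        if self.rib_hump_z_span is not None and self.rib_hump_z_span <= 0:
            raise SynthesisError("rib_hump_z_span must be positive")

    @property
    def hump_center(self) -> float:
        return (
            0.5 * self.torso_height
            if self.rib_hump_z_center is None
            else self.rib_hump_z_center
        )

    @property
    def hump_span(self) -> float:
        return (
            0.32 * self.torso_height
            if self.rib_hump_z_span is None
            else self.rib_hump_z_span
        )

    def mirrored(self) -> "SynthParams":
        """Parameters of the sagittally mirrored torso (left/right swap)."""
        return replace(
            self,
            shoulder_tilt_deg=-self.shoulder_tilt_deg,
            shoulder_rotation_deg=-self.shoulder_rotation_deg,
            scapula_prominence_left=self.scapula_prominence_right,
            scapula_prominence_right=self.scapula_prominence_left,
            scapula_height_offset=-self.scapula_height_offset,
            psis_height_offset_deg=-self.psis_height_offset_deg,
            psis_rotation_deg=-self.psis_rotation_deg,
            rib_hump_deg=-self.rib_hump_deg,
            head_shift=-self.head_shift,
        )


@dataclass(frozen=True)
class GroundTruth:
    """True metric values implied by a parameter set, plus ROI placements.

    ``metrics`` is keyed ShR/ShT/ScR/ScT/HR/HT (degrees), TR (degrees),
    HPS (mm); ``landmarks`` holds the exact feature apex/floor points the
    metrics derive from; ``roi_config`` is the recommended ROI set
    centred on those landmarks.
    """

    metrics: dict
    landmarks: dict
    roi_config: ROIConfig

    def to_dict(self) -> dict:
        return {
            "metrics": {k: float(v) for k, v in self.metrics.items()},
            "landmarks": {
                k: [float(x) for x in v] for k, v in self.landmarks.items()
            },
            "roi_config": self.roi_config.to_dict(),
        }


def _snap_column(x_columns: np.ndarray, target_x: float, posterior: np.ndarray) -> int:
    """Grid column (posterior half) whose x is closest to ``target_x``."""
    candidates = np.where(posterior)[0]
    return int(candidates[np.argmin(np.abs(x_columns[candidates] - target_x))])


def generate_torso(params: SynthParams) -> tuple:
    """Build the synthetic torso mesh and its exact ground truth.

    Returns ``(TorsoMesh, GroundTruth)``.  Deterministic for fixed
    parameters and seed.  Raises :class:`ResolutionError` when the mesh
    resolution cannot resolve the smallest surface feature (feature
    diameter under three vertex spacings).
    """
    p = params
    A, B, H = p.base_half_width, p.base_half_depth, p.torso_height

    n_u = int(math.ceil(p.mesh_resolution / 4.0)) * 4  # symmetric grid
    n_t = n_u
    du_arc = 2.0 * math.pi * A / n_u
    dz = H / n_t
    spacing = max(du_arc, dz)
    min_feature = 6.0 * _PSIS_SIGMA * A  # smallest feature diameter
    if min_feature < 3.0 * spacing:
        raise ResolutionError(
            f"vertex spacing {spacing:.1f} mm cannot resolve the smallest "
            f"surface feature ({min_feature:.1f} mm across); increase "
            "mesh_resolution"
        )

    u = 2.0 * math.pi * np.arange(n_u) / n_u
    x_col = A * np.cos(u)
    y_col = B * np.sin(u)
    posterior = np.sin(u) > 1e-12
    flat = posterior & (np.abs(x_col) <= _X_FLAT * A)
    y_col = np.where(flat, B, y_col)

    t = np.arange(n_t + 1) * dz  # ring heights, 0 .. H
    X = np.tile(x_col, (n_t + 1, 1))
    Y = np.tile(y_col, (n_t + 1, 1))
    Z = np.tile(t[:, None], (1, n_u))

    landmarks = {}
    metrics = {}

    # ---- rib hump: sheared flat panel with an exact plateau ----------
    zc, span = p.hump_center, p.hump_span
    w0 = min(10.0 * H / 500.0, span / 8.0)  # plateau half-height
    d = np.abs(t - zc)
    ramp = np.zeros_like(t)
    ramp[d <= w0] = 1.0
    edge = (d > w0) & (d <= span / 2.0)
    ramp[edge] = np.cos(
        0.5 * math.pi * (d[edge] - w0) / (span / 2.0 - w0)
    ) ** 2
    m = math.tan(math.radians(p.rib_hump_deg)) * ramp
    Y[:, flat] += m[:, None] * x_col[flat]
    metrics["TR"] = p.rib_hump_deg

    # ---- scapula prominences ----------------------------------------
    # a small baseline prominence keeps the apex a unique extreme point
    # even on a symmetric back (scapulae always protrude); it cancels in
    # the left-right differences so no ground-truth angle changes
    sc_sigma = _SCAPULA_SIGMA * A
    scapula_points = {}
    j_sc_left = _snap_column(x_col, _X_SCAPULA * A, flat)
    for side, sgn, j, amp in (
        ("left", 1.0, j_sc_left, _SCAPULA_BASE_H + p.scapula_prominence_left),
        ("right", -1.0, n_u // 2 - j_sc_left, _SCAPULA_BASE_H + p.scapula_prominence_right),
    ):
        z_target = _Z_SCAPULA * H + sgn * p.scapula_height_offset / 2.0
        i = int(round(z_target / dz))
        g = np.exp(
            -(
                (X - x_col[j]) ** 2 / (2.0 * sc_sigma ** 2)
                + (Z - t[i]) ** 2 / (2.0 * sc_sigma ** 2)
            )
        )
        Y[:, flat] += amp * g[:, flat]
        X[i, j], Y[i, j], Z[i, j] = x_col[j], B + amp, z_target
        scapula_points[side] = np.array([x_col[j], B + amp, z_target])
    landmarks["scapula_left"] = scapula_points["left"]
    landmarks["scapula_right"] = scapula_points["right"]
    dxy = scapula_points["left"] - scapula_points["right"]
    metrics["ScR"] = math.degrees(math.atan(dxy[1] / dxy[0]))
    metrics["ScT"] = math.degrees(math.atan(dxy[2] / math.hypot(dxy[0], dxy[1])))

    # ---- PSIS dimples ------------------------------------------------
    ps_sigma = _PSIS_SIGMA * A
    j_l = _snap_column(x_col, _X_PSIS * A, flat)
    j_r = n_u // 2 - j_l  # exact mirror column
    dx_p = x_col[j_l] - x_col[j_r]
    dy_p = dx_p * math.tan(math.radians(p.psis_rotation_deg))
    dz_p = math.tan(math.radians(p.psis_height_offset_deg)) * math.hypot(dx_p, dy_p)
    # deepen both dimples by |dy|/2 so each stays a genuine depression
    # whatever the requested hip rotation; a 2 mm minimum keeps the floor
    # a unique extremum (PSIS dimples are always present on a back)
    depth_base = max(p.psis_depth, _PSIS_BASE_DEPTH) + abs(dy_p) / 2.0
    psis_points = {}
    for side, j, y_floor, z_target in (
        ("left", j_l, B - depth_base + dy_p / 2.0, _Z_PSIS * H + dz_p / 2.0),
        ("right", j_r, B - depth_base - dy_p / 2.0, _Z_PSIS * H - dz_p / 2.0),
    ):
        i = int(round(z_target / dz))
        depth = B - y_floor
        g = np.exp(
            -(
                (X - x_col[j]) ** 2 / (2.0 * ps_sigma ** 2)
                + (Z - t[i]) ** 2 / (2.0 * ps_sigma ** 2)
            )
        )
        Y[:, flat] -= depth * g[:, flat]
        X[i, j], Y[i, j], Z[i, j] = x_col[j], y_floor, z_target
        psis_points[side] = np.array([x_col[j], y_floor, z_target])
    landmarks["psis_left"] = psis_points["left"]
    landmarks["psis_right"] = psis_points["right"]
    metrics["HR"] = p.psis_rotation_deg
    metrics["HT"] = p.psis_height_offset_deg

    # ---- shoulders: wavy top rim with two exact peaks ----------------
    j_sl = _snap_column(x_col, _X_SHOULDER * A, posterior)
    j_sr = n_u // 2 - j_sl  # exact mirror column
    dx_s = x_col[j_sl] - x_col[j_sr]
    dy_s = dx_s * math.tan(math.radians(p.shoulder_rotation_deg))
    dz_s = math.tan(math.radians(p.shoulder_tilt_deg)) * math.hypot(dx_s, dy_s)
    # a downward-displaced peak would stop being its ROI's superior
    # extremum, so the full tilt offset raises one side only
    peak_h = {
        "left": _SHOULDER_BASE_H + max(dz_s, 0.0),
        "right": _SHOULDER_BASE_H + max(-dz_s, 0.0),
    }
    du_wrap = (u - u[j_sl] + math.pi) % (2.0 * math.pi) - math.pi
    g_l = np.exp(-(du_wrap ** 2) / (2.0 * _SHOULDER_SIGMA_U ** 2))
    du_wrap = (u - u[j_sr] + math.pi) % (2.0 * math.pi) - math.pi
    g_r = np.exp(-(du_wrap ** 2) / (2.0 * _SHOULDER_SIGMA_U ** 2))
    Z[n_t, :] = H + peak_h["left"] * g_l + peak_h["right"] * g_r
    Y[n_t, :] += (dy_s / 2.0) * (g_l - g_r)
    shoulder_points = {
        "left": np.array(
            [x_col[j_sl], y_col[j_sl] + dy_s / 2.0, H + peak_h["left"]]
        ),
        "right": np.array(
            [x_col[j_sr], y_col[j_sr] - dy_s / 2.0, H + peak_h["right"]]
        ),
    }
    X[n_t, j_sl], Y[n_t, j_sl], Z[n_t, j_sl] = shoulder_points["left"]
    X[n_t, j_sr], Y[n_t, j_sr], Z[n_t, j_sr] = shoulder_points["right"]
    landmarks["shoulder_left"] = shoulder_points["left"]
    landmarks["shoulder_right"] = shoulder_points["right"]
    metrics["ShR"] = p.shoulder_rotation_deg
    metrics["ShT"] = p.shoulder_tilt_deg

    # ---- trunk vertices and faces ------------------------------------
    def tube_faces(n_rings: int, n_around: int, offset: int) -> np.ndarray:
        i_idx, j_idx = np.meshgrid(
            np.arange(n_rings), np.arange(n_around), indexing="ij"
        )
        v00 = offset + i_idx * n_around + j_idx
        v01 = offset + i_idx * n_around + (j_idx + 1) % n_around
        v10 = v00 + n_around
        v11 = v01 + n_around
        quads = np.stack(
            [
                np.stack([v00, v01, v11], axis=-1),
                np.stack([v00, v11, v10], axis=-1),
            ],
            axis=-2,
        )
        return quads.reshape(-1, 3)

    trunk_vertices = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    trunk_faces = tube_faces(n_t, n_u, 0)

    # ---- neck stub ----------------------------------------------------
    r_neck = _NECK_RADIUS * B
    neck_z = H + np.linspace(0.0, _NECK_HEIGHT, _NECK_RINGS)
    nx = p.head_shift + r_neck * np.cos(u)
    ny = r_neck * np.sin(u)
    neck_vertices = np.stack(
        [
            np.tile(nx, _NECK_RINGS),
            np.tile(ny, _NECK_RINGS),
            np.repeat(neck_z, n_u),
        ],
        axis=-1,
    )
    neck_faces = tube_faces(_NECK_RINGS - 1, n_u, len(trunk_vertices))
    neck_plane_z = H + 45.0  # between stub rings
    landmarks["neck_center"] = np.array([p.head_shift, 0.0, neck_plane_z])
    psis_mid = (psis_points["left"] + psis_points["right"]) / 2.0
    metrics["HPS"] = p.head_shift - float(psis_mid[0])

    vertices = np.vstack([trunk_vertices, neck_vertices])
    faces = np.vstack([trunk_faces, neck_faces])

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        vertices = vertices + rng.normal(0.0, p.noise_sd, vertices.shape)

    mesh = TorsoMesh(
        vertices,
        faces,
        provenance=f"synthetic torso (seed={p.seed}, resolution={n_u})",
    )

    # ---- recommended ROI set -----------------------------------------
    scale = A / 150.0
    zc_box = zc
    half_span = span / 2.0
    roi_config = ROIConfig.from_dict(
        {
            "shoulder": {
                side: {
                    "center": [float(c) for c in shoulder_points[side]],
                    "radius": _ROI_R_SHOULDER * scale,
                }
                for side in ("left", "right")
            },
            "scapula": {
                side: {
                    "center": [float(c) for c in scapula_points[side]],
                    "radius": _ROI_R_SCAPULA * scale,
                }
                for side in ("left", "right")
            },
            "hip": {
                side: {
                    "center": [float(c) for c in psis_points[side]],
                    "radius": _ROI_R_PSIS * scale,
                }
                for side in ("left", "right")
            },
            "torso_rotation": {
                "left": {
                    "center": [0.433 * A, B, zc_box],
                    "half_extents": [0.233 * A, 1.2 * B, half_span],
                },
                "right": {
                    "center": [-0.433 * A, B, zc_box],
                    "half_extents": [0.233 * A, 1.2 * B, half_span],
                },
                "step": 1.0,
            },
            "hps": {"neck_plane_z": neck_plane_z},
        }
    )

    truth = GroundTruth(
        metrics=metrics, landmarks=landmarks, roi_config=roi_config
    )
    return mesh, truth


def simulate_ratings(
    truth,
    rater_bias_sd: float,
    residual_sd: float,
    n_raters: int,
    seed: int = 0,
) -> RatingsMatrix:
    """Simulate a subjects x raters ratings table around true values.

    ``value[i, j] = truth[i] + bias[j] + e[i, j]`` with rater biases
    ``~ N(0, rater_bias_sd^2)`` and residuals ``~ N(0, residual_sd^2)``.
    With subject variance ``sigma_s^2`` the population ICC(A,1) is
    ``sigma_s^2 / (sigma_s^2 + rater_bias_sd^2 + residual_sd^2)``.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    if truth.size < 2:
        raise ValueError("need at least 2 subjects")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if rater_bias_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, rater_bias_sd, n_raters) if rater_bias_sd > 0 else np.zeros(n_raters)
    resid = (
        rng.normal(0.0, residual_sd, (truth.size, n_raters))
        if residual_sd > 0
        else np.zeros((truth.size, n_raters))
    )
    values = truth[:, None] + bias[None, :] + resid
    return RatingsMatrix(
        values,
        subject_ids=tuple(range(1, truth.size + 1)),
        rating_labels=tuple(f"R{j}" for j in range(1, n_raters + 1)),
    )
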