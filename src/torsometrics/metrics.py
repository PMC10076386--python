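"""The five AIS cosmesis metrics.

All angles are measured against world-fixed anatomical planes
(coronal = XZ, transverse = XY; see :mod:`torsometrics.mesh_io`), never
against planes fitted to the mesh:

* **Rotation** of a left-right landmark line is its deviation from the
  coronal plane viewed in the transverse plane: ``atan(dy/dx)`` with
  ``d = left - right``.  Positive when the patient's left landmark is
  more posterior than the right.
* **Tilt** is the line's elevation out of the transverse plane:
  ``atan(dz / hypot(dx, dy))``.  Positive when the left landmark is
  higher.
* **Torso rotation (TR)** scans the rib prominence: at every height the
  line joining the most posterior surface points inside the left/right
  boxes is formed, and TR is the rotation of the line with maximum
  magnitude — a standing-posture analogue of the rib-hump angle.
* **Head-pelvis shift (HPS)** is the lateral (X) offset of the neck
  cross-section's area centroid from the midpoint of the PSIS dimple
  line; positive when the head sits toward the patient's left.

Angles are reported *signed*; the sign encodes laterality (clinically
recorded as left/right) and magnitudes are trivially derivable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .config import ROIConfig, SPHERE_FEATURES
from .exceptions import (
    ConfigError,
    NoNeckSectionError,
    TorsoMetricsError,
    UndefinedAngleError,
)
from .mesh_io import TorsoMesh
from .roi import (
    CuboidROI,
    SectionPlane,
    SphericalROI,
    contour_centroid,
    cross_section,
    extreme_point,
    slice_extremes,
)

__all__ = [
    "AsymmetryAngles",
    "TorsoRotationResult",
    "HPSResult",
    "MeasurementReport",
    "rotation_angle",
    "tilt_angle",
    "paired_feature_asymmetry",
    "torso_rotation",
    "head_pelvis_shift",
    "measure_all",
    "METRIC_KEYS",
]

log = logging.getLogger(__name__)

#: report keys, in clinical reading order: shoulder/scapula/hip
#: rotation+tilt, then torso rotation, then head-pelvis shift.
METRIC_KEYS = ("ShR", "ShT", "ScR", "ScT", "HR", "HT", "TR", "HPS")

_EPS = 1e-9


@dataclass(frozen=True)
class AsymmetryAngles:
    """Rotation/tilt pair for one paired-landmark feature (degrees)."""

    feature: str  # shoulder | scapula | hip
    rotation_deg: float
    tilt_deg: float
    left_point: np.ndarray
    right_point: np.ndarray


@dataclass(frozen=True)
class TorsoRotationResult:
    """Torso rotation with its per-height angle profile."""

    tr_deg: float
    z_at_max: float
    left_point: np.ndarray
    right_point: np.ndarray
    profile: tuple  # ((z, angle_deg), ...)


@dataclass(frozen=True)
class HPSResult:
    """Head-pelvis shift with its supporting geometry (mm)."""

    shift_mm: float
    neck_centroid: np.ndarray
    psis_midpoint: np.ndarray


def rotation_angle(left_point, right_point) -> float:
    """Signed deviation (degrees) of a landmark line from the coronal plane.

    ``atan(dy/dx)`` with ``d = left - right``; positive when the left
    point is more posterior.  A near-vertical pair (``|dx|`` below
    1e-9 mm) has no transverse-plane direction and raises
    :class:`UndefinedAngleError`.
    """
    d = np.asarray(left_point, float) - np.asarray(right_point, float)
    if abs(d[0]) < _EPS:
        raise UndefinedAngleError(
            "rotation undefined: landmark pair has no lateral (X) separation"
        )
    return math.degrees(math.atan(d[1] / d[0]))


def tilt_angle(left_point, right_point) -> float:
    """Signed elevation (degrees) of a landmark line from the transverse plane.

    ``atan(dz / hypot(dx, dy))``; positive when the left point is
    higher.  A purely vertical pair raises :class:`UndefinedAngleError`.
    """
    d = np.asarray(left_point, float) - np.asarray(right_point, float)
    horizontal = math.hypot(d[0], d[1])
    if horizontal < _EPS:
        raise UndefinedAngleError(
            "tilt undefined: landmark pair is purely vertical"
        )
    return math.degrees(math.atan(d[2] / horizontal))


def paired_feature_asymmetry(
    mesh: TorsoMesh,
    left_roi: SphericalROI,
    right_roi: SphericalROI,
    feature: str,
    direction=None,
) -> AsymmetryAngles:
    """Rotation and tilt of one paired anatomical feature.

    The feature-specific extreme point is extracted per side (defaults:
    shoulder -> most superior, scapula -> most posterior, hip/PSIS ->
    most anterior, i.e. the dimple floor) and the connecting line's
    rotation and tilt are returned.
    """
    if feature not in SPHERE_FEATURES:
        raise ConfigError(f"unknown paired feature {feature!r}")
    if not left_roi.center[0] > right_roi.center[0]:
        raise ConfigError(
            f"{feature}: left ROI must lie on the patient's left (+X) of "
            "the right ROI"
        )
    if direction is None:
        from .config import DEFAULT_DIRECTIONS

        direction = DEFAULT_DIRECTIONS[feature]
    left_point = extreme_point(mesh, left_roi, direction)
    right_point = extreme_point(mesh, right_roi, direction)
    rot = rotation_angle(left_point, right_point)
    tilt = tilt_angle(left_point, right_point)
    log.debug(
        "%s: left=%s right=%s rotation=%.3f deg tilt=%.3f deg",
        feature, left_point, right_point, rot, tilt,
    )
    return AsymmetryAngles(feature, rot, tilt, left_point, right_point)


def torso_rotation(
    mesh: TorsoMesh,
    left_box: CuboidROI,
    right_box: CuboidROI,
    step: float = 1.0,
) -> TorsoRotationResult:
    """Maximum per-height coronal deviation of the rib-prominence line.

    The most posterior surface point inside each box is found every
    ``step`` mm of height; TR is the rotation angle of largest magnitude
    over those lines (left- and right-sided humps are treated
    symmetrically), ties resolved to the lowest height.  Levels whose
    landmark pair has no lateral separation are skipped.
    """
    levels = slice_extremes(mesh, left_box, right_box, step=step)
    profile = []
    points = []
    for z, lp, rp in levels:
        try:
            ang = rotation_angle(lp, rp)
        except UndefinedAngleError:
            continue
        profile.append((z, ang))
        points.append((lp, rp))
    if len(profile) < 3:
        raise UndefinedAngleError(
            "torso rotation undefined: fewer than 3 levels with laterally "
            "separated extreme points"
        )
    angles = np.array([a for _, a in profile])
    best = int(np.argmax(np.abs(angles)))  # first max -> lowest z (sorted)
    z_best, ang_best = profile[best]
    lp, rp = points[best]
    log.debug("TR=%.3f deg at z=%.1f mm (%d levels)", ang_best, z_best, len(profile))
    return TorsoRotationResult(
        tr_deg=float(ang_best),
        z_at_max=float(z_best),
        left_point=lp,
        right_point=rp,
        profile=tuple(profile),
    )


def head_pelvis_shift(
    mesh: TorsoMesh,
    neck_plane: SectionPlane,
    left_psis: SphericalROI,
    right_psis: SphericalROI,
    psis_direction=(0.0, -1.0, 0.0),
) -> HPSResult:
    """Lateral offset of the neck centroid from the PSIS-line midpoint.

    The neck centroid is the area centroid of the largest-area contour
    where the section plane cuts the mesh (scan slivers are thereby
    ignored); the pelvic reference is the midpoint of the two PSIS
    dimple floors.  Positive shift = head toward the patient's left.
    """
    contours = cross_section(mesh, neck_plane)
    if not contours:
        raise NoNeckSectionError(
            f"section plane z={neck_plane.z_height} mm does not intersect the mesh"
        )
    neck_centroid = contour_centroid(contours[0])
    lp = extreme_point(mesh, left_psis, psis_direction)
    rp = extreme_point(mesh, right_psis, psis_direction)
    midpoint = (lp + rp) / 2.0
    shift = float(neck_centroid[0] - midpoint[0])
    log.debug(
        "HPS=%.3f mm (neck centroid %s, PSIS midpoint %s)",
        shift, neck_centroid, midpoint,
    )
    return HPSResult(shift_mm=shift, neck_centroid=neck_centroid, psis_midpoint=midpoint)


def _point(p) -> list:
    return [float(x) for x in p]


@dataclass
class MeasurementReport:
    """Structured result of :func:`measure_all`.

    Per-metric failures are captured in :attr:`errors` (metric name ->
    message) instead of aborting the whole measurement.
    """

    shoulder: AsymmetryAngles | None = None
    scapula: AsymmetryAngles | None = None
    hip: AsymmetryAngles | None = None
    torso_rotation: TorsoRotationResult | None = None
    hps: HPSResult | None = None
    errors: dict = field(default_factory=dict)
    provenance: str = ""

    def values(self) -> dict:
        """The eight metric values keyed ShR..HPS; None where failed."""
        out = dict.fromkeys(METRIC_KEYS)
        for feature, (rk, tk) in (
            ("shoulder", ("ShR", "ShT")),
            ("scapula", ("ScR", "ScT")),
            ("hip", ("HR", "HT")),
        ):
            angles = getattr(self, feature)
            if angles is not None:
                out[rk] = angles.rotation_deg
                out[tk] = angles.tilt_deg
        if self.torso_rotation is not None:
            out["TR"] = self.torso_rotation.tr_deg
        if self.hps is not None:
            out["HPS"] = self.hps.shift_mm
        return out

    def to_dict(self) -> dict:
        out = {"provenance": self.provenance, "metrics": {}, "errors": dict(self.errors)}
        units = dict.fromkeys(METRIC_KEYS, "deg")
        units["HPS"] = "mm"
        for key, value in self.values().items():
            out["metrics"][key] = {
                "value": None if value is None else float(value),
                "units": units[key],
            }
        for feature in ("shoulder", "scapula", "hip"):
            angles = getattr(self, feature)
            if angles is not None:
                out.setdefault("landmarks", {})[feature] = {
                    "left": _point(angles.left_point),
                    "right": _point(angles.right_point),
                }
        if self.torso_rotation is not None:
            tr = self.torso_rotation
            out.setdefault("landmarks", {})["torso_rotation"] = {
                "z_at_max": float(tr.z_at_max),
                "left": _point(tr.left_point),
                "right": _point(tr.right_point),
            }
        if self.hps is not None:
            out.setdefault("landmarks", {})["hps"] = {
                "neck_centroid": _point(self.hps.neck_centroid),
                "psis_midpoint": _point(self.hps.psis_midpoint),
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_csv_rows(self, patient_id: str = "") -> list:
        """Flat rows: (patient, metric, value, units, supporting coords)."""
        rows = []
        d = self.to_dict()
        for key in METRIC_KEYS:
            entry = d["metrics"][key]
            rows.append(
                {
                    "patient": patient_id or self.provenance,
                    "metric": key,
                    "value": entry["value"],
                    "units": entry["units"],
                    "error": self.errors.get(_metric_group(key), ""),
                }
            )
        return rows


def _metric_group(key: str) -> str:
    return {
        "ShR": "shoulder", "ShT": "shoulder",
        "ScR": "scapula", "ScT": "scapula",
        "HR": "hip", "HT": "hip",
        "TR": "torso_rotation", "HPS": "hps",
    }[key]


def measure_all(
    mesh: TorsoMesh,
    config: ROIConfig,
    metrics=("shoulder", "scapula", "hip", "torso_rotation", "hps"),
) -> MeasurementReport:
    """Run every requested metric, capturing per-metric failures.

    A metric whose ROI block is absent from the config, or whose
    computation raises a tool error, is recorded in ``report.errors``
    and the remaining metrics still run.  HPS depends on the hip (PSIS)
    ROIs as its pelvic reference, so it fails alongside a missing hip
    block.
    """
    if isinstance(config, dict):
        config = ROIConfig.from_dict(config)
    report = MeasurementReport(provenance=mesh.provenance)

    for feature in SPHERE_FEATURES:
        if feature not in metrics:
            continue
        pair = getattr(config, feature)
        if pair is None:
            report.errors[feature] = f"config has no {feature!r} ROI block"
            continue
        try:
            setattr(
                report,
                feature,
                paired_feature_asymmetry(
                    mesh, pair[0], pair[1], feature,
                    direction=config.direction_for(feature),
                ),
            )
        except TorsoMetricsError as exc:
            report.errors[feature] = str(exc)

    if "torso_rotation" in metrics:
        if config.tr_boxes is None:
            report.errors["torso_rotation"] = "config has no 'torso_rotation' block"
        else:
            try:
                report.torso_rotation = torso_rotation(
                    mesh, config.tr_boxes[0], config.tr_boxes[1], step=config.tr_step
                )
            except TorsoMetricsError as exc:
                report.errors["torso_rotation"] = str(exc)

    if "hps" in metrics:
        if config.neck_plane is None:
            report.errors["hps"] = "config has no 'hps' block"
        elif config.hip is None:
            report.errors["hps"] = (
                "head-pelvis shift needs the hip (PSIS) ROIs as pelvic reference"
            )
        else:
            try:
                report.hps = head_pelvis_shift(
                    mesh, config.neck_plane, config.hip[0], config.hip[1],
                    psis_direction=config.direction_for("hip"),
                )
            except TorsoMetricsError as exc:
                report.errors["hps"] = str(exc)

    return report
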