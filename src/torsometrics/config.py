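"""Declarative measurement configuration (the ROI placement schema).

The interactive step of the measurement workflow — a user dragging
spheres, boxes and a neck plane over the torso — is captured here as a
declarative YAML/JSON document, so a measurement session is a
reproducible, diffable artifact.  Schema (units mm throughout)::

    shoulder:
      left:  {center: [x, y, z], radius: r}
      right: {center: [x, y, z], radius: r}
    scapula: { ... same shape ... }
    hip:     { ... same shape ... }
    torso_rotation:
      left:  {center: [x, y, z], half_extents: [hx, hy, hz]}
      right: {center: [x, y, z], half_extents: [hx, hy, hz]}
      step: 1.0            # optional, mm
    hps:
      neck_plane_z: 545.0
    directions:            # optional extremum-direction overrides
      shoulder: [0, 0, 1]
      scapula:  [0, 1, 0]
      hip:      [0, -1, 0]

Any metric block may be omitted; only the metrics whose blocks are
present can be measured.  ``left`` always means the patient's left
(+X side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError
from .roi import CuboidROI, SectionPlane, SphericalROI

__all__ = ["ROIConfig", "SPHERE_FEATURES", "DEFAULT_DIRECTIONS"]

SPHERE_FEATURES = ("shoulder", "scapula", "hip")

#: default extremum direction per paired feature: shoulders are read at
#: their most superior point, scapulae at their most posterior
#: (prominence apex), PSIS dimples at their most anterior (dimple floor,
#: i.e. "most inward" on the back surface).
DEFAULT_DIRECTIONS = {
    "shoulder": (0.0, 0.0, 1.0),
    "scapula": (0.0, 1.0, 0.0),
    "hip": (0.0, -1.0, 0.0),
}


def _require(mapping, keys, where):
    missing = [k for k in keys if k not in mapping]
    if missing:
        raise ConfigError(
            f"config section {where!r} is missing keys: {', '.join(missing)}",
            missing=[f"{where}.{k}" for k in missing],
        )


def _sphere_pair(block, feature):
    _require(block, ("left", "right"), feature)
    rois = {}
    for side in ("left", "right"):
        spec = block[side]
        _require(spec, ("center", "radius"), f"{feature}.{side}")
        rois[side] = SphericalROI(
            center=spec["center"], radius=spec["radius"], label=f"{feature}.{side}"
        )
    if not rois["left"].center[0] > rois["right"].center[0]:
        raise ConfigError(
            f"{feature}: left ROI must lie on the patient's left (+X) of the "
            f"right ROI (got x_left={rois['left'].center[0]}, "
            f"x_right={rois['right'].center[0]})"
        )
    return rois["left"], rois["right"]


@dataclass(frozen=True)
class ROIConfig:
    """Validated ROI placements for any subset of the five metrics."""

    shoulder: tuple | None = None  # (left, right) SphericalROI
    scapula: tuple | None = None
    hip: tuple | None = None
    tr_boxes: tuple | None = None  # (left, right) CuboidROI
    tr_step: float = 1.0
    neck_plane: SectionPlane | None = None
    directions: dict = field(default_factory=dict)

    def direction_for(self, feature: str):
        return self.directions.get(feature, DEFAULT_DIRECTIONS[feature])

    @classmethod
    def from_dict(cls, raw: dict) -> "ROIConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        kwargs = {}
        for feature in SPHERE_FEATURES:
            if feature in raw:
                kwargs[feature] = _sphere_pair(raw[feature], feature)
        if "torso_rotation" in raw:
            block = raw["torso_rotation"]
            _require(block, ("left", "right"), "torso_rotation")
            boxes = []
            for side in ("left", "right"):
                spec = block[side]
                _require(
                    spec, ("center", "half_extents"), f"torso_rotation.{side}"
                )
                boxes.append(
                    CuboidROI(
                        center=spec["center"],
                        half_extents=spec["half_extents"],
                        label=f"torso_rotation.{side}",
                    )
                )
            if not boxes[0].center[0] > boxes[1].center[0]:
                raise ConfigError(
                    "torso_rotation: left box must lie on the patient's left "
                    "(+X) of the right box"
                )
            kwargs["tr_boxes"] = tuple(boxes)
            kwargs["tr_step"] = float(block.get("step", 1.0))
            if kwargs["tr_step"] <= 0:
                raise ConfigError("torso_rotation.step must be positive")
        if "hps" in raw:
            _require(raw["hps"], ("neck_plane_z",), "hps")
            kwargs["neck_plane"] = SectionPlane(float(raw["hps"]["neck_plane_z"]))
        if "directions" in raw:
            dirs = raw["directions"]
            unknown = set(dirs) - set(SPHERE_FEATURES)
            if unknown:
                raise ConfigError(
                    f"directions: unknown features {sorted(unknown)}"
                )
            kwargs["directions"] = {
                k: tuple(float(c) for c in v) for k, v in dirs.items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ROIConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw if raw is not None else {})

    def to_dict(self) -> dict:
        out = {}
        for feature in SPHERE_FEATURES:
            pair = getattr(self, feature)
            if pair is not None:
                out[feature] = {
                    side: {"center": list(roi.center), "radius": roi.radius}
                    for side, roi in zip(("left", "right"), pair)
                }
        if self.tr_boxes is not None:
            out["torso_rotation"] = {
                side: {
                    "center": list(box.center),
                    "half_extents": list(box.half_extents),
                }
                for side, box in zip(("left", "right"), self.tr_boxes)
            }
            out["torso_rotation"]["step"] = self.tr_step
        if self.neck_plane is not None:
            out["hps"] = {"neck_plane_z": self.neck_plane.z_height}
        if self.directions:
            out["directions"] = {k: list(v) for k, v in self.directions.items()}
        return out

    def mirrored_x(self) -> "ROIConfig":
        """Reflect every ROI across the sagittal plane, swapping sides."""
        def flip_pair(pair):
            if pair is None:
                return None
            left, right = pair
            return (right.mirrored_x(), left.mirrored_x())

        return ROIConfig(
            shoulder=flip_pair(self.shoulder),
            scapula=flip_pair(self.scapula),
            hip=flip_pair(self.hip),
            tr_boxes=flip_pair(self.tr_boxes),
            tr_step=self.tr_step,
            neck_plane=self.neck_plane,
            directions=dict(self.directions),
        )

    def translated(self, offset) -> "ROIConfig":
        ox, oy, oz = (float(o) for o in offset)

        def move_sphere(roi):
            c = roi.center
            return SphericalROI(
                (c[0] + ox, c[1] + oy, c[2] + oz), roi.radius, roi.label
            )

        def move_pair(pair, mover):
            return None if pair is None else tuple(mover(r) for r in pair)

        def move_box(box):
            c = box.center
            return CuboidROI(
                (c[0] + ox, c[1] + oy, c[2] + oz), box.half_extents, box.label
            )

        return ROIConfig(
            shoulder=move_pair(self.shoulder, move_sphere),
            scapula=move_pair(self.scapula, move_sphere),
            hip=move_pair(self.hip, move_sphere),
            tr_boxes=move_pair(self.tr_boxes, move_box),
            tr_step=self.tr_step,
            neck_plane=None
            if self.neck_plane is None
            else SectionPlane(self.neck_plane.z_height + oz),
            directions=dict(self.directions),
        )

    def scaled(self, s: float) -> "ROIConfig":
        s = float(s)

        def scale_sphere(roi):
            return SphericalROI(
                tuple(c * s for c in roi.center), roi.radius * s, roi.label
            )

        def scale_box(box):
            return CuboidROI(
                tuple(c * s for c in box.center),
                tuple(h * s for h in box.half_extents),
                box.label,
            )

        def scale_pair(pair, scaler):
            return None if pair is None else tuple(scaler(r) for r in pair)

        return ROIConfig(
            shoulder=scale_pair(self.shoulder, scale_sphere),
            scapula=scale_pair(self.scapula, scale_sphere),
            hip=scale_pair(self.hip, scale_sphere),
            tr_boxes=scale_pair(self.tr_boxes, scale_box),
            tr_step=self.tr_step * s,
            neck_plane=None
            if self.neck_plane is None
            else SectionPlane(self.neck_plane.z_height * s),
            directions=dict(self.directions),
        )
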