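import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from torsometrics import (
    METRIC_KEYS,
    ROIConfig,
    SphericalROI,
    head_pelvis_shift,
    measure_all,
    paired_feature_asymmetry,
    rotation_angle,
    tilt_angle,
    torso_rotation,
)
from torsometrics.exceptions import ConfigError, UndefinedAngleError

finite = st.floats(-500, 500, allow_nan=False)


class TestAngleClosedForm:
    def test_coronal_pair_zero_rotation(self):
        assert rotation_angle((100, 0, 0), (-100, 0, 0)) == 0.0
        assert tilt_angle((100, 0, 0), (-100, 0, 0)) == 0.0

    @pytest.mark.parametrize("deg", [1.0, 10.0, 30.0, 45.0])
    def test_rotation_matches_trigonometry(self, deg):
        left = (100.0, 100.0 * math.tan(math.radians(deg)), 17.0)
        right = (0.0, 0.0, 17.0)
        assert rotation_angle(left, right) == pytest.approx(deg, abs=1e-9)

    @pytest.mark.parametrize("deg", [1.0, 10.0, 45.0 - 1e-6])
    def test_tilt_matches_trigonometry(self, deg):
        dz = math.hypot(100.0, 100.0) * math.tan(math.radians(deg))
        assert tilt_angle((100.0, 100.0, dz), (0.0, 0.0, 0.0)) == pytest.approx(
            deg, abs=1e-9
        )

    def test_mirror_negates_rotation(self):
        left, right = (100.0, 17.633, 0.0), (0.0, 0.0, 0.0)
        base = rotation_angle(left, right)
        mirrored = rotation_angle((0.0, 0.0, 0.0), (-100.0, 17.633, 0.0))
        assert mirrored == pytest.approx(-base, abs=1e-12)

    def test_vertical_pair_undefined_rotation(self):
        with pytest.raises(UndefinedAngleError):
            rotation_angle((0, 5, 0), (0, -5, 10))

    def test_vertical_pair_undefined_tilt(self):
        with pytest.raises(UndefinedAngleError):
            tilt_angle((0, 0, 0), (0, 0, 10))

    def test_yaw_shifts_rotation_linearly(self):
        """Yawing a coronal pair by phi changes rotation by exactly phi."""
        left, right = np.array([120.0, 0, 30]), np.array([-120.0, 0, 30])
        for phi in (0.5, 2.0, 5.0):
            c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
            rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            assert rotation_angle(rot @ left, rot @ right) == pytest.approx(
                phi, abs=0.01
            )


@given(
    lx=finite, ly=finite, lz=finite, rx=finite, ry=finite, rz=finite
)
def test_angle_bounds_and_swap_antisymmetry(lx, ly, lz, rx, ry, rz):
    """Angles stay in [-90, 90]; swapping the points negates both."""
    left, right = (lx, ly, lz), (rx, ry, rz)
    try:
        rot = rotation_angle(left, right)
        assert abs(rot) <= 90.0
        assert rotation_angle(right, left) == pytest.approx(rot, abs=1e-9)
        # note: swapping labels flips both signs of d, leaving atan(dy/dx)
        # unchanged -- rotation is a property of the unordered pair
    except UndefinedAngleError:
        pass
    try:
        tilt = tilt_angle(left, right)
        assert abs(tilt) <= 90.0
        assert tilt_angle(right, left) == pytest.approx(-tilt, abs=1e-9)
    except UndefinedAngleError:
        pass


class TestPairedFeature:
    def test_recovers_generator_truth(self, deformed_torso, deformed_values):
        _, truth = deformed_torso
        for key in ("ShR", "ShT", "ScR", "ScT", "HR", "HT"):
            assert deformed_values[key] == pytest.approx(
                truth.metrics[key], abs=0.5
            )

    def test_sides_must_not_be_swapped(self, symmetric_torso):
        mesh, truth = symmetric_torso
        left, right = truth.roi_config.shoulder
        with pytest.raises(ConfigError):
            paired_feature_asymmetry(mesh, right, left, "shoulder")

    def test_unknown_feature(self, symmetric_torso):
        mesh, truth = symmetric_torso
        left, right = truth.roi_config.shoulder
        with pytest.raises(ConfigError):
            paired_feature_asymmetry(mesh, left, right, "elbow")


class TestTorsoRotation:
    def test_symmetric_profile_is_flat(self, symmetric_torso):
        mesh, truth = symmetric_torso
        result = torso_rotation(mesh, *truth.roi_config.tr_boxes)
        assert abs(result.tr_deg) < 0.5

    def test_exact_ties_resolve_to_lowest_level(self):
        """On a fixture whose angle is identical at every height, the
        reported maximising level is the lowest one."""
        from test_roi import _WALL_BOXES, _walls_mesh

        result = torso_rotation(_walls_mesh(), *_WALL_BOXES)
        assert result.z_at_max == result.profile[0][0]
        # extreme tie-break picks the outermost wall edges: dx = 60 mm
        assert result.tr_deg == pytest.approx(
            math.degrees(math.atan(20.0 / 60.0)), abs=1e-9
        )

    def test_tr_is_max_abs_profile_entry(self, deformed_torso):
        mesh, truth = deformed_torso
        result = torso_rotation(mesh, *truth.roi_config.tr_boxes)
        angles = [a for _, a in result.profile]
        assert abs(result.tr_deg) == pytest.approx(max(np.abs(angles)), abs=1e-12)
        zlo, zhi = truth.roi_config.tr_boxes[0].z_range
        assert zlo <= result.z_at_max <= zhi

    def test_negative_hump_measured_symmetrically(self):
        from torsometrics import SynthParams, generate_torso

        mesh, truth = generate_torso(SynthParams(rib_hump_deg=-12.0))
        result = torso_rotation(mesh, *truth.roi_config.tr_boxes)
        assert result.tr_deg == pytest.approx(-12.0, abs=1.0)


class TestHeadPelvisShift:
    def test_shift_matches_generator(self, deformed_torso):
        mesh, truth = deformed_torso
        cfg = truth.roi_config
        res = head_pelvis_shift(mesh, cfg.neck_plane, *cfg.hip)
        assert res.shift_mm == pytest.approx(truth.metrics["HPS"], abs=1.0)
        assert res.shift_mm == pytest.approx(
            res.neck_centroid[0] - res.psis_midpoint[0], abs=1e-12
        )

    def test_mirroring_negates_shift(self, deformed_torso):
        mesh, truth = deformed_torso
        cfg = truth.roi_config
        base = head_pelvis_shift(mesh, cfg.neck_plane, *cfg.hip)
        mcfg = cfg.mirrored_x()
        mres = head_pelvis_shift(mesh.mirrored_x(), mcfg.neck_plane, *mcfg.hip)
        assert mres.shift_mm == pytest.approx(-base.shift_mm, abs=1e-9)

    def test_plane_missing_mesh(self, symmetric_torso):
        from torsometrics import SectionPlane
        from torsometrics.exceptions import NoNeckSectionError

        mesh, truth = symmetric_torso
        with pytest.raises(NoNeckSectionError):
            head_pelvis_shift(mesh, SectionPlane(-500.0), *truth.roi_config.hip)


class TestMeasureAll:
    def test_partial_config_fails_only_dependent_metrics(self, symmetric_torso):
        mesh, truth = symmetric_torso
        raw = truth.roi_config.to_dict()
        del raw["hip"]
        report = measure_all(mesh, ROIConfig.from_dict(raw))
        assert set(report.errors) == {"hip", "hps"}
        values = report.values()
        assert values["HR"] is None and values["HPS"] is None
        assert values["ShR"] is not None and values["TR"] is not None

    def test_repeat_measurement_bit_identical(self, symmetric_torso):
        mesh, truth = symmetric_torso
        a = measure_all(mesh, truth.roi_config).to_json()
        b = measure_all(mesh, truth.roi_config).to_json()
        assert a == b

    def test_empty_roi_reported_not_raised(self, symmetric_torso):
        mesh, truth = symmetric_torso
        raw = truth.roi_config.to_dict()
        raw["scapula"]["left"]["center"] = [900.0, 900.0, 900.0]
        report = measure_all(mesh, ROIConfig.from_dict(raw))
        assert "scapula" in report.errors
        assert report.values()["ScR"] is None

    def test_csv_rows_cover_all_metrics(self, symmetric_torso):
        mesh, truth = symmetric_torso
        rows = measure_all(mesh, truth.roi_config).to_csv_rows("p1")
        assert [r["metric"] for r in rows] == list(METRIC_KEYS)
        assert all(r["value"] is not None for r in rows)


class TestConfigSchema:
    def test_missing_keys_listed(self):
        with pytest.raises(ConfigError) as err:
            ROIConfig.from_dict({"shoulder": {"left": {"center": [1, 2, 3]}}})
        assert any("radius" in m for m in err.value.missing) or "right" in str(err.value)

    def test_yaml_round_trip(self, symmetric_torso, tmp_path):
        import yaml

        _, truth = symmetric_torso
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(truth.roi_config.to_dict()))
        cfg = ROIConfig.from_yaml(path)
        assert cfg.to_dict() == truth.roi_config.to_dict()
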