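"""Via-point geometry: posing, path lengths, moment arms, out-of-plane angles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ankledyn.errors import DegenerateSegmentError
from ankledyn.geometry import (
    JointConfiguration,
    joint_adjacent_points,
    joint_angles_from_segment_angles,
    moment_arm_sagittal,
    muscle_path_state,
    path_length,
    pose_path,
    sagittal_angle,
)


class TestPosePath:
    def test_reference_posture_reproduces_configured_coordinates(self, subject):
        # at the standing reference, ankle-frame points are untouched and
        # knee-frame points are shifted by the knee-origin offset
        sol = pose_path(subject.muscles["soleus"], subject, JointConfiguration())
        assert np.allclose(sol, [[-1.8, 252.0, 6.7], [-46.0, -10.4, 2.8]])
        gas = pose_path(subject.muscles["med_gas"], subject, JointConfiguration())
        assert np.allclose(gas[0], [-2.8 - 11.2, 17.0 + 386.0, -22.6])
        assert np.allclose(gas[1], [-13.0 - 11.2, 11.3 + 386.0, -24.5])
        assert np.allclose(gas[2], [-46.0, -10.4, 2.8])

    def test_full_turn_is_identity(self, subject):
        ref = pose_path(subject.muscles["tib_ant"], subject, JointConfiguration())
        turned = pose_path(
            subject.muscles["tib_ant"],
            subject,
            JointConfiguration(ankle_angle=2 * np.pi, knee_angle=2 * np.pi),
        )
        assert np.allclose(turned, ref, atol=1e-9)

    def test_quarter_turn_maps_xy(self, subject):
        posed = pose_path(
            subject.muscles["soleus"],
            subject,
            JointConfiguration(ankle_angle=np.pi / 2),
        )
        assert posed[-1] == pytest.approx([10.4, -46.0, 2.8])


class TestPathLength:
    def test_three_four_five(self):
        assert path_length([(0, 0, 0), (3, 4, 0)]) == 5.0

    def test_collinear_via_point_is_neutral(self):
        direct = path_length([(0, 0, 0), (2, 4, 6)])
        with_via = path_length([(0, 0, 0), (1, 2, 3), (2, 4, 6)])
        assert with_via == pytest.approx(direct)

    def test_soleus_reference_length_matches_euclidean_oracle(self, subject):
        coords = pose_path(subject.muscles["soleus"], subject, JointConfiguration())
        oracle = np.linalg.norm(coords[1] - coords[0])
        assert path_length(coords) == pytest.approx(oracle)
        assert path_length(coords) == pytest.approx(266.1, abs=0.1)


class TestMomentArm:
    def test_hand_examples(self):
        assert moment_arm_sagittal((0, 1), (1, 0)) == pytest.approx(1 / np.sqrt(2))
        assert moment_arm_sagittal((1, 1), (2, 2)) == pytest.approx(0.0, abs=1e-9)
        assert moment_arm_sagittal((-5, 10), (-5, -10)) == pytest.approx(5.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            moment_arm_sagittal((1, 2), (1, 2))

    def test_as_printed_variant_uses_semiperimeter(self):
        # for joint (0,0), p1 (0,1), p2 (1,0): S = 1/2, sides 1, 1, sqrt(2)
        p = (2 + np.sqrt(2)) / 2
        assert moment_arm_sagittal((0, 1), (1, 0), as_printed=True) == pytest.approx(1.0 / p)

    def test_against_brute_force_point_to_line_oracle(self):
        """h equals the minimised distance from the joint to the supporting line."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            p1, p2, jc = rng.uniform(-100, 100, (3, 2))
            if np.allclose(p1, p2):
                continue
            d = p2 - p1

            def dist(t):
                return float(np.linalg.norm(p1 + t * d - jc))

            res = minimize_scalar(dist, bounds=(-50, 50), method="bounded",
                                  options={"xatol": 1e-12})
            h = moment_arm_sagittal(p1, p2, jc)
            assert abs(h - res.fun) < 1e-6

    def test_isometry_invariance(self, subject):
        """In-plane rigid motions leave the moment arm unchanged; any rigid
        rotation leaves the path length unchanged."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p1, p2, jc = rng.uniform(-50, 50, (3, 2))
            if np.allclose(p1, p2):
                continue
            ang = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(-20, 20, 2)
            rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
            h0 = moment_arm_sagittal(p1, p2, jc)
            h1 = moment_arm_sagittal(rot @ p1 + shift, rot @ p2 + shift, rot @ jc + shift)
            assert h1 == pytest.approx(h0, abs=1e-9)

            pts = rng.uniform(-50, 50, (4, 3))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            theta = rng.uniform(0, 2 * np.pi)
            k = np.array([
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ])
            rot3 = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
            assert path_length(pts @ rot3.T) == pytest.approx(path_length(pts), rel=1e-9)


class TestSagittalAngle:
    def test_in_plane_segment(self):
        assert sagittal_angle((0, 0, 0), (5, 3, 0)) == 0.0

    def test_plane_normal_segment(self):
        assert sagittal_angle((0, 0, 0), (0, 0, 10)) == pytest.approx(np.pi / 2)

    def test_three_four_five_out_of_plane(self):
        assert sagittal_angle((0, 0, 0), (3, 0, 4)) == pytest.approx(np.arcsin(0.8))

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateSegmentError):
            sagittal_angle((1, 1, 1), (1, 1, 1))


def test_segment_to_joint_angle_mapping():
    # upright standing (all segments vertical) is the zero-deviation reference
    ankle, knee = joint_angles_from_segment_angles(np.pi / 2, np.pi / 2)
    assert ankle == 0.0 and knee == 0.0
    # a forward shank lean dorsiflexes the ankle (positive deviation)
    ankle, _ = joint_angles_from_segment_angles(np.radians(80), np.pi / 2)
    assert ankle == pytest.approx(np.radians(10))


def test_virtual_work_consistency(subject):
    """d(l_mt)/d(ankle angle) matches the sagittal moment arm within 5 %.

    Rotating the foot-borne points changes the path length at a rate equal
    to the perpendicular distance from the joint centre to the crossing
    segment (virtual work), up to the small out-of-plane component.
    """
    eps = 1e-5
    for name, muscle in subject.muscles.items():
        for ang in np.linspace(-0.25, 0.25, 6):
            lo = path_length(pose_path(muscle, subject, JointConfiguration(ankle_angle=ang - eps)))
            hi = path_length(pose_path(muscle, subject, JointConfiguration(ankle_angle=ang + eps)))
            deriv = abs(hi - lo) / (2 * eps)
            state = muscle_path_state(muscle, subject, JointConfiguration(ankle_angle=ang))
            assert deriv == pytest.approx(state.moment_arm, rel=0.05), name


def test_joint_adjacent_point_selection(subject):
    # last shank/thigh-borne point and first foot-borne point
    gas = subject.muscles["med_gas"]
    coords = pose_path(gas, subject, JointConfiguration())
    p1, p2 = joint_adjacent_points(gas, coords)
    assert np.allclose(p1, coords[1])
    assert np.allclose(p2, coords[2])
    ext = subject.muscles["ext_dig"]
    coords = pose_path(ext, subject, JointConfiguration())
    p1, p2 = joint_adjacent_points(ext, coords)
    assert np.allclose(p1, coords[1])
    assert np.allclose(p2, coords[2])
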