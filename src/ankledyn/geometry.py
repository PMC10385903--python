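"""Musculoskeletal geometry: via-point paths, moment arms, out-of-plane angles.

Each muscle-tendon unit is a 3-D polyline of attachment and via points.
Coordinates are defined at the quiet-standing reference posture, in either
the ankle or the knee joint frame (X anterior, Y proximal, Z lateral); the
knee frame is mapped into the ankle frame by the standing-posture offset of
the knee origin.  Sagittal motion is modelled as rotations about the joint
Z axes: foot-borne points rotate about the ankle centre by the ankle-angle
deviation from reference, thigh-borne points rotate about the knee centre
by the knee-angle deviation, and shank-borne points are fixed in the ankle
frame.

The sagittal moment arm h about the ankle is the perpendicular distance
from the joint centre to the line through the two path points adjacent to
the joint crossing, projected onto the sagittal (XY) plane.  It is computed
via Heron's formula: with triangle sides a, b (joint to each point) and c
(point to point), semiperimeter p and area S, the distance to the line
supporting side c is h = 2S/c.  The geometry formula is also available in
an "as-printed" variant h = 2S/p for reproduction studies.

phi_m, the out-of-sagittal angle of the joint-crossing segment, is
arcsin(|dz| / segment length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSegmentError, InvalidModelError
from .subject import MuscleParameters, SubjectModel

__all__ = [
    "JointConfiguration",
    "MusclePathState",
    "pose_path",
    "path_length",
    "moment_arm_sagittal",
    "sagittal_angle",
    "joint_adjacent_points",
    "muscle_path_state",
    "joint_angles_from_segment_angles",
]


@dataclass(frozen=True)
class JointConfiguration:
    """Sagittal joint angles, as deviations-from-standing carriers.

    ankle_angle / knee_angle are the current angles; the reference angles
    correspond to the standing posture in which the path coordinates are
    defined.  Positive ankle deviation rotates the foot counterclockwise
    about +Z (dorsiflexion with X anterior, Y proximal).
    """

    ankle_angle: float = 0.0
    knee_angle: float = 0.0
    reference_ankle_angle: float = 0.0
    reference_knee_angle: float = 0.0


@dataclass(frozen=True)
class MusclePathState:
    """Posed geometry of one muscle at one instant (ankle frame, mm)."""

    muscle: str
    point_coords: np.ndarray  # (n_points, 3)
    total_length: float  # mm
    moment_arm: float  # mm
    sagittal_angle: float  # rad


def _rot_z(points: np.ndarray, angle: float, center: np.ndarray) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    rel = points - center
    out = rel.copy()
    out[:, 0] = c * rel[:, 0] - s * rel[:, 1]
    out[:, 1] = s * rel[:, 0] + c * rel[:, 1]
    return out + center


def joint_angles_from_segment_angles(
    shank_angle: np.ndarray | float, thigh_angle: np.ndarray | float
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Map sagittal segment elevation angles to joint deviations.

    Segment angles are measured counterclockwise from the horizontal X axis
    to the segment axis; upright standing has both at pi/2, which is the
    zero-deviation reference posture.  With the foot flat on the ground, a
    forward shank lean (shank angle below pi/2) dorsiflexes the ankle, so
    the foot's rotation relative to the shank frame is pi/2 - shank_angle.
    The knee deviation is the change of the thigh's orientation relative to
    the shank, (thigh_angle - shank_angle) - 0.
    """
    ankle = np.pi / 2 - np.asarray(shank_angle, dtype=float)
    knee = np.asarray(thigh_angle, dtype=float) - np.asarray(shank_angle, dtype=float)
    return ankle[()], knee[()]


def pose_path(
    muscle: MuscleParameters,
    subject: SubjectModel,
    config: JointConfiguration,
) -> np.ndarray:
    """Pose a muscle's path points in the ankle frame at a joint configuration.

    Knee-frame points are first translated by the standing knee-origin
    offset; thigh-borne points then rotate about the knee centre by the
    knee deviation and foot-borne points rotate about the ankle centre by
    the ankle deviation.  Shank-borne points are unchanged.
    """
    knee_center = np.asarray(subject.knee_origin_in_ankle_frame, dtype=float)
    pts = []
    for p in muscle.path:
        xyz = np.asarray(p.coords, dtype=float)
        if p.frame == "knee":
            xyz = xyz + knee_center
        elif p.frame != "ankle":
            raise InvalidModelError(f"unknown frame {p.frame!r}")
        pts.append(xyz)
    coords = np.array(pts)

    d_knee = config.knee_angle - config.reference_knee_angle
    d_ankle = config.ankle_angle - config.reference_ankle_angle
    segments = [p.segment for p in muscle.path]
    thigh_idx = [i for i, s in enumerate(segments) if s == "thigh"]
    foot_idx = [i for i, s in enumerate(segments) if s == "foot"]
    if any(s not in ("foot", "shank", "thigh") for s in segments):
        raise InvalidModelError("unknown segment label in muscle path")
    if thigh_idx and d_knee != 0.0:
        coords[thigh_idx] = _rot_z(coords[thigh_idx], d_knee, knee_center)
    if foot_idx and d_ankle != 0.0:
        coords[foot_idx] = _rot_z(
            coords[foot_idx], d_ankle, np.zeros(3)
        )
    return coords


def path_length(point_coords: np.ndarray) -> float:
    """Total 3-D polyline length in mm (sum of consecutive point distances)."""
    coords = np.asarray(point_coords, dtype=float)
    if coords.shape[0] < 2:
        raise DegenerateSegmentError("path needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(coords, axis=0), axis=1)))


def moment_arm_sagittal(
    p1: tuple[float, float] | np.ndarray,
    p2: tuple[float, float] | np.ndarray,
    joint_center: tuple[float, float] | np.ndarray = (0.0, 0.0),
    as_printed: bool = False,
) -> float:
    """Sagittal-plane moment arm via Heron's formula.

    p1, p2 are the sagittal projections of the two path points adjacent to
    the joint crossing.  The default returns the perpendicular distance
    from the joint centre to the line through them, h = 2S/c.  With
    ``as_printed=True`` the variant h = 2S/p (p the semiperimeter) is
    returned instead.
    """
    p1 = np.asarray(p1, dtype=float)[:2]
    p2 = np.asarray(p2, dtype=float)[:2]
    jc = np.asarray(joint_center, dtype=float)[:2]
    a = float(np.hypot(*(p1 - jc)))
    b = float(np.hypot(*(p2 - jc)))
    c = float(np.hypot(*(p2 - p1)))
    if c == 0.0:
        raise DegenerateSegmentError("coincident attachment points")
    p = (a + b + c) / 2.0
    s_sq = p * (p - a) * (p - b) * (p - c)
    s = math.sqrt(max(s_sq, 0.0))
    return 2.0 * s / p if as_printed else 2.0 * s / c


def sagittal_angle(
    p1: tuple[float, float, float] | np.ndarray,
    p2: tuple[float, float, float] | np.ndarray,
) -> float:
    """Angle between the segment p1->p2 and the sagittal (XY) plane, rad."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    norm = float(np.linalg.norm(d))
    if norm == 0.0:
        raise DegenerateSegmentError("coincident points")
    return float(np.arcsin(abs(d[2]) / norm))


def joint_adjacent_points(
    muscle: MuscleParameters, point_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """The two posed path points straddling the ankle joint.

    Taken as the last point borne by the shank (or thigh) and the first
    borne by the foot.
    """
    segments = [p.segment for p in muscle.path]
    foot_first = next(
        (i for i, s in enumerate(segments) if s == "foot"), None
    )
    if foot_first is None or foot_first == 0:
        raise InvalidModelError(
            f"{muscle.name}: path must cross from shank/thigh to foot"
        )
    return point_coords[foot_first - 1], point_coords[foot_first]


def muscle_path_state(
    muscle: MuscleParameters,
    subject: SubjectModel,
    config: JointConfiguration,
    as_printed: bool = False,
) -> MusclePathState:
    """Pose one muscle and evaluate its length, moment arm and phi_m."""
    coords = pose_path(muscle, subject, config)
    p1, p2 = joint_adjacent_points(muscle, coords)
    return MusclePathState(
        muscle=muscle.name,
        point_coords=coords,
        total_length=path_length(coords),
        moment_arm=moment_arm_sagittal(p1, p2, as_printed=as_printed),
        sagittal_angle=sagittal_angle(p1, p2),
    )


def muscle_geometry_series(
    subject: SubjectModel,
    ankle_angles: np.ndarray,
    knee_angles: np.ndarray,
) -> dict[str, dict[str, np.ndarray]]:
    """Path length, moment arm and phi_m for every muscle over a trajectory.

    ankle_angles / knee_angles are joint deviations from the standing
    reference (rad).  Returns per muscle arrays keyed ``l_mt``, ``h``,
    ``phi``.
    """
    ankle_angles = np.atleast_1d(np.asarray(ankle_angles, dtype=float))
    knee_angles = np.atleast_1d(np.asarray(knee_angles, dtype=float))
    if ankle_angles.shape != knee_angles.shape:
        raise InvalidModelError("angle series must have equal length")
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, muscle in subject.muscles.items():
        n = ankle_angles.size
        l_mt = np.empty(n)
        h = np.empty(n)
        phi = np.empty(n)
        for i in range(n):
            state = muscle_path_state(
                muscle,
                subject,
                JointConfiguration(
                    ankle_angle=float(ankle_angles[i]),
                    knee_angle=float(knee_angles[i]),
                ),
            )
            l_mt[i] = state.total_length
            h[i] = state.moment_arm
            phi[i] = state.sagittal_angle
        out[name] = {"l_mt": l_mt, "h": h, "phi": phi}
    return out
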