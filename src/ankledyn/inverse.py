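"""Four-segment inverse-dynamics estimate of the ankle moment.

The body is modelled as foot, shank, thigh and HAT links in the sagittal
plane.  While the subject is still seated, part of the thigh and HAT weight
rests on the chair; the vertical chair reaction force F_chair partitions
the load through the fractions

    n = F_chair / G            (thigh fraction carried by the chair)
    q = (F_chair - n m2 g) / (m3 g)   (HAT fraction carried by the chair)

with G the weight of body plus carried load, both fractions clamped to
[0, 1] (after seat-off F_chair = 0 and both vanish).  The ankle moment is
the eight-term rigid-link expression in the segment elevation angles t_i,
angular velocities w_i and accelerations a_i (i = 1 shank, 2 thigh, 3 HAT):

    M = (1-n) m2 g (l1 cos t1 - k2 l2 cos t2)
      + (1-q) m3 g (l1 cos t1 - l2 cos t2 + k3 l3 cos t3)
      + a1 [l1^2 (m1 k1^2 + m2 + m3) + J1]
      + a2 l1 l2 (m2 k2 + m3) cos(t1 + t2)
      + a3 m3 k3 l1 l3 cos(t1 - t3)
      + k1 l1 m1 g cos t1
      - w2^2 (m2 k2 + m3) l1 l2 sin(t1 + t2)
      + w3^2 m3 k3 l1 l3 sin(t1 - t3)

The 10-kg waist load is carried above the hip, so it is added to the HAT
mass m3 and to G.  In upright static stance (all angles pi/2, zero rates,
zero chair force) every term vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .subject import GRAVITY, SubjectModel
from .timeseries import KinematicState, MomentSeries, resample_to

__all__ = [
    "LoadShare",
    "load_share",
    "inverse_moment_terms",
    "inverse_ankle_moment",
    "resample_to",
]


@dataclass(frozen=True)
class LoadShare:
    """Chair load-sharing fractions, clamped to [0, 1]."""

    n: np.ndarray  # thigh-on-chair fraction
    q: np.ndarray  # HAT-on-chair fraction


def load_share(
    f_chair: np.ndarray | float, subject: SubjectModel
) -> LoadShare:
    """Partition the chair reaction into thigh and HAT support fractions."""
    f_chair = np.asarray(f_chair, dtype=float)
    if np.any(f_chair < 0):
        raise InvalidParameterError("chair force must be >= 0")
    g_total = subject.total_weight
    m2 = subject.segments["thigh"].mass
    m3 = subject.hat_mass()
    n = np.clip(f_chair / g_total, 0.0, 1.0)
    q = np.clip((f_chair - n * m2 * GRAVITY) / (m3 * GRAVITY), 0.0, 1.0)
    return LoadShare(n=n[()], q=q[()])


def _model_params(subject: SubjectModel):
    shank = subject.segments["shank"]
    thigh = subject.segments["thigh"]
    hat = subject.segments["HAT"]
    return (
        shank.length, thigh.length, hat.length,
        shank.com_factor, thigh.com_factor, hat.com_factor,
        shank.mass, thigh.mass, subject.hat_mass(),
        shank.inertia,
    )


def inverse_moment_terms(
    state: KinematicState, subject: SubjectModel
) -> dict[str, np.ndarray]:
    """The eight additive terms of the moment expression, each in N·m."""
    t1, w1, a1 = state.segment("shank")
    t2, w2, a2 = state.segment("thigh")
    t3, w3, a3 = state.segment("hat")
    l1, l2, l3, k1, k2, k3, m1, m2, m3, j1 = _model_params(subject)
    g = GRAVITY
    share = load_share(state.chair_force, subject)
    n, q = share.n, share.q

    return {
        "thigh_gravity": (1 - n) * m2 * g * (l1 * np.cos(t1) - k2 * l2 * np.cos(t2)),
        "hat_gravity": (1 - q) * m3 * g
        * (l1 * np.cos(t1) - l2 * np.cos(t2) + k3 * l3 * np.cos(t3)),
        "shank_inertial": a1 * (l1**2 * (m1 * k1**2 + m2 + m3) + j1),
        "thigh_inertial": a2 * l1 * l2 * (m2 * k2 + m3) * np.cos(t1 + t2),
        "hat_inertial": a3 * m3 * k3 * l1 * l3 * np.cos(t1 - t3),
        "shank_gravity": k1 * l1 * m1 * g * np.cos(t1),
        "thigh_centripetal": -(w2**2) * (m2 * k2 + m3) * l1 * l2 * np.sin(t1 + t2),
        "hat_centripetal": (w3**2) * m3 * k3 * l1 * l3 * np.sin(t1 - t3),
    }


def inverse_ankle_moment(
    state: KinematicState, subject: SubjectModel
) -> MomentSeries:
    """Evaluate the four-segment ankle moment at every 100-Hz sample."""
    t1, w1, a1 = state.segment("shank")
    t2, w2, a2 = state.segment("thigh")
    t3, w3, a3 = state.segment("hat")
    l1, l2, l3, k1, k2, k3, m1, m2, m3, j1 = _model_params(subject)
    g = GRAVITY
    share = load_share(state.chair_force, subject)
    n, q = share.n, share.q

    m = (
        (1 - n) * m2 * g * (l1 * np.cos(t1) - k2 * l2 * np.cos(t2))
        + (1 - q) * m3 * g * (l1 * np.cos(t1) - l2 * np.cos(t2) + k3 * l3 * np.cos(t3))
        + a1 * (l1**2 * (m1 * k1**2 + m2 + m3) + j1)
        + a2 * l1 * l2 * (m2 * k2 + m3) * np.cos(t1 + t2)
        + a3 * m3 * k3 * l1 * l3 * np.cos(t1 - t3)
        + k1 * l1 * m1 * g * np.cos(t1)
        - (w2**2) * (m2 * k2 + m3) * l1 * l2 * np.sin(t1 + t2)
        + (w3**2) * m3 * k3 * l1 * l3 * np.sin(t1 - t3)
    )
    return MomentSeries(times=state.times, values=m, source="inverse")


def rates_from_angles(
    times: np.ndarray, angles: np.ndarray, smooth_points: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference fallback when only angles are recorded.

    Central differences after a moving-average smooth (default 5 points).
    The wearable inertial units report angular velocity and acceleration
    directly, so this is only for angle-only logs.
    """
    angles = np.asarray(angles, dtype=float)
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        padded = np.pad(angles, ((pad, pad), (0, 0)), mode="edge")
        angles = np.apply_along_axis(
            lambda col: np.convolve(col, kernel, mode="valid"), 0, padded
        )
    dt = float(np.mean(np.diff(times)))
    vel = np.gradient(angles, dt, axis=0)
    acc = np.gradient(vel, dt, axis=0)
    return vel, acc
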