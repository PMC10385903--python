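"""sEMG-driven (forward-dynamics) ankle moment assembly.

At each activation window centre the muscle paths are posed from the joint
kinematics, fiber states follow from the rigid-tendon reduction, the Hill
model gives each muscle's tendon force, projection by cos(phi_m) gives the
sagittal force F_S, and the moment arms h close the sum

    M = F_S,tib * h_tib + F_S,ext * h_ext - F_S,med * h_med - F_S,sol * h_sol

with dorsiflexion positive (tibialis anterior and extensor digitorum are
dorsiflexors; medial gastrocnemius and soleus are plantarflexors).

Because the tendon is rigid, fiber length and velocity depend only on the
kinematics, so the moment is affine in the activation vector:
M(t) = sum_i s_i * (a_i(t) * A_i(t) + P_i(t)), where A_i is the activation
gain (f_active * f_velocity * F_m0 * cos(theta_m) * cos(phi_m) * h) and P_i
the passive contribution.  The synthetic generator exploits this linearity
to invert the model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hill
from .emg import ActivationSeries
from .errors import AlignmentError, InvalidParameterError
from .geometry import joint_angles_from_segment_angles, muscle_geometry_series
from .subject import MUSCLE_NAMES, SubjectModel
from .timeseries import KinematicState, MomentSeries

__all__ = [
    "MUSCLE_SIGNS",
    "moment_from_force",
    "linear_moment_gains",
    "forward_ankle_moment",
]

# Eq.-(10) signs: dorsiflexors positive, plantarflexors negative.
MUSCLE_SIGNS = {"tib_ant": 1.0, "ext_dig": 1.0, "med_gas": -1.0, "soleus": -1.0}


def moment_from_force(force_n: float, arm_mm: float) -> float:
    """Convert a force [N] times a millimetre moment arm to N·m."""
    return force_n * arm_mm / 1000.0


@dataclass(frozen=True)
class MomentGains:
    """Per-muscle affine decomposition of the forward moment.

    For muscle i at window t: signed moment contribution =
    sign_i * (a_i * active_gain_i + passive_moment_i), both in N·m.
    Geometry terms (h in mm, phi, fiber state) are kept for diagnostics.
    """

    times: np.ndarray
    active_gain: dict[str, np.ndarray]  # N·m per unit activation
    passive_moment: dict[str, np.ndarray]  # N·m
    arm_mm: dict[str, np.ndarray]
    phi: dict[str, np.ndarray]
    fiber_length: dict[str, np.ndarray]
    fiber_velocity: dict[str, np.ndarray]
    pennation: dict[str, np.ndarray]

    def moment(self, activations: dict[str, np.ndarray]) -> np.ndarray:
        total = np.zeros_like(self.times)
        for name in MUSCLE_NAMES:
            total += MUSCLE_SIGNS[name] * (
                activations[name] * self.active_gain[name]
                + self.passive_moment[name]
            )
        return total

    def sagittal_force(
        self, name: str, activation: np.ndarray
    ) -> np.ndarray:
        """F_S of one muscle for a given activation series [N]."""
        contrib = activation * self.active_gain[name] + self.passive_moment[name]
        return contrib / (self.arm_mm[name] / 1000.0)


def linear_moment_gains(
    subject: SubjectModel,
    times: np.ndarray,
    shank_angles: np.ndarray,
    thigh_angles: np.ndarray,
    curves: hill.CurveCoefficients = hill.DEFAULT_CURVES,
) -> MomentGains:
    """Evaluate the kinematics-only part of the forward model on a time grid."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise InvalidParameterError("need at least two time samples")
    dt = float(np.mean(np.diff(times)))
    ankle, knee = joint_angles_from_segment_angles(shank_angles, thigh_angles)
    geo = muscle_geometry_series(subject, ankle, knee)

    active_gain, passive_moment = {}, {}
    arm, phi, flen, fvel, penn = {}, {}, {}, {}, {}
    for name in MUSCLE_NAMES:
        muscle = subject.muscles[name]
        l_mt, h_mm, phi_m = geo[name]["l_mt"], geo[name]["h"], geo[name]["phi"]
        l_m, v_m, theta_m = hill.fiber_state_series(l_mt, dt, muscle)
        l_ratio = l_m / muscle.optimal_fiber_length
        v_ratio = v_m / (hill.VMAX_PER_LM0 * muscle.optimal_fiber_length)
        geom_gain = np.cos(theta_m) * np.cos(phi_m) * h_mm / 1000.0
        active_gain[name] = (
            hill.f_active(l_ratio, curves)
            * hill.f_velocity(v_ratio, curves)
            * muscle.peak_force
            * geom_gain
        )
        passive_moment[name] = (
            hill.f_passive(l_ratio, curves) * muscle.peak_force * geom_gain
        )
        arm[name], phi[name] = h_mm, phi_m
        flen[name], fvel[name], penn[name] = l_m, v_m, theta_m
    return MomentGains(
        times=times,
        active_gain=active_gain,
        passive_moment=passive_moment,
        arm_mm=arm,
        phi=phi,
        fiber_length=flen,
        fiber_velocity=fvel,
        pennation=penn,
    )


def _interp_kinematics(
    kinematics: KinematicState, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if times.min() < kinematics.times.min() - 1e-9 or times.max() > kinematics.times.max() + 1e-9:
        raise AlignmentError(
            "activation windows extend beyond the kinematic record"
        )
    shank = np.interp(times, kinematics.times, kinematics.angles[:, 0])
    thigh = np.interp(times, kinematics.times, kinematics.angles[:, 1])
    return shank, thigh


def forward_ankle_moment(
    activations: dict[str, ActivationSeries],
    kinematics: KinematicState,
    subject: SubjectModel,
    curves: hill.CurveCoefficients = hill.DEFAULT_CURVES,
    return_detail: bool = False,
) -> MomentSeries | tuple[MomentSeries, pd.DataFrame]:
    """Assemble the sEMG-driven ankle moment on the activation window grid.

    The 100-Hz kinematics are linearly interpolated to the 20-Hz window
    centres.  With ``return_detail=True`` a tidy per-muscle DataFrame
    (activation, F_S, h, phi, fiber state) is returned alongside.
    """
    missing = [m for m in MUSCLE_NAMES if m not in activations]
    if missing:
        raise InvalidParameterError(f"missing muscle channels: {missing}")
    times = activations[MUSCLE_NAMES[0]].times
    for name in MUSCLE_NAMES[1:]:
        if not np.allclose(activations[name].times, times):
            raise AlignmentError("activation series must share one time grid")

    shank, thigh = _interp_kinematics(kinematics, times)
    gains = linear_moment_gains(subject, times, shank, thigh, curves)
    act = {name: activations[name].values for name in MUSCLE_NAMES}
    series = MomentSeries(times=times, values=gains.moment(act), source="forward")
    if not return_detail:
        return series
    rows = []
    for name in MUSCLE_NAMES:
        f_s = gains.sagittal_force(name, act[name])
        rows.append(
            pd.DataFrame(
                {
                    "time_s": times,
                    "muscle": name,
                    "a": act[name],
                    "F_S_N": f_s,
                    "h_mm": gains.arm_mm[name],
                    "phi_rad": gains.phi[name],
                    "l_m_mm": gains.fiber_length[name],
                    "v_m_mm_s": gains.fiber_velocity[name],
                    "theta_m_rad": gains.pennation[name],
                }
            )
        )
    return series, pd.concat(rows, ignore_index=True)
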