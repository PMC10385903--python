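"""Hill muscle-tendon model with a rigid series tendon.

The contractile machinery is described by three fitted dimensionless curves:

* active force-length, a sum of five Gaussians of the normalised fiber
  length l_m / l_m0;
* passive force-length, a single exponential 2.342e-6 * exp(8.085 * l_m/l_m0);
* force-velocity, a sum of seven Gaussians of the normalised fiber velocity
  v_m / v_max with v_max = 10 * l_m0 per second (lengthening positive).

The fiber runs at a pennation angle theta_m to the tendon line of action,
with the constant-thickness constraint l_m * sin(theta_m) = l_m0 * sin(theta_0).
The series tendon is treated as rigid at its slack length l_t, so the fiber
length follows directly from the whole muscle-tendon path length l_mt:

    l_m = sqrt( (l_mt - l_t)^2 + (l_m0 sin theta_0)^2 )

The tendon (= muscle output) force is

    F_T = ( a * f_active(l_m) * f_velocity(v_m) + f_passive(l_m) ) * F_m0 * cos(theta_m)

and its component in the sagittal plane is F_S = F_T * cos(phi_m), where
phi_m is the out-of-plane angle of the joint-crossing segment.

Curve coefficients live in this module's constants and can be overridden by
constructing a custom :class:`CurveCoefficients` for sensitivity studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError, InvalidParameterError
from .subject import MuscleParameters

__all__ = [
    "CurveCoefficients",
    "DEFAULT_CURVES",
    "MuscleState",
    "f_active",
    "f_passive",
    "f_velocity",
    "pennation",
    "fiber_length",
    "fiber_state_series",
    "tendon_force",
    "sagittal_force",
    "VMAX_PER_LM0",
]

# v_max equals 10 optimal fiber lengths per second
VMAX_PER_LM0 = 10.0

_ACTIVE_B = (10.39, -9.785, 0.8545, 0.3125, 0.3284)
_ACTIVE_C = (0.8466, 0.8481, 1.117, 0.6376, 1.479)
_ACTIVE_D = (0.1576, 0.1546, 0.2614, 0.1108, 0.1976)

_PASSIVE_SCALE = 2.342e-6
_PASSIVE_EXPONENT = 8.085

_VEL_E = (1.283, -21.66, -6.873, 0.8195, -0.6551, 0.08876, 26.84)
_VEL_F = (1.242, 0.2219, 0.3008, 0.3125, 0.1152, 1.36, 0.2371)
_VEL_H = (0.801, 0.1248, 0.1208, 0.6103, 0.08606, 1.36, 0.1361)


@dataclass(frozen=True)
class CurveCoefficients:
    """Coefficients of the three fitted Hill curves."""

    active_b: tuple[float, ...] = _ACTIVE_B
    active_c: tuple[float, ...] = _ACTIVE_C
    active_d: tuple[float, ...] = _ACTIVE_D
    passive_scale: float = _PASSIVE_SCALE
    passive_exponent: float = _PASSIVE_EXPONENT
    vel_e: tuple[float, ...] = _VEL_E
    vel_f: tuple[float, ...] = _VEL_F
    vel_h: tuple[float, ...] = _VEL_H

    def __post_init__(self) -> None:
        if any(d == 0 for d in self.active_d) or any(h == 0 for h in self.vel_h):
            raise InvalidParameterError("Gaussian widths must be non-zero")


DEFAULT_CURVES = CurveCoefficients()


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous state of one muscle-tendon unit."""

    fiber_length: float  # mm
    fiber_velocity: float  # mm/s, lengthening positive
    pennation: float  # rad
    tendon_force: float  # N
    sagittal_force: float  # N


def f_active(
    l_ratio: np.ndarray | float, curves: CurveCoefficients = DEFAULT_CURVES
) -> np.ndarray | float:
    """Active force-length curve at normalised fiber length l_m/l_m0.

    The Gaussian fit can dip below zero far from the optimum; values are
    clamped at 0 because the contractile element cannot push.
    """
    l_ratio = np.asarray(l_ratio, dtype=float)
    if np.any(l_ratio <= 0):
        raise InvalidParameterError("l_ratio must be > 0")
    total = sum(
        b * np.exp(-(((l_ratio - c) / d) ** 2))
        for b, c, d in zip(curves.active_b, curves.active_c, curves.active_d)
    )
    return np.maximum(total, 0.0)[()]


def f_passive(
    l_ratio: np.ndarray | float, curves: CurveCoefficients = DEFAULT_CURVES
) -> np.ndarray | float:
    """Passive force-length curve: a strictly increasing exponential."""
    l_ratio = np.asarray(l_ratio, dtype=float)
    if np.any(l_ratio < 0):
        raise InvalidParameterError("l_ratio must be >= 0")
    return (curves.passive_scale * np.exp(curves.passive_exponent * l_ratio))[()]


def f_velocity(
    v_ratio: np.ndarray | float, curves: CurveCoefficients = DEFAULT_CURVES
) -> np.ndarray | float:
    """Force-velocity curve at normalised fiber velocity v_m/v_max.

    Shortening is negative, lengthening positive; eccentric force exceeds
    isometric on the fitted curve.  Clamped at 0.
    """
    v_ratio = np.asarray(v_ratio, dtype=float)
    total = sum(
        e * np.exp(-(((v_ratio - f) / h) ** 2))
        for e, f, h in zip(curves.vel_e, curves.vel_f, curves.vel_h)
    )
    return np.maximum(total, 0.0)[()]


def pennation(
    l_m: np.ndarray | float, l_m0: float, theta0: float
) -> np.ndarray | float:
    """Pennation angle from the constant-thickness constraint.

    theta_m = arcsin(l_m0 sin(theta_0) / l_m).  If the fiber is reported
    shorter than the muscle's constant thickness the argument exceeds 1;
    the angle is clamped to pi/2 with a warning.
    """
    l_m = np.asarray(l_m, dtype=float)
    if np.any(l_m <= 0):
        raise InvalidParameterError("fiber length must be > 0")
    arg = l_m0 * np.sin(theta0) / l_m
    if np.any(arg > 1):
        warnings.warn(
            "fiber shorter than muscle thickness; pennation clamped to pi/2",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.arcsin(np.clip(arg, -1.0, 1.0))[()]


def fiber_length(
    l_mt: np.ndarray | float, muscle: MuscleParameters
) -> np.ndarray | float:
    """Fiber length from path length under the rigid-tendon reduction."""
    l_mt = np.asarray(l_mt, dtype=float)
    if np.any(l_mt <= muscle.tendon_length):
        bad = int(np.argmax(l_mt <= muscle.tendon_length))
        raise InvalidGeometryError(
            f"{muscle.name}: path length <= tendon slack length at index {bad}"
        )
    w = muscle.optimal_fiber_length * np.sin(muscle.pennation_at_optimum)
    return np.sqrt((l_mt - muscle.tendon_length) ** 2 + w**2)[()]


def fiber_state_series(
    l_mt: np.ndarray, dt: float, muscle: MuscleParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fiber length, velocity and pennation along a sampled path-length series.

    Velocity uses central differences in the interior and one-sided
    differences at the ends.
    """
    l_m = np.atleast_1d(fiber_length(l_mt, muscle))
    v_m = np.gradient(l_m, dt) if l_m.size > 1 else np.zeros_like(l_m)
    theta_m = pennation(
        l_m, muscle.optimal_fiber_length, muscle.pennation_at_optimum
    )
    return l_m, v_m, np.atleast_1d(theta_m)


def tendon_force(
    a: np.ndarray | float,
    l_m: np.ndarray | float,
    v_m: np.ndarray | float,
    theta_m: np.ndarray | float,
    muscle: MuscleParameters,
    curves: CurveCoefficients = DEFAULT_CURVES,
) -> np.ndarray | float:
    """Muscle output (= tendon) force in newtons.

    F_T = (a f_active f_velocity + f_passive) F_m0 cos(theta_m), never
    negative.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise InvalidParameterError("activation must lie in [0, 1]")
    l_ratio = np.asarray(l_m, dtype=float) / muscle.optimal_fiber_length
    v_ratio = np.asarray(v_m, dtype=float) / (
        VMAX_PER_LM0 * muscle.optimal_fiber_length
    )
    ft = (
        a * f_active(l_ratio, curves) * f_velocity(v_ratio, curves)
        + f_passive(l_ratio, curves)
    ) * muscle.peak_force * np.cos(theta_m)
    return np.maximum(ft, 0.0)[()]


def sagittal_force(
    f_t: np.ndarray | float, phi_m: np.ndarray | float
) -> np.ndarray | float:
    """Project the tendon force onto the sagittal plane: F_S = F_T cos(phi_m)."""
    f_t = np.asarray(f_t, dtype=float)
    if np.any(f_t < 0):
        raise InvalidParameterError("tendon force must be >= 0")
    return (f_t * np.cos(phi_m))[()]
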