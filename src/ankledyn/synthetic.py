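"""Synthetic sit-to-stand trials with mutually consistent sensor streams.

The study's human sensor logs are not publicly available, so this module
generates complete trials in which the three streams — 100-Hz segment
kinematics, 100-Hz chair force, and 1000-Hz four-channel sEMG — are
dynamically consistent by construction: the ground-truth ankle moment is
computed from the kinematics with the four-segment inverse model, and the
sEMG envelopes are chosen so that the Hill-model forward path reproduces
that same moment.

Trajectories are minimum-jerk profiles s(u) = 10u^3 - 15u^4 + 6u^5 per
segment with staggered onsets (HAT first, then thigh, then shank), matching
the observed ordering in which the hip moves sharply before the knee and
ankle.  The chair force decays smoothly from its seated value to zero at
seat-off.

Muscle redundancy is resolved by an agonist/antagonist rule: the group
opposing the demanded moment sign holds a small co-activation floor, and
the residual moment (after passive and antagonist contributions) is shared
among agonists in proportion to each muscle's instantaneous
moment-generating capacity — which, because the rigid-tendon forward model
is affine in activation, amounts to an exact linear inversion with equal
activation increments across the agonist group.

Raw sEMG is amplitude-modulated band-limited Gaussian noise whose
instantaneous standard deviation is a(t) * RMS_MVC: sufficient, because the
estimator only ever uses the windowed RMS.  All randomness is owned by the
spec's seed, so identical specs produce bit-identical trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .emg import DEFAULT_WINDOW, ActivationSeries, EmgChannel
from .errors import InfeasibleTrialError, InvalidParameterError
from .forward import MUSCLE_SIGNS, MomentGains, linear_moment_gains
from .inverse import inverse_ankle_moment
from .subject import MUSCLE_NAMES, SubjectModel
from .timeseries import KinematicState, MomentSeries, resample_to

__all__ = [
    "MeasurementNoise",
    "JointProfile",
    "TrialSpec",
    "SyntheticTrial",
    "minimum_jerk",
    "generate_trajectories",
    "required_activations",
    "synthesize_emg",
    "generate_trial",
]

EMG_RATE = 1000.0  # Hz
IMU_RATE = 100.0  # Hz


@dataclass(frozen=True)
class MeasurementNoise:
    """Sensor-noise magnitudes added on top of the deterministic core.

    emg_rms_rel: relative per-window jitter of the sEMG envelope gain
    (electrode/gain fluctuation); imu_angle_sd_rad: additive white noise on
    the inertial angle channels; force_sd_N: additive white noise on the
    chair-force channel (clipped at zero).
    """

    emg_rms_rel: float = 0.05
    imu_angle_sd_rad: float = 0.0087  # 0.5 degrees
    force_sd_N: float = 5.0

    @classmethod
    def zero(cls) -> "MeasurementNoise":
        return cls(emg_rms_rel=0.0, imu_angle_sd_rad=0.0, force_sd_N=0.0)


@dataclass(frozen=True)
class JointProfile:
    """Minimum-jerk profile of one segment elevation angle.

    Angles in rad, measured from the horizontal; onset/offset are fractions
    of the trial duration.
    """

    start: float
    end: float
    onset: float
    offset: float


@dataclass(frozen=True)
class TrialSpec:
    """Study conditions of one synthetic sit-to-stand trial.

    Defaults emulate a 3.5-s transfer with seat-off at 40 % of the
    duration: the HAT pitches forward-to-upright first (60 -> 90 deg over
    0-70 % of the trial), the thigh extends next (55 -> 90 deg, 25-85 %)
    and the shank rights itself last (80 -> 90 deg, 35-95 %), so the hip
    leads the knee and the ankle.  The chair initially carries 80 % of the
    total weight.
    """

    duration: float = 3.5  # s
    seat_off_time: float = 1.4  # s
    shank: JointProfile = field(
        default_factory=lambda: JointProfile(math.radians(80), math.pi / 2, 0.35, 0.95)
    )
    thigh: JointProfile = field(
        default_factory=lambda: JointProfile(math.radians(55), math.pi / 2, 0.25, 0.85)
    )
    hat: JointProfile = field(
        default_factory=lambda: JointProfile(math.radians(60), math.pi / 2, 0.0, 0.70)
    )
    chair_load_fraction: float = 0.8  # of total weight, while seated
    emg_noise_band: tuple[float, float] = (20.0, 450.0)  # Hz
    co_activation_floor: float = 0.05
    measurement_noise: MeasurementNoise = field(default_factory=MeasurementNoise)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.seat_off_time < self.duration:
            raise InvalidParameterError("need 0 < seat_off_time < duration")
        if not 0 <= self.co_activation_floor <= 0.2:
            raise InvalidParameterError("co_activation_floor must be in [0, 0.2]")
        if not 0 < self.chair_load_fraction <= 1:
            raise InvalidParameterError("chair_load_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free internals of a generated trial."""

    activations: dict[str, ActivationSeries]
    sagittal_forces: dict[str, np.ndarray]  # N on the window grid
    moment: MomentSeries  # inverse-dynamics moment, 100 Hz
    kinematics: KinematicState  # clean kinematics
    clipped: bool  # whether the activation solver had to clip


@dataclass(frozen=True)
class SyntheticTrial:
    """One generated trial: noisy sensor streams plus clean ground truth."""

    spec: TrialSpec
    kinematics: KinematicState  # with measurement noise
    emg: dict[str, EmgChannel]  # 1000 Hz, mV
    ground_truth: GroundTruth


def minimum_jerk(u: np.ndarray | float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quintic minimum-jerk shape and its first two derivatives in u.

    s(u) = 10u^3 - 15u^4 + 6u^5 rises from 0 to 1 on [0, 1] with zero
    velocity and acceleration at both ends.
    """
    u = np.asarray(u, dtype=float)
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = 30 * u**2 - 60 * u**3 + 30 * u**4
    d2s = 60 * u - 180 * u**2 + 120 * u**3
    return s[()], ds[()], d2s[()]


def _profile_series(
    profile: JointProfile, times: np.ndarray, duration: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t_on = profile.onset * duration
    t_off = profile.offset * duration
    span = t_off - t_on
    u = np.clip((times - t_on) / span, 0.0, 1.0)
    s, ds, d2s = minimum_jerk(u)
    inside = (times >= t_on) & (times <= t_off)
    delta = profile.end - profile.start
    theta = profile.start + delta * s
    omega = np.where(inside, delta * ds / span, 0.0)
    alpha = np.where(inside, delta * d2s / span**2, 0.0)
    return theta, omega, alpha


def generate_trajectories(
    spec: TrialSpec, subject: SubjectModel
) -> KinematicState:
    """Noise-free segment kinematics and chair force at 100 Hz."""
    n = int(round(spec.duration * IMU_RATE))
    times = np.arange(n) / IMU_RATE

    angles = np.empty((n, 3))
    velocities = np.empty((n, 3))
    accelerations = np.empty((n, 3))
    for j, profile in enumerate((spec.shank, spec.thigh, spec.hat)):
        angles[:, j], velocities[:, j], accelerations[:, j] = _profile_series(
            profile, times, spec.duration
        )

    f0 = spec.chair_load_fraction * subject.total_weight
    s, _, _ = minimum_jerk(np.clip(times / spec.seat_off_time, 0.0, 1.0))
    chair = np.where(times < spec.seat_off_time, f0 * (1.0 - s), 0.0)
    return KinematicState(
        times=times,
        angles=angles,
        velocities=velocities,
        accelerations=accelerations,
        chair_force=chair,
    )


def _window_centers(duration: float, window: float = DEFAULT_WINDOW) -> np.ndarray:
    n_windows = int(round(duration * EMG_RATE)) // int(round(window * EMG_RATE))
    return (np.arange(n_windows) + 0.5) * window


def required_activations(
    kinematics: KinematicState,
    subject: SubjectModel,
    floor: float = 0.05,
    window: float = DEFAULT_WINDOW,
) -> tuple[dict[str, ActivationSeries], MomentGains, bool]:
    """Invert the forward model: activations that reproduce the inverse moment.

    The target moment comes from the four-segment inverse model on the same
    kinematics, resampled to the activation window grid.  The antagonist
    group (the pair whose moment sign opposes the demand) is held at the
    co-activation floor; the residual demand after passive and floor
    contributions is met by equal activation increments across the agonist
    pair (capacity-proportional moment sharing).  Raises
    :class:`InfeasibleTrialError` if the demand exceeds the agonist
    capacity at any window; returns a clipping flag for marginal numerical
    clipping.
    """
    target_100 = inverse_ankle_moment(kinematics, subject)
    duration = kinematics.times[-1] + 1.0 / IMU_RATE
    centers = _window_centers(duration, window)
    target = resample_to(target_100, centers).values

    shank = np.interp(centers, kinematics.times, kinematics.angles[:, 0])
    thigh = np.interp(centers, kinematics.times, kinematics.angles[:, 1])
    gains = linear_moment_gains(subject, centers, shank, thigh)

    floor_act = {name: np.full_like(centers, floor) for name in MUSCLE_NAMES}
    m_floor = gains.moment(floor_act)
    residual = target - m_floor

    dorsi = [m for m in MUSCLE_NAMES if MUSCLE_SIGNS[m] > 0]
    plantar = [m for m in MUSCLE_NAMES if MUSCLE_SIGNS[m] < 0]
    act = {name: np.full_like(centers, floor) for name in MUSCLE_NAMES}
    clipped = False
    headroom = 1.0 - floor

    for group, sign in ((dorsi, 1.0), (plantar, -1.0)):
        sel = sign * residual > 0
        if not np.any(sel):
            continue
        capacity = np.sum([gains.active_gain[m][sel] for m in group], axis=0)
        if np.any(capacity <= 0):
            raise InfeasibleTrialError(
                "agonist group has no moment-generating capacity"
            )
        delta = sign * residual[sel] / capacity
        if np.any(delta > headroom * (1 + 1e-9)):
            idx = int(np.flatnonzero(sel)[np.argmax(delta)])
            raise InfeasibleTrialError(
                f"demanded moment exceeds agonist capacity at window {idx}"
            )
        if np.any(delta > headroom):
            clipped = True
        for m in group:
            vals = act[m]
            vals[sel] = np.clip(floor + delta, floor, 1.0)

    series = {
        name: ActivationSeries(
            muscle=name, times=centers, values=act[name], window=window
        )
        for name in MUSCLE_NAMES
    }
    return series, gains, clipped


def synthesize_emg(
    activations: dict[str, ActivationSeries],
    rms_mvc: dict[str, float],
    spec: TrialSpec,
    rng: np.random.Generator,
) -> dict[str, EmgChannel]:
    """Amplitude-modulated band-limited Gaussian sEMG at 1000 Hz.

    The carrier is unit-variance noise band-limited to the spec's band; the
    instantaneous standard deviation equals a(t) * RMS_MVC with a(t)
    linearly interpolated between window centres.  Per-window envelope-gain
    jitter of relative size ``measurement_noise.emg_rms_rel`` models
    electrode-gain fluctuation.
    """
    n = int(round(spec.duration * EMG_RATE))
    times = np.arange(n) / EMG_RATE
    low, high = spec.emg_noise_band
    sos = sps.butter(4, [low, high], btype="bandpass", fs=EMG_RATE, output="sos")
    channels = {}
    for name in MUSCLE_NAMES:
        series = activations[name]
        envelope = np.interp(times, series.times, series.values) * rms_mvc[name]
        rel = spec.measurement_noise.emg_rms_rel
        if rel > 0:
            gain = 1.0 + rel * rng.standard_normal(series.times.size)
            envelope *= np.maximum(
                np.interp(times, series.times, gain), 0.0
            )
        carrier = rng.standard_normal(n)
        carrier = sps.sosfiltfilt(sos, carrier)
        std = carrier.std()
        if std > 0:
            carrier /= std
        channels[name] = EmgChannel(
            muscle=name, samples=envelope * carrier, rate=EMG_RATE
        )
    return channels


def generate_trial(spec: TrialSpec, subject: SubjectModel) -> SyntheticTrial:
    """Generate one complete trial: clean core, then seeded measurement noise."""
    rng = np.random.default_rng(spec.seed)
    clean = generate_trajectories(spec, subject)
    activations, gains, clipped = required_activations(
        clean, subject, floor=spec.co_activation_floor
    )
    emg = synthesize_emg(activations, dict(subject.rms_mvc), spec, rng)

    forces = {
        name: gains.sagittal_force(name, activations[name].values)
        for name in MUSCLE_NAMES
    }
    truth = GroundTruth(
        activations=activations,
        sagittal_forces=forces,
        moment=inverse_ankle_moment(clean, subject),
        kinematics=clean,
        clipped=clipped,
    )

    noise = spec.measurement_noise
    angles = clean.angles.copy()
    chair = clean.chair_force.copy()
    if noise.imu_angle_sd_rad > 0:
        angles = angles + rng.normal(0.0, noise.imu_angle_sd_rad, angles.shape)
    if noise.force_sd_N > 0:
        chair = np.maximum(
            chair + rng.normal(0.0, noise.force_sd_N, chair.shape), 0.0
        )
        chair[clean.chair_force == 0.0] = 0.0  # seat-off is observed exactly
    noisy = KinematicState(
        times=clean.times,
        angles=angles,
        velocities=clean.velocities,
        accelerations=clean.accelerations,
        chair_force=chair,
    )
    return SyntheticTrial(spec=spec, kinematics=noisy, emg=emg, ground_truth=truth)
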