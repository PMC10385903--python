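"""Shared time-series containers for both moment estimators.

:class:`KinematicState` carries the 100-Hz inertial channels — sagittal
segment elevation angles, angular velocities and accelerations for the
shank, thigh and HAT (indexed in that order), plus the vertical chair
reaction force.  Segment angles are measured counterclockwise from the
horizontal X axis; upright standing puts every segment at pi/2.

:class:`MomentSeries` is an ankle-moment trace from either estimator,
dorsiflexion positive, in N·m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, InvalidParameterError, RangeError

__all__ = ["KinematicState", "MomentSeries", "SEGMENT_ORDER", "resample_to"]

SEGMENT_ORDER = ("shank", "thigh", "hat")


@dataclass(frozen=True)
class KinematicState:
    """Sampled joint kinematics and chair force on a uniform time grid."""

    times: np.ndarray  # s
    angles: np.ndarray  # (T, 3) rad: shank, thigh, hat
    velocities: np.ndarray  # (T, 3) rad/s
    accelerations: np.ndarray  # (T, 3) rad/s^2
    chair_force: np.ndarray  # (T,) N, >= 0

    def __post_init__(self) -> None:
        for name in ("times", "angles", "velocities", "accelerations", "chair_force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        t = self.times.size
        for name in ("angles", "velocities", "accelerations"):
            arr = getattr(self, name)
            if arr.shape != (t, 3):
                raise AlignmentError(f"{name} must have shape ({t}, 3)")
        if self.chair_force.shape != (t,):
            raise AlignmentError("chair_force length must match times")
        if np.any(self.chair_force < 0):
            raise InvalidParameterError("chair_force must be >= 0")
        if t > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(angle, velocity, acceleration) series for one segment."""
        i = SEGMENT_ORDER.index(name)
        return self.angles[:, i], self.velocities[:, i], self.accelerations[:, i]


@dataclass(frozen=True)
class MomentSeries:
    """Ankle joint moment vs time, dorsiflexion positive [N·m]."""

    times: np.ndarray  # s
    values: np.ndarray  # N·m
    source: str = ""  # "forward" | "inverse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise AlignmentError("times and values must match in shape")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("moment values must be finite")


def resample_to(series: MomentSeries, target_times: np.ndarray) -> MomentSeries:
    """Linearly interpolate a moment series onto new times within its span."""
    target_times = np.asarray(target_times, dtype=float)
    if target_times.size and (
        target_times.min() < series.times.min() - 1e-12
        or target_times.max() > series.times.max() + 1e-12
    ):
        raise RangeError("target times extend beyond the series span")
    values = np.interp(target_times, series.times, series.values)
    return MomentSeries(times=target_times, values=values, source=series.source)
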