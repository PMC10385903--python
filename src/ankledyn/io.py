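"""Headered-CSV readers and writers for the sensor-log formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EmgChannel
from .errors import AlignmentError
from .subject import MUSCLE_NAMES
from .timeseries import SEGMENT_ORDER, KinematicState, MomentSeries

__all__ = [
    "write_emg_csv", "read_emg_csv",
    "write_imu_csv", "read_imu_csv",
    "write_force_csv", "read_force_csv",
    "write_moment_csv", "read_moment_csv",
]


def write_emg_csv(channels: dict[str, EmgChannel], path: str | Path) -> None:
    rate = channels[MUSCLE_NAMES[0]].rate
    n = channels[MUSCLE_NAMES[0]].samples.size
    data = {"time_s": np.arange(n) / rate}
    for name in MUSCLE_NAMES:
        ch = channels[name]
        if ch.samples.size != n or ch.rate != rate:
            raise AlignmentError("EMG channels must share rate and length")
        data[f"{name}_mV"] = ch.samples
    pd.DataFrame(data).to_csv(path, index=False)


def read_emg_csv(path: str | Path) -> dict[str, EmgChannel]:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy()
    rate = 1.0 / float(np.mean(np.diff(t)))
    return {
        name: EmgChannel(
            muscle=name, samples=frame[f"{name}_mV"].to_numpy(), rate=round(rate)
        )
        for name in MUSCLE_NAMES
    }


def write_imu_csv(state: KinematicState, path: str | Path) -> None:
    data = {"time_s": state.times}
    for i, seg in enumerate(SEGMENT_ORDER):
        data[f"{seg}_angle_rad"] = state.angles[:, i]
        data[f"{seg}_angvel_rad_s"] = state.velocities[:, i]
        data[f"{seg}_angacc_rad_s2"] = state.accelerations[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_imu_csv(path: str | Path, chair_force: np.ndarray | None = None) -> KinematicState:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy()
    angles = np.column_stack([frame[f"{s}_angle_rad"] for s in SEGMENT_ORDER])
    vel = np.column_stack([frame[f"{s}_angvel_rad_s"] for s in SEGMENT_ORDER])
    acc = np.column_stack([frame[f"{s}_angacc_rad_s2"] for s in SEGMENT_ORDER])
    if chair_force is None:
        chair_force = np.zeros_like(t)
    return KinematicState(
        times=t, angles=angles, velocities=vel, accelerations=acc,
        chair_force=np.asarray(chair_force, dtype=float),
    )


def write_force_csv(times: np.ndarray, force: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": times, "chair_force_N": force}).to_csv(path, index=False)


def read_force_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path)
    return frame["time_s"].to_numpy(), frame["chair_force_N"].to_numpy()


def write_moment_csv(series: MomentSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times, "moment_Nm": series.values}).to_csv(
        path, index=False
    )


def read_moment_csv(path: str | Path, source: str = "") -> MomentSeries:
    frame = pd.read_csv(path)
    return MomentSeries(
        times=frame["time_s"].to_numpy(),
        values=frame["moment_Nm"].to_numpy(),
        source=source,
    )
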