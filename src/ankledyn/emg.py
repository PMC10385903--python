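"""sEMG preprocessing and activation estimation.

Raw surface EMG (1000 Hz, mV) is band-pass filtered and rectified, reduced
to a root-mean-square envelope on contiguous non-overlapping 0.05-s windows,

    RMS = sqrt( (1/N) * sum_i v_i^2 ),

and normalised by the RMS at maximum voluntary contraction to give a linear
muscle activation a(t) = RMS(t) / RMS_MVC, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import EmptySignalError, InvalidParameterError

__all__ = [
    "EmgChannel",
    "ActivationSeries",
    "preprocess",
    "windowed_rms",
    "activation",
    "emg_to_activation",
    "DEFAULT_BAND",
    "DEFAULT_WINDOW",
]

DEFAULT_BAND = (20.0, 450.0)  # Hz, standard surface-EMG band
DEFAULT_WINDOW = 0.05  # s


@dataclass(frozen=True)
class EmgChannel:
    """One muscle's raw or preprocessed sEMG trace in mV."""

    muscle: str
    samples: np.ndarray
    rate: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise InvalidParameterError("rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must be finite")


@dataclass(frozen=True)
class ActivationSeries:
    """Muscle activation on the windowed-RMS grid; values in [0, 1]."""

    muscle: str
    times: np.ndarray  # s, window centers
    values: np.ndarray  # dimensionless
    window: float  # s

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise InvalidParameterError("times and values must match in shape")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise InvalidParameterError("activation values must lie in [0, 1]")


def preprocess(
    raw: EmgChannel, band: tuple[float, float] = DEFAULT_BAND
) -> EmgChannel:
    """Zero-phase band-pass filter (4th-order Butterworth) then full-wave rectify.

    The band must satisfy 0 < low < high < rate/2.
    """
    low, high = band
    nyq = raw.rate / 2.0
    if not 0 < low < high < nyq:
        raise InvalidParameterError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=raw.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, raw.samples)
    return EmgChannel(muscle=raw.muscle, samples=np.abs(filtered), rate=raw.rate)


def windowed_rms(
    channel: EmgChannel, window: float = DEFAULT_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """RMS over contiguous non-overlapping windows.

    Returns (window-center times [s], RMS values [mV]).  A trailing
    incomplete window is discarded; a signal shorter than one window is an
    error.
    """
    n = int(round(window * channel.rate))
    if n < 1:
        raise InvalidParameterError("window must span at least one sample")
    n_windows = channel.samples.size // n
    if n_windows == 0:
        raise EmptySignalError("signal shorter than one RMS window")
    chunks = channel.samples[: n_windows * n].reshape(n_windows, n)
    rms = np.sqrt(np.mean(chunks**2, axis=1))
    times = (np.arange(n_windows) + 0.5) * n / channel.rate
    return times, rms


def activation(
    rms: np.ndarray,
    rms_mvc: float,
    muscle: str = "",
    times: np.ndarray | None = None,
    window: float = DEFAULT_WINDOW,
) -> ActivationSeries:
    """Normalise an RMS envelope by the MVC RMS, clipping to [0, 1]."""
    if rms_mvc <= 0:
        raise InvalidParameterError("rms_mvc must be > 0")
    rms = np.asarray(rms, dtype=float)
    if times is None:
        times = (np.arange(rms.size) + 0.5) * window
    values = np.clip(rms / rms_mvc, 0.0, 1.0)
    return ActivationSeries(muscle=muscle, times=np.asarray(times), values=values, window=window)


def emg_to_activation(
    raw: EmgChannel,
    rms_mvc: float,
    band: tuple[float, float] = DEFAULT_BAND,
    window: float = DEFAULT_WINDOW,
) -> ActivationSeries:
    """Full pipeline: filter + rectify, windowed RMS, MVC normalisation."""
    clean = preprocess(raw, band)
    times, rms = windowed_rms(clean, window)
    return activation(rms, rms_mvc, muscle=raw.muscle, times=times, window=window)
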