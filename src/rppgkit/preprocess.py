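"""Per-window signal conditioning.

Stage order is fixed: linear detrend -> max-abs normalization -> moving
average smoothing -> 0.7-4 Hz band-pass.  Every stage preserves length,
and detrend/smooth/bandpass are linear operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from rppgkit.traces import RGBWindow

#: Default pass band: 0.7-4 Hz, i.e. 42-240 beats per minute.
DEFAULT_F_LOW = 0.7
DEFAULT_F_HIGH = 4.0


@dataclass(frozen=True)
class BandLimits:
    """Physiological pass band in Hz."""

    f_low: float = DEFAULT_F_LOW
    f_high: float = DEFAULT_F_HIGH

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"need 0 < f_low < f_high, got ({self.f_low}, {self.f_high})")

    @property
    def min_bpm(self) -> float:
        """Lowest reportable heart rate: ``f_low * 60``."""
        return self.f_low * 60.0

    @property
    def max_bpm(self) -> float:
        """Highest reportable heart rate: ``f_high * 60``."""
        return self.f_high * 60.0

    def validate_for_fps(self, fps: float) -> None:
        if self.f_high >= fps / 2:
            raise ValueError(
                f"f_high {self.f_high} Hz >= Nyquist ({fps / 2} Hz at {fps} fps)")


@dataclass(frozen=True)
class PreprocessConfig:
    band: BandLimits = BandLimits()
    order: int = 3
    smooth_w: int = 5
    filter: str = "butterworth"  # or "ideal"


@dataclass(frozen=True)
class ConditionedWindow:
    """Detrended, normalized, smoothed and band-passed channel signals."""

    start_s: float
    fps: float
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            x = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite values in channel {name}")
            object.__setattr__(self, name, x)
        if not (len(self.r) == len(self.g) == len(self.b)):
            raise ValueError("channels must have equal length")


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line; output has zero best-fit slope."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("detrend needs at least 2 samples")
    return sps.detrend(x, type="linear")


def normalize_maxabs(x: np.ndarray) -> np.ndarray:
    """Divide by the maximum absolute value; all-zero input passes through."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    m = np.max(np.abs(x))
    if m == 0.0:
        return x.copy()
    return x / m


def smooth_moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    """Centered w-point mean with reflection padding at the edges."""
    x = np.asarray(x, dtype=float)
    if w < 1 or w % 2 == 0:
        raise ValueError(f"smoothing width must be a positive odd int, got {w}")
    if w > x.size:
        raise ValueError(f"smoothing width {w} exceeds signal length {x.size}")
    if w == 1:
        return x.copy()
    half = w // 2
    padded = np.pad(x, half, mode="reflect")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(padded, kernel, mode="valid")


def bandpass(x: np.ndarray, fps: float, band: BandLimits = BandLimits(),
             order: int = 3, mode: str = "butterworth") -> np.ndarray:
    """Zero-phase band-pass restricted to the physiological band.

    ``butterworth`` (default) applies an order-*order* Butterworth filter
    forward and backward (``filtfilt``); ``ideal`` zeroes all FFT
    coefficients outside the band (brick-wall comparison mode).
    """
    x = np.asarray(x, dtype=float)
    band.validate_for_fps(fps)
    if mode == "butterworth":
        sos = sps.butter(order, [band.f_low, band.f_high], btype="bandpass",
                         fs=fps, output="sos")
        # pad length capped for short windows
        padlen = min(3 * (2 * order + 1), x.size - 1)
        return sps.sosfiltfilt(sos, x, padlen=padlen)
    if mode == "ideal":
        spectrum = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
        spectrum[(freqs < band.f_low) | (freqs > band.f_high)] = 0.0
        return np.fft.irfft(spectrum, n=x.size)
    raise ValueError(f"unknown filter mode: {mode!r}")


def condition_window(window: RGBWindow,
                     config: PreprocessConfig = PreprocessConfig()
                     ) -> ConditionedWindow:
    """Apply the full conditioning chain to each channel of a window.

    The detrend step of the chain removes the fitted slope but keeps the
    window mean, so the normalized signals lie in [0, 1]: dividing by the
    maximum absolute value then scales each channel by roughly its
    baseline intensity, which preserves the relative pulse amplitudes the
    chrominance projection relies on (stripping the mean here would
    instead equalize the channels' AC amplitude and cancel the pulse).
    The DC component is removed later by the band-pass.
    """
    def chain(x: np.ndarray) -> np.ndarray:
        x = detrend_linear(x) + np.mean(x)
        x = normalize_maxabs(x)
        x = smooth_moving_average(x, config.smooth_w)
        return bandpass(x, window.fps, config.band, config.order, config.filter)

    return ConditionedWindow(start_s=window.start_s, fps=window.fps,
                             r=chain(window.r), g=chain(window.g),
                             b=chain(window.b))
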