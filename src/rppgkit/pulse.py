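"""Chrominance (CHROM) pulse extraction and spectral heart-rate readout.

The three conditioned color signals are projected onto two chrominance
axes,

    X(t) = 3 R(t) - 2 G(t)
    Y(t) = 1.5 R(t) + G(t) - 1.5 B(t)

and combined as ``rPPG(t) = X(t) - mu Y(t)`` with ``mu`` the ratio of the
standard deviations of X and Y.  Because equal-channel (achromatic)
variation yields X = Y and mu = 1, illumination changes cancel exactly.
The heart rate is the frequency of the maximum power-spectrum peak inside
the pass band, times 60.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from rppgkit.preprocess import BandLimits, ConditionedWindow

logger = logging.getLogger(__name__)

#: Minimum zero-padded FFT length; at 30 fps this yields a grid spacing of
#: 30/32768 Hz ~ 0.055 bpm, well under the 0.5 bpm resolution target.
MIN_FFT_POINTS = 2 ** 15


@dataclass(frozen=True)
class ChromPair:
    """The two chrominance projections and their std ratio mu.

    ``degenerate`` is set when std(Y) == 0 (mu reported as 0).
    """

    x: np.ndarray
    y: np.ndarray
    mu: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValueError("chrominance projections must have equal length")
        if self.mu < 0 or not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite and >= 0, got {self.mu}")


@dataclass(frozen=True)
class PulseSignal:
    """The rPPG waveform for one analysis window."""

    samples: np.ndarray
    fps: float
    start_s: float = 0.0
    no_signal: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError("pulse signal contains non-finite values")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class HREstimate:
    """Dominant in-band frequency and the derived heart rate.

    ``f_hr``/``hr_bpm`` are None for a no-signal window;
    ``hr_bpm == 60 * f_hr`` holds exactly otherwise.
    """

    f_hr: Optional[float]
    hr_bpm: Optional[float]
    peak_power_fraction: float
    window_start_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_power_fraction <= 1.0:
            raise ValueError("peak_power_fraction outside [0, 1]")


def chrom_project(window: ConditionedWindow,
                  mean_normalize: bool = False) -> ChromPair:
    """Project conditioned R, G, B onto the two chrominance axes.

    ``mean_normalize=True`` first divides each channel by its temporal
    mean (the original chrominance-method convention); the default applies
    the projection directly to the already-normalized channels.
    """
    r, g, b = window.r, window.g, window.b
    if len(r) < 2:
        raise ValueError("projection needs at least 2 samples")
    if mean_normalize:
        def unit_mean(c: np.ndarray) -> np.ndarray:
            m = c.mean()
            return c / m if m != 0 else c
        r, g, b = unit_mean(r), unit_mean(g), unit_mean(b)

    x = 3.0 * r - 2.0 * g
    y = 1.5 * r + g - 1.5 * b
    sx = float(np.std(x))  # population (1/N) standard deviation
    sy = float(np.std(y))
    if sy == 0.0:
        logger.info("degenerate chrominance pair: std(Y) = 0")
        return ChromPair(x=x, y=y, mu=0.0, degenerate=True)
    return ChromPair(x=x, y=y, mu=sx / sy)


def chrom_pulse(pair: ChromPair, fps: float, start_s: float = 0.0) -> PulseSignal:
    """Combine the chrominance pair into the pulse: ``x - mu * y``."""
    samples = pair.x - pair.mu * pair.y
    no_signal = pair.degenerate and float(np.std(samples)) == 0.0
    if no_signal:
        samples = np.zeros_like(samples)
    return PulseSignal(samples=samples, fps=fps, start_s=start_s,
                       no_signal=no_signal)


def power_spectrum(samples: np.ndarray, fps: float,
                   n_min: int = MIN_FFT_POINTS) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered, zero-padded power spectrum: (freqs_hz, power)."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    tapered = x * np.hanning(n)
    n_fft = max(n_min, n)
    spectrum = np.fft.rfft(tapered, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fps)
    return freqs, np.abs(spectrum) ** 2


def estimate_hr(pulse: PulseSignal, band: BandLimits = BandLimits()) -> HREstimate:
    """Heart rate from the maximum in-band power-spectrum peak.

    ``hr_bpm = 60 * f_hr`` where ``f_hr`` is the argmax of the power
    spectrum restricted to the pass band (ties broken toward the lower
    frequency).  The quality figure is the fraction of in-band power at
    the peak bin.  An all-zero pulse gives a no-signal estimate.
    """
    samples = np.asarray(pulse.samples, dtype=float)
    if samples.size < 2:
        raise ValueError("heart-rate estimation needs at least 2 samples")
    if pulse.no_signal or not samples.any():
        return HREstimate(f_hr=None, hr_bpm=None, peak_power_fraction=0.0,
                          window_start_s=pulse.start_s)

    freqs, power = power_spectrum(samples, pulse.fps)
    in_band = (freqs >= band.f_low) & (freqs <= band.f_high)
    if not in_band.any():
        return HREstimate(f_hr=None, hr_bpm=None, peak_power_fraction=0.0,
                          window_start_s=pulse.start_s)
    band_power = power[in_band]
    total = band_power.sum()
    if total == 0.0:
        return HREstimate(f_hr=None, hr_bpm=None, peak_power_fraction=0.0,
                          window_start_s=pulse.start_s)
    peak = int(np.argmax(band_power))  # argmax takes the first (lowest) bin
    f_hr = float(freqs[in_band][peak])
    return HREstimate(f_hr=f_hr, hr_bpm=60.0 * f_hr,
                      peak_power_fraction=float(band_power[peak] / total),
                      window_start_s=pulse.start_s)


def window_to_estimate(window: ConditionedWindow,
                       band: BandLimits = BandLimits(),
                       mean_normalize: bool = False) -> HREstimate:
    """Convenience: projection + combination + spectral readout."""
    pair = chrom_project(window, mean_normalize=mean_normalize)
    pulse = chrom_pulse(pair, fps=window.fps, start_s=window.start_s)
    return estimate_hr(pulse, band)
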