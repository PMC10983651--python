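"""Frequency-domain characterization of circumnutation.

The nutation-distance series (XY distance between the raw tip trajectory
and its smoothed main growth component) is analysed with a plain DFT: the
series mean is subtracted, the one-sided magnitude spectrum is computed on
the standard FFT frequency grid, and the main period of nutation is the
reciprocal of the frequency with maximum amplitude.  Spectra of several
plants can be smoothed (8-sample moving average by default, display
convention) and averaged frequency-by-frequency into a population
spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import GridMismatchError, NoPeakError, SchemaError
from .smoothing import centered_moving_average
from .trajectory import infer_sampling_interval

__all__ = [
    "NutationDistanceSeries",
    "AmplitudeSpectrum",
    "amplitude_spectrum",
    "main_period",
    "smooth_spectrum",
    "average_spectra",
    "period_hours",
]


@dataclass
class NutationDistanceSeries:
    """XY-plane distance of the tip from its main growth component, vs time.

    times in minutes on a uniform grid; distances in mm, non-negative.
    """

    times: np.ndarray
    distances: np.ndarray
    sampling_interval: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise SchemaError("times and distances must have equal length")
        if np.any(self.distances < -1e-12):
            raise SchemaError("distances must be non-negative")
        if not self.sampling_interval:
            self.sampling_interval = infer_sampling_interval(self.times)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum of a nutation-distance series.

    frequencies in Hz (ascending, DC excluded); amplitudes in mm (a pure
    sinusoid of amplitude A produces a peak of ~A).
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    n_samples: int
    sampling_interval: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.frequencies.shape != self.amplitudes.shape:
            raise SchemaError("frequency and amplitude arrays must match")

    @property
    def resolution_hz(self) -> float:
        """Frequency bin width, 1 / (n * dt)."""
        return 1.0 / (self.n_samples * self.sampling_interval * 60.0)

    def __len__(self) -> int:
        return self.frequencies.size


def amplitude_spectrum(series: NutationDistanceSeries) -> AmplitudeSpectrum:
    """One-sided FFT amplitude spectrum of the mean-subtracted distance series.

    The distance series is non-negative with a large mean, so the mean is
    removed and the DC bin excluded before any peak search.  No taper is
    applied.
    """
    n = len(series)
    if n < 16:
        raise SchemaError("need at least 16 samples for a spectrum")
    infer_sampling_interval(series.times)  # raises on non-uniform grid
    dt_s = series.sampling_interval * 60.0
    x = series.distances - series.distances.mean()
    F = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, dt_s)
    amps = 2.0 * np.abs(F) / n
    if n % 2 == 0:
        amps[-1] = np.abs(F[-1]) / n  # Nyquist bin is not doubled
    return AmplitudeSpectrum(
        frequencies=freqs[1:],
        amplitudes=amps[1:],
        n_samples=n,
        sampling_interval=series.sampling_interval,
    )


def period_hours(frequency_hz: float) -> float:
    """Convert a frequency in Hz to a period in hours."""
    if frequency_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1.0 / frequency_hz / 3600.0


def main_period(spec: AmplitudeSpectrum) -> float:
    """Main period of nutation (hours): 1 / frequency of the maximum bin.

    Ties are broken toward the lower frequency (longer period).
    """
    if len(spec) == 0:
        raise NoPeakError("empty spectrum")
    if np.all(spec.amplitudes <= 0):
        raise NoPeakError("all-zero spectrum has no peak")
    k = int(np.argmax(spec.amplitudes))  # argmax returns the first (lowest-f) max
    return period_hours(spec.frequencies[k])


def smooth_spectrum(spec: AmplitudeSpectrum, window: int = 8) -> AmplitudeSpectrum:
    """Moving-average smoothing of the amplitude array (display convention).

    Same shrinking-edge centred window as trajectory smoothing; the
    frequency grid is unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(spec):
        raise ValueError("smoothing window longer than the spectrum")
    return AmplitudeSpectrum(
        frequencies=spec.frequencies.copy(),
        amplitudes=centered_moving_average(spec.amplitudes, window),
        n_samples=spec.n_samples,
        sampling_interval=spec.sampling_interval,
    )


def average_spectra(specs: Sequence[AmplitudeSpectrum]) -> AmplitudeSpectrum:
    """Frequency-by-frequency average spectrum over a cohort of plants.

    Records of different lengths have different frequency grids; all
    spectra are linearly interpolated onto the grid of the spectrum with
    the coarsest resolution, restricted to the frequency range common to
    all, and averaged element-wise.
    """
    if len(specs) == 0:
        raise ValueError("average_spectra needs at least one spectrum")
    coarsest = max(specs, key=lambda s: s.resolution_hz)
    lo = max(s.frequencies[0] for s in specs)
    hi = min(s.frequencies[-1] for s in specs)
    if hi <= lo:
        raise GridMismatchError("spectra have no overlapping frequency range")
    mask = (coarsest.frequencies >= lo) & (coarsest.frequencies <= hi)
    grid = coarsest.frequencies[mask]
    stack = np.array(
        [np.interp(grid, s.frequencies, s.amplitudes) for s in specs]
    )
    return AmplitudeSpectrum(
        frequencies=grid,
        amplitudes=stack.mean(axis=0),
        n_samples=coarsest.n_samples,
        sampling_interval=coarsest.sampling_interval,
    )
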