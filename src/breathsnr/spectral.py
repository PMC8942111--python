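"""Power-spectral-density and band-power estimation.

All signal and noise powers in this package are *band powers*: integrals of a
one-sided Welch power spectral density over a frequency band.  The density is
normalized so that integrating it over [0, rate/2] returns the time-domain
signal power (Parseval contract), which makes the SNR power terms
well-defined physical quantities in watts (for a unit-impedance signal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigurationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray   # Hz, spanning [0, rate/2]
    density: np.ndarray       # power per Hz, >= 0
    rate: float               # Hz
    window: str = "hann"
    nperseg: int = 0
    noverlap: int = 0


def welch_psd(waveform: np.ndarray, rate: float, segment_length: float = 1.0,
              overlap_fraction: float = 0.5, window: str = "hann") -> PowerSpectrum:
    """Averaged-periodogram (Welch) PSD with Parseval normalization.

    Parameters
    ----------
    segment_length:
        Welch segment length in seconds; must give at least 8 samples.
    overlap_fraction:
        Fractional overlap between segments, in [0, 1).

    Signals shorter than one segment fall back to a single periodogram over
    the whole signal (with a logged warning) rather than failing.
    """
    x = np.asarray(waveform, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidConfigurationError("empty waveform")
    if rate <= 0:
        raise InvalidConfigurationError("rate must be positive")
    if not 0.0 <= overlap_fraction < 1.0:
        raise InvalidConfigurationError("overlap_fraction must be in [0, 1)")
    nperseg = int(round(segment_length * rate))
    if nperseg < 8:
        raise InvalidConfigurationError(
            f"segment_length*rate = {nperseg} samples; need >= 8"
        )
    if x.size < nperseg:
        log.warning("signal (%d samples) shorter than one Welch segment (%d); "
                    "using a single periodogram", x.size, nperseg)
        nperseg = x.size
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, density = sps.welch(x, fs=rate, window=window, nperseg=nperseg,
                               noverlap=noverlap, detrend=False,
                               scaling="density")
    return PowerSpectrum(frequencies=freqs, density=density, rate=float(rate),
                         window=window, nperseg=nperseg, noverlap=noverlap)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Integrate the PSD over ``band`` (Hz) by the trapezoid rule.

    The density is linearly interpolated at the exact band edges, so powers
    over disjoint adjacent bands add exactly to the power over their union.
    """
    lo, hi = float(band[0]), float(band[1])
    nyquist = spectrum.rate / 2.0
    if not (0.0 <= lo < hi <= nyquist + 1e-9):
        raise InvalidConfigurationError(
            f"band {band} empty or outside [0, {nyquist}] Hz"
        )
    f, d = spectrum.frequencies, spectrum.density
    inner = (f > lo) & (f < hi)
    grid = np.concatenate(([lo], f[inner], [hi]))
    vals = np.concatenate(([np.interp(lo, f, d)], d[inner],
                           [np.interp(hi, f, d)]))
    return float(np.trapezoid(vals, grid))


def band_power_direct(waveform: np.ndarray, rate: float,
                      band: tuple[float, float], order: int = 4) -> float:
    """Band power by zero-phase band-pass filtering + time-domain variance.

    An independent route to the same quantity as :func:`band_power`; used for
    ground-truth bookkeeping so the simulator's truth does not depend on the
    Welch estimator it is used to check.
    """
    y = bandpass(waveform, rate, band, order=order)
    return float(np.mean(y ** 2))


def bandpass(waveform: np.ndarray, rate: float, band: tuple[float, float],
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass restricted to the Nyquist range."""
    lo, hi = band
    nyquist = rate / 2.0
    if not (0.0 <= lo < hi <= nyquist):
        raise InvalidConfigurationError(
            f"band {band} outside [0, {nyquist}] Hz at rate {rate}"
        )
    if lo == 0.0:
        sos = sps.butter(order, hi / nyquist, btype="low", output="sos")
    else:
        sos = sps.butter(order, [lo / nyquist, hi / nyquist],
                         btype="band", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(waveform, dtype=np.float64))


def spectrum_to_csv(spectrum: PowerSpectrum, path) -> None:
    """Export (frequency_hz, density) columns for external plotting."""
    import pandas as pd

    pd.DataFrame({"frequency_hz": spectrum.frequencies,
                  "density": spectrum.density}).to_csv(path, index=False)
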