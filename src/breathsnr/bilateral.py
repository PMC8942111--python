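"""Bilateral (two-sensor) combination and array-gain reporting.

The two chest channels observe the same breath source through different
sparse multipath filters.  Combination is single-tap delay-and-sum: the
inter-channel lag is estimated by normalized cross-correlation restricted
to breath-active intervals (the coherent component is the breath signal,
not the noise), the right channel is shifted into alignment, and the
channels are averaged with weights proportional to their linear SNRs.  When
the channels are incoherent (peak correlation below a threshold) the
combination degrades gracefully to selecting the better channel, so the
combined SNR never falls materially below the best single channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .errors import BandMismatchError, DeadChannelError, InvalidConfigurationError
from .recording import Recording
from .segment import PHASE_ACTIVE, SegmentLabel
from .snr import SnrResult, channel_snr, session_snr

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentEstimate:
    """Inter-channel delay and combination weights.

    ``lag`` is in samples, positive when the right channel lags the left
    (x_r[n] ~ x_l[n - lag]).  ``weights`` = (w_left, w_right), sum to 1.
    """

    lag: int
    peak_correlation: float
    weights: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.weights), 1.0):
            raise InvalidConfigurationError("weights must sum to 1")
        if min(self.weights) < 0:
            raise InvalidConfigurationError("weights must be >= 0")


def estimate_delay(x_left: np.ndarray, x_right: np.ndarray, rate: float,
                   max_lag: float = 0.050,
                   active_intervals: np.ndarray | None = None,
                   snr_left: float | None = None,
                   snr_right: float | None = None) -> AlignmentEstimate:
    """Estimate the right-vs-left lag by normalized cross-correlation.

    The search is limited to +/- ``max_lag`` seconds.  If
    ``active_intervals`` is given ((k, 2) sample pairs), samples outside
    them are zeroed first so only the breath signal drives the estimate.
    Ties are broken toward the smallest |lag|, then toward negative lag.
    Weights are proportional to the supplied per-channel *linear* SNRs
    (equal weights when omitted).
    """
    xl = np.asarray(x_left, dtype=np.float64).ravel()
    xr = np.asarray(x_right, dtype=np.float64).ravel()
    if xl.size != xr.size:
        raise InvalidConfigurationError("channels must have equal length")
    max_lag_n = int(round(max_lag * rate))
    if xl.size < 2 * max_lag_n:
        raise InvalidConfigurationError(
            "channels shorter than twice the maximum lag")
    if active_intervals is not None and len(active_intervals) > 0:
        mask = np.zeros(xl.size, dtype=bool)
        for s, e in np.asarray(active_intervals, dtype=np.int64).reshape(-1, 2):
            mask[s:e] = True
        xl, xr = np.where(mask, xl, 0.0), np.where(mask, xr, 0.0)
    el, er = float(np.sum(xl ** 2)), float(np.sum(xr ** 2))
    for side, energy in (("left", el), ("right", er)):
        if energy == 0.0:
            raise DeadChannelError(f"{side} channel has zero variance")

    full = sps.correlate(xr, xl, mode="full", method="fft")
    # full[i] = sum_n xr[n] xl[n - s] with s = i - (len - 1); peak at s = lag
    center = xl.size - 1
    lags = np.arange(-max_lag_n, max_lag_n + 1)
    corr = full[center + lags] / np.sqrt(el * er)
    peak = float(corr.max())
    candidates = lags[np.isclose(corr, peak, rtol=0.0, atol=1e-12)]
    lag = int(min(candidates, key=lambda s: (abs(s), s)))

    if snr_left is not None and snr_right is not None:
        total = snr_left + snr_right
        if total <= 0:
            weights = (0.5, 0.5)
        else:
            weights = (snr_left / total, snr_right / total)
    else:
        weights = (0.5, 0.5)
    return AlignmentEstimate(lag=lag, peak_correlation=peak, weights=weights)


def combine_bilateral(x_left: np.ndarray, x_right: np.ndarray,
                      alignment: AlignmentEstimate,
                      incoherence_threshold: float = 0.2) -> np.ndarray:
    """Delay-and-sum the two channels under the given alignment.

    The right channel is advanced by ``lag`` samples (zero-padded) and the
    channels are summed with the alignment weights.  If the peak
    correlation is below ``incoherence_threshold`` the higher-weight
    channel is returned unmixed (weights degrade to 1/0) with a logged
    notice, since blind summing of incoherent channels costs SNR.
    """
    xl = np.asarray(x_left, dtype=np.float64).ravel()
    xr = np.asarray(x_right, dtype=np.float64).ravel()
    if xl.size != xr.size:
        raise InvalidConfigurationError("channels must have equal length")
    w_l, w_r = alignment.weights
    if alignment.peak_correlation < incoherence_threshold:
        log.info("peak correlation %.3f below %.2f; selecting the "
                 "higher-weight channel instead of summing",
                 alignment.peak_correlation, incoherence_threshold)
        return xl.copy() if w_l >= w_r else xr.copy()
    aligned = np.zeros_like(xr)
    lag = alignment.lag
    if lag > 0:                       # right lags left -> advance right
        aligned[:-lag or None] = xr[lag:]
    elif lag < 0:
        aligned[-lag:] = xr[:lag]
    else:
        aligned = xr.copy()
    return w_l * xl + w_r * aligned


def array_gain_db(combined_snr: SnrResult, *single_snrs: SnrResult) -> float:
    """Array gain: combined SNR over the best single channel, in dB.

    May be negative; it is reported, not clamped.  All results must share
    the same analysis band.
    """
    if not single_snrs:
        raise InvalidConfigurationError("need at least one single-channel result")
    for r in single_snrs:
        if tuple(r.band) != tuple(combined_snr.band):
            raise BandMismatchError(
                f"band mismatch: combined {combined_snr.band} vs {r.band}")
    return float(combined_snr.snr_db - max(r.snr_db for r in single_snrs))


@dataclass(frozen=True)
class BilateralResult:
    """Per-channel and combined SNR of one bilateral session."""

    left: SnrResult
    right: SnrResult
    combined: SnrResult
    alignment: AlignmentEstimate
    gain_db: float


def bilateral_session(recording: Recording,
                      config: AnalysisConfig = AnalysisConfig(),
                      ) -> BilateralResult:
    """Full bilateral pipeline: per-channel SNR, alignment, combination, gain.

    The combined channel is re-segmented and re-estimated with the same
    configuration so the gain compares like with like.
    """
    if recording.n_channels != 2:
        raise InvalidConfigurationError(
            "bilateral processing needs a 2-channel recording")
    results, segs = session_snr(recording, config)
    left, right = results["left"], results["right"]
    alignment = estimate_delay(
        recording.channel("left"), recording.channel("right"),
        recording.rate, max_lag=config.max_lag,
        active_intervals=segs["left"].intervals(PHASE_ACTIVE, usable_only=True),
        snr_left=left.snr_linear, snr_right=right.snr_linear)
    combined = combine_bilateral(recording.channel("left"),
                                 recording.channel("right"), alignment,
                                 incoherence_threshold=config.incoherence_threshold)
    from .segment import segment_session

    comb_segs = segment_session(combined, recording.rate, config,
                                motion_trace=recording.motion,
                                motion_rate=recording.motion_rate)
    comb_res = channel_snr(combined, recording.rate, comb_segs, config,
                           channel="combined")
    if alignment.peak_correlation < config.incoherence_threshold:
        import dataclasses

        comb_res = dataclasses.replace(comb_res, low_confidence=True)
    gain = array_gain_db(comb_res, left, right)
    return BilateralResult(left=left, right=right, combined=comb_res,
                           alignment=alignment, gain_db=gain)
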