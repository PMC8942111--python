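"""The breathing-intensity metric: band-limited signal-to-noise ratio.

SNR_dB = 10 log10(P_S / P_N) = P_S,dB - P_N,dB, where P_S is the breath
signal power during breathing activity and P_N the noise power (ambient
background plus obstruction-turbulence noise).  Obstructed airflow induces
acoustic turbulence that is counted as noise, so greater obstruction lowers
the SNR — the metric's clinical rationale.

Operationally P_N is estimated from the quiet (no-airflow) intervals of the
session, which observe the ambient noise alone; the active-interval band
power minus that ambient estimate gives P_S.  Turbulence that coincides
with airflow is therefore attributed to the active-interval power; under
the severity model in :mod:`breathsnr.synth` (obstruction weakens the
transmitted breath sound while injecting broader-band turbulence) the
estimate still decreases monotonically with obstruction, as the metric
intends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .errors import BandMismatchError, InsufficientDataError, InvalidConfigurationError
from .recording import Recording
from .segment import PHASE_ACTIVE, PHASE_QUIET, SegmentLabel, segment_session
from .spectral import band_power, welch_psd

#: floor on P_S as a fraction of P_N, so subtraction never goes negative
EPSILON_SIGNAL = 1e-6


@dataclass(frozen=True)
class SnrResult:
    """Signal power, noise power and SNR for one channel of one session."""

    p_signal: float              # watts, >= 0
    p_noise: float               # watts, > 0
    snr_db: float                # = p_signal_db - p_noise_db, capped
    band: tuple[float, float]    # Hz
    n_active: int = 0
    n_quiet: int = 0
    n_rejected: int = 0
    channel: str = ""            # 'left' | 'right' | 'combined'
    low_confidence: bool = False

    @property
    def p_signal_db(self) -> float:
        return 10.0 * math.log10(max(self.p_signal, 1e-300))

    @property
    def p_noise_db(self) -> float:
        return 10.0 * math.log10(self.p_noise)

    @property
    def snr_linear(self) -> float:
        return 10.0 ** (self.snr_db / 10.0)


def snr_db(p_signal: float, p_noise: float, cap: float = 60.0) -> float:
    """10 log10(P_S / P_N), capped to [-cap, +cap] dB.

    P_N must be strictly positive; P_S = 0 returns the cap floor.
    """
    if p_noise <= 0.0:
        raise InvalidConfigurationError("noise power must be strictly positive")
    if p_signal < 0.0:
        raise InvalidConfigurationError("signal power must be >= 0")
    if p_signal == 0.0:
        return -cap
    return float(np.clip(10.0 * math.log10(p_signal / p_noise), -cap, cap))


def _concat(waveform: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    if len(intervals) == 0:
        return np.empty(0)
    return np.concatenate([waveform[s:e] for s, e in intervals])


def estimate_powers(waveform: np.ndarray, rate: float, segments: SegmentLabel,
                    band: tuple[float, float] = (100.0, 1000.0),
                    include_deep: bool = True,
                    welch_segment: float = 1.0,
                    welch_overlap: float = 0.5) -> tuple[float, float]:
    """Estimate (P_S, P_N) in watts over the analysis band.

    P_N is the band power of the concatenated non-rejected quiet intervals
    (ambient-noise proxy).  P_S is the band power of the concatenated
    non-rejected active intervals minus P_N, floored at
    ``EPSILON_SIGNAL * P_N`` so the subtraction is never negative.
    """
    x = np.asarray(waveform, dtype=np.float64).ravel()
    quiet = segments.intervals(PHASE_QUIET, usable_only=True)
    active = segments.intervals(PHASE_ACTIVE, usable_only=True,
                                include_deep=include_deep)
    if len(quiet) == 0:
        raise InsufficientDataError(
            "no usable quiet interval to estimate the noise power from")
    if len(active) == 0:
        raise InsufficientDataError(
            "no usable breath-active interval to estimate the signal power from")
    xq, xa = _concat(x, quiet), _concat(x, active)
    p_noise = band_power(welch_psd(xq, rate, segment_length=welch_segment,
                                   overlap_fraction=welch_overlap), band)
    p_raw = band_power(welch_psd(xa, rate, segment_length=welch_segment,
                                 overlap_fraction=welch_overlap), band)
    p_noise = max(p_noise, 1e-300)
    p_signal = max(p_raw - p_noise, EPSILON_SIGNAL * p_noise)
    return p_signal, p_noise


def channel_snr(waveform: np.ndarray, rate: float, segments: SegmentLabel,
                config: AnalysisConfig = AnalysisConfig(),
                channel: str = "") -> SnrResult:
    """SNR of one channel given an existing segmentation."""
    p_s, p_n = estimate_powers(waveform, rate, segments, band=config.band,
                               include_deep=config.include_deep,
                               welch_segment=config.welch_segment,
                               welch_overlap=config.welch_overlap)
    n_active = len(segments.intervals(PHASE_ACTIVE, usable_only=True,
                                      include_deep=config.include_deep))
    return SnrResult(
        p_signal=p_s, p_noise=p_n,
        snr_db=snr_db(p_s, p_n, cap=config.snr_cap_db),
        band=config.band,
        n_active=n_active,
        n_quiet=len(segments.intervals(PHASE_QUIET, usable_only=True)),
        n_rejected=segments.n_rejected,
        channel=channel,
        low_confidence=n_active < 2,
    )


def session_snr(recording: Recording,
                config: AnalysisConfig = AnalysisConfig(),
                ) -> tuple[dict[str, SnrResult], dict[str, SegmentLabel]]:
    """Run the full per-channel pipeline on a recording.

    Envelope -> activity detection -> depth classification -> motion gating
    -> power estimation -> SNR, independently per channel.  Returns the
    per-channel results and the segmentations they used.
    """
    results: dict[str, SnrResult] = {}
    segmentations: dict[str, SegmentLabel] = {}
    for ch in range(recording.n_channels):
        side = recording.sides[ch]
        x = recording.data[:, ch]
        try:
            segs = segment_session(x, recording.rate, config,
                                   motion_trace=recording.motion,
                                   motion_rate=recording.motion_rate)
            results[side] = channel_snr(x, recording.rate, segs, config,
                                        channel=side)
            segmentations[side] = segs
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"channel {side!r}: {exc}") from exc
    return results, segmentations
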