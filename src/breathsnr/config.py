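"""Analysis configuration.

One dataclass carries every tunable of the session pipeline (segmentation,
spectral estimation, SNR, bilateral combination) so that a whole analysis is
reproducible from a single YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidConfigurationError

#: Default auscultation analysis band for breath sounds, Hz.
BREATH_BAND: tuple[float, float] = (100.0, 1000.0)

#: Typical band of the S1/S2 heart sounds, Hz.
HEART_BAND: tuple[float, float] = (20.0, 150.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunables of the recording -> SNR pipeline.

    Attributes
    ----------
    band:
        Analysis band in Hz over which all signal/noise powers are integrated.
        Defaults to the breath-sound band 100-1000 Hz, which excludes DC drift
        and most heart-sound energy.
    frame, hop:
        RMS-envelope frame length and hop, seconds.
    hi_threshold, lo_threshold:
        Hysteresis thresholds for breath-activity detection, as multiples of
        the robust envelope noise floor.  Enter *active* above ``hi``, leave
        below ``lo``.
    min_interval:
        Minimum duration of a detected interval, seconds; shorter active
        intervals are dropped, shorter quiet gaps are bridged.
    depth_separation_db:
        Minimum two-means cluster separation (dB band power) below which all
        breaths are labelled *normal* rather than normal/deep.
    motion_threshold:
        Motion-trace gating threshold, multiples of the trace baseline RMS.
    welch_segment, welch_overlap:
        Welch PSD segment length (seconds) and overlap fraction.
    max_lag:
        Cross-correlation search window for bilateral alignment, seconds.
    incoherence_threshold:
        Peak normalized cross-correlation below which bilateral combination
        falls back to the best single channel.
    include_deep:
        Whether deep-breathing intervals enter the signal-power estimate.
    snr_cap_db:
        Symmetric cap on reported SNR values, dB.
    """

    band: tuple[float, float] = BREATH_BAND
    frame: float = 0.100
    hop: float = 0.025
    hi_threshold: float = 3.0
    lo_threshold: float = 1.5
    min_interval: float = 0.250
    depth_separation_db: float = 3.0
    motion_threshold: float = 5.0
    welch_segment: float = 1.0
    welch_overlap: float = 0.5
    max_lag: float = 0.050
    incoherence_threshold: float = 0.2
    include_deep: bool = True
    snr_cap_db: float = 60.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0.0 <= lo < hi):
            raise InvalidConfigurationError(f"invalid analysis band {self.band}")
        if not (0.0 < self.hop <= self.frame):
            raise InvalidConfigurationError("require 0 < hop <= frame")
        if not (self.hi_threshold > self.lo_threshold > 1.0):
            raise InvalidConfigurationError(
                "require hi_threshold > lo_threshold > 1"
            )
        if not (0.0 <= self.welch_overlap < 1.0):
            raise InvalidConfigurationError("welch_overlap must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(float(v) for v in raw["band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["band"] = list(self.band)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
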