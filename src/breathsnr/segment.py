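"""Breathing-phase segmentation and motion-artifact gating.

The pipeline partitions a recording into breath-active vs quiet intervals
with an RMS-envelope hysteresis detector, classifies active intervals into
normal vs deep breaths by relative band power, and flags intervals that
overlap motion-trace excursions.  Intervals are half-open 0-based sample
ranges that always tile the recording exactly; motion gating only flags
intervals, it never deletes samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import InvalidConfigurationError
from .spectral import band_power, welch_psd

log = logging.getLogger(__name__)

PHASE_ACTIVE = "active"
PHASE_QUIET = "quiet"
DEPTH_NORMAL = "normal"
DEPTH_DEEP = "deep"
DEPTH_NA = "n/a"


@dataclass
class SegmentLabel:
    """A tiling of ``[0, n_samples)`` into labelled intervals.

    ``starts``/``ends`` are half-open sample indices; ``phase`` is
    'active'/'quiet' per interval; ``depth`` is 'normal'/'deep' for active
    intervals and 'n/a' otherwise; ``motion_rejected`` flags intervals
    contaminated by body movement.
    """

    starts: np.ndarray
    ends: np.ndarray
    phase: np.ndarray
    depth: np.ndarray
    motion_rejected: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.phase = np.asarray(self.phase, dtype=object)
        self.depth = np.asarray(self.depth, dtype=object)
        self.motion_rejected = np.asarray(self.motion_rejected, dtype=bool)
        n = len(self.starts)
        if not (len(self.ends) == len(self.phase) == len(self.depth)
                == len(self.motion_rejected) == n):
            raise InvalidConfigurationError("segment field lengths differ")
        if n == 0:
            raise InvalidConfigurationError("a segmentation needs >= 1 interval")
        if self.starts[0] != 0 or self.ends[-1] != self.n_samples:
            raise InvalidConfigurationError("intervals must span [0, n_samples)")
        if np.any(self.ends <= self.starts):
            raise InvalidConfigurationError("intervals must be non-empty")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise InvalidConfigurationError("intervals must tile without gaps")
        quiet = self.phase == PHASE_QUIET
        if np.any((self.depth != DEPTH_NA) & quiet):
            raise InvalidConfigurationError("depth defined only for active intervals")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def n_active(self) -> int:
        return int(np.sum(self.phase == PHASE_ACTIVE))

    @property
    def n_quiet(self) -> int:
        return int(np.sum(self.phase == PHASE_QUIET))

    @property
    def n_rejected(self) -> int:
        return int(np.sum(self.motion_rejected))

    def intervals(self, phase: str | None = None, *, usable_only: bool = False,
                  include_deep: bool = True) -> np.ndarray:
        """Return (k, 2) array of [start, end) pairs, optionally filtered."""
        mask = np.ones(len(self), dtype=bool)
        if phase is not None:
            mask &= self.phase == phase
        if usable_only:
            mask &= ~self.motion_rejected
        if not include_deep:
            mask &= self.depth != DEPTH_DEEP
        return np.column_stack([self.starts[mask], self.ends[mask]])

    def sample_mask(self, phase: str, *, usable_only: bool = False,
                    include_deep: bool = True) -> np.ndarray:
        """Boolean per-sample mask of the selected intervals."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for s, e in self.intervals(phase, usable_only=usable_only,
                                   include_deep=include_deep):
            mask[s:e] = True
        return mask

    def to_frame(self, subject_id: str = "", channel: str = "") -> pd.DataFrame:
        """Tabular form matching the truth-label CSV schema."""
        return pd.DataFrame({
            "subject_id": subject_id,
            "channel": channel,
            "start_sample": self.starts,
            "end_sample": self.ends,
            "phase": self.phase,
            "depth": self.depth,
            "motion_rejected": self.motion_rejected,
        })

    @classmethod
    def from_active_intervals(cls, active: np.ndarray, n_samples: int,
                              depths: list[str] | None = None) -> "SegmentLabel":
        """Build a full tiling from (k, 2) active intervals; gaps become quiet."""
        active = np.asarray(active, dtype=np.int64).reshape(-1, 2)
        starts, ends, phase, depth = [], [], [], []
        cursor = 0
        for i, (s, e) in enumerate(active):
            s, e = int(s), int(min(e, n_samples))
            if e <= s:
                continue
            if s > cursor:
                starts.append(cursor); ends.append(s)
                phase.append(PHASE_QUIET); depth.append(DEPTH_NA)
            starts.append(s); ends.append(e)
            phase.append(PHASE_ACTIVE)
            depth.append(depths[i] if depths is not None else DEPTH_NA)
            cursor = e
        if cursor < n_samples or not starts:
            starts.append(cursor); ends.append(n_samples)
            phase.append(PHASE_QUIET); depth.append(DEPTH_NA)
        return cls(starts=np.array(starts), ends=np.array(ends),
                   phase=np.array(phase, dtype=object),
                   depth=np.array(depth, dtype=object),
                   motion_rejected=np.zeros(len(starts), dtype=bool),
                   n_samples=int(n_samples))


# ---------------------------------------------------------------------------
# envelope + activity detection

def energy_envelope(waveform: np.ndarray, rate: float, frame: float = 0.100,
                    hop: float = 0.025) -> tuple[np.ndarray, np.ndarray]:
    """Short-time RMS envelope.

    Returns ``(envelope, frame_starts)`` where ``frame_starts`` are the
    0-based sample indices of each analysis frame.
    """
    x = np.asarray(waveform, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidConfigurationError("empty waveform")
    nf = int(round(frame * rate))
    nh = int(round(hop * rate))
    if not 0 < nh <= nf:
        raise InvalidConfigurationError("require 0 < hop <= frame")
    if nf >= x.size:
        raise InvalidConfigurationError("frame longer than the signal")
    csum = np.concatenate(([0.0], np.cumsum(x ** 2)))
    starts = np.arange(0, x.size - nf + 1, nh)
    env = np.sqrt((csum[starts + nf] - csum[starts]) / nf)
    return env, starts


def noise_floor(envelope: np.ndarray) -> float:
    """Robust envelope noise floor: median of the lowest-quartile frames."""
    env = np.sort(np.asarray(envelope, dtype=np.float64).ravel())
    k = max(1, env.size // 4)
    return float(np.median(env[:k]))


def detect_activity(envelope: np.ndarray, frame_starts: np.ndarray,
                    n_samples: int, rate: float,
                    hi_threshold: float = 3.0, lo_threshold: float = 1.5,
                    min_interval: float = 0.250,
                    hop: float = 0.025) -> SegmentLabel:
    """Hysteresis activity detection against a robust noise floor.

    Enter *active* when the envelope exceeds ``hi_threshold * floor``, leave
    when it drops below ``lo_threshold * floor``.  Active intervals shorter
    than ``min_interval`` are dropped; quiet gaps shorter than it are
    bridged.  A flat or all-quiet envelope yields one quiet interval.
    """
    if not hi_threshold > lo_threshold > 1.0:
        raise InvalidConfigurationError("require hi_threshold > lo_threshold > 1")
    env = np.asarray(envelope, dtype=np.float64).ravel()
    floor = noise_floor(env)
    if floor <= 0.0:
        # silence-dominated file: fall back to a tiny positive floor so a
        # genuinely loud portion can still trigger; an all-zero file stays quiet
        peak = float(env.max(initial=0.0))
        if peak == 0.0:
            return SegmentLabel.from_active_intervals(
                np.empty((0, 2)), n_samples)
        floor = 1e-12 * peak

    active_frames = np.zeros(env.size, dtype=bool)
    state = False
    for i, v in enumerate(env):
        if not state and v > hi_threshold * floor:
            state = True
        elif state and v < lo_threshold * floor:
            state = False
        active_frames[i] = state

    nh = int(round(hop * rate))
    edges = np.flatnonzero(np.diff(active_frames.astype(np.int8)))
    runs = []
    open_start = 0 if active_frames[0] else None
    for e in edges:
        if active_frames[e]:          # active -> quiet after frame e
            runs.append((open_start, e + 1))
            open_start = None
        else:
            open_start = e + 1
    if open_start is not None:
        runs.append((open_start, env.size))

    # frame runs -> half-open sample intervals
    intervals = []
    for f0, f1 in runs:
        s = int(frame_starts[f0])
        e = int(frame_starts[f1 - 1] + nh) if f1 < env.size else n_samples
        intervals.append([s, min(e, n_samples)])

    min_n = int(round(min_interval * rate))
    # bridge short quiet gaps, then drop short active intervals
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < min_n:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    kept = [iv for iv in merged if iv[1] - iv[0] >= min_n]
    return SegmentLabel.from_active_intervals(np.array(kept).reshape(-1, 2),
                                              n_samples)


# ---------------------------------------------------------------------------
# depth classification

def _two_means_1d(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact 1-D two-means by exhaustive sorted-split search.

    Returns (boolean mask of the upper cluster, separation of cluster means).
    Ties between splits are broken toward the split with the smallest
    within-cluster sum of squares, which the exhaustive search does by
    construction (first minimum wins, i.e. the smaller upper cluster).
    """
    v = np.asarray(values, dtype=np.float64)
    order = np.argsort(v)
    sv = v[order]
    n = v.size
    best_cost, best_k = np.inf, 1
    csum = np.concatenate(([0.0], np.cumsum(sv)))
    csum2 = np.concatenate(([0.0], np.cumsum(sv ** 2)))
    for k in range(1, n):                      # lower cluster = sv[:k]
        lo_ss = csum2[k] - csum[k] ** 2 / k
        hi_ss = (csum2[n] - csum2[k]) - (csum[n] - csum[k]) ** 2 / (n - k)
        cost = lo_ss + hi_ss
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    upper = np.zeros(n, dtype=bool)
    upper[order[best_k:]] = True
    sep = float(v[upper].mean() - v[~upper].mean())
    return upper, sep


def classify_depth(waveform: np.ndarray, rate: float, segments: SegmentLabel,
                   band: tuple[float, float] = (100.0, 1000.0),
                   separation_db: float = 3.0,
                   welch_segment: float = 1.0,
                   welch_overlap: float = 0.5) -> SegmentLabel:
    """Label active intervals normal vs deep by relative band power.

    Per-interval dB band powers are split by exact 1-D two-means; the
    higher-power cluster is *deep*.  If the cluster-mean separation is below
    ``separation_db`` (or there is a single active interval), every active
    interval is labelled conservatively: 'normal' for >= 2 intervals, 'n/a'
    for a single one.  Classification is relative within the session because
    absolute levels depend on sensor coupling and fabric.
    """
    x = np.asarray(waveform, dtype=np.float64).ravel()
    idx = np.flatnonzero(segments.phase == PHASE_ACTIVE)
    depth = segments.depth.copy()
    if idx.size == 0:
        return replace(segments, depth=depth)
    if idx.size == 1:
        depth[idx[0]] = DEPTH_NA
        return replace(segments, depth=depth)
    powers_db = np.empty(idx.size)
    for j, i in enumerate(idx):
        seg = x[segments.starts[i]:segments.ends[i]]
        # short truncated intervals get a proportionally shorter Welch segment
        seg_len = min(welch_segment, max(seg.size / rate, 8.0 / rate))
        ps = welch_psd(seg, rate, segment_length=seg_len,
                       overlap_fraction=welch_overlap)
        powers_db[j] = 10.0 * np.log10(max(band_power(ps, band), 1e-300))
    upper, sep = _two_means_1d(powers_db)
    if sep < separation_db:
        depth[idx] = DEPTH_NORMAL
    else:
        depth[idx[upper]] = DEPTH_DEEP
        depth[idx[~upper]] = DEPTH_NORMAL
    return replace(segments, depth=depth)


# ---------------------------------------------------------------------------
# motion gating

def motion_gate(segments: SegmentLabel, motion_trace: np.ndarray | None,
                motion_rate: float, audio_rate: float,
                threshold: float = 5.0) -> SegmentLabel:
    """Flag intervals overlapping motion-trace excursions.

    The trace baseline RMS is estimated robustly (1.4826 * MAD about the
    median); any interval containing a motion sample whose deviation from
    the median exceeds ``threshold * baseline`` is flagged
    ``motion_rejected``.  A non-positive threshold rejects everything.
    Gating is idempotent and only sets flags; the tiling is unchanged.
    """
    if motion_trace is None:
        log.warning("no motion trace supplied; motion gating skipped")
        return replace(segments, motion_rejected=segments.motion_rejected.copy())
    trace = np.asarray(motion_trace, dtype=np.float64).ravel()
    rejected = segments.motion_rejected.copy()
    if threshold <= 0:
        rejected[:] = True
        return replace(segments, motion_rejected=rejected)
    dev = np.abs(trace - np.median(trace))
    baseline = 1.4826 * float(np.median(dev))
    if baseline <= 0.0:
        baseline = max(1e-12 * float(dev.max(initial=0.0)), 1e-300)
    exceed = np.flatnonzero(dev > threshold * baseline)
    if exceed.size:
        # motion sample k covers audio samples [k, k+1) / motion_rate
        lo = exceed * audio_rate / motion_rate
        hi = (exceed + 1) * audio_rate / motion_rate
        for i in range(len(segments)):
            s, e = segments.starts[i], segments.ends[i]
            if np.any((hi > s) & (lo < e)):
                rejected[i] = True
    return replace(segments, motion_rejected=rejected)


def segment_session(waveform: np.ndarray, rate: float,
                    config: AnalysisConfig = AnalysisConfig(),
                    motion_trace: np.ndarray | None = None,
                    motion_rate: float | None = None) -> SegmentLabel:
    """Full segmentation pipeline for one channel.

    Envelope (on the band-passed signal) -> hysteresis activity detection ->
    depth classification -> motion gating.
    """
    from .spectral import bandpass

    x = np.asarray(waveform, dtype=np.float64).ravel()
    xb = bandpass(x, rate, config.band)
    env, starts = energy_envelope(xb, rate, frame=config.frame, hop=config.hop)
    segs = detect_activity(env, starts, x.size, rate,
                           hi_threshold=config.hi_threshold,
                           lo_threshold=config.lo_threshold,
                           min_interval=config.min_interval, hop=config.hop)
    segs = classify_depth(x, rate, segs, band=config.band,
                          separation_db=config.depth_separation_db,
                          welch_segment=config.welch_segment,
                          welch_overlap=config.welch_overlap)
    if motion_trace is not None and motion_rate is not None:
        segs = motion_gate(segs, motion_trace, motion_rate, rate,
                           threshold=config.motion_threshold)
    return segs
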