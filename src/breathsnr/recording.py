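"""In-memory audio container and WAV / CSV I/O.

A :class:`Recording` holds one or two channels of chest-wall audio sampled at
a common rate, with an optional synchronized motion trace (one scalar per
motion frame, typically from an accelerometer or posture sensor at a much
lower rate than the audio).

WAV files are read and written with :mod:`scipy.io.wavfile`; integer PCM is
rescaled to float in [-1, 1] on load, and recordings are written as float32.
Channel 0 is the left thorax, channel 1 the right thorax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import InvalidConfigurationError

#: channel index -> anatomical side for stereo chest recordings
CHANNEL_SIDES = ("left", "right")


@dataclass
class Recording:
    """Sampled chest-wall audio with optional motion trace.

    ``data`` has shape ``(n_samples, n_channels)`` with 1 or 2 channels;
    ``sides`` maps each channel to an anatomical side label.
    """

    data: np.ndarray
    rate: float
    sides: tuple[str, ...] = CHANNEL_SIDES
    motion: np.ndarray | None = None
    motion_rate: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.ndim != 2 or not 1 <= self.data.shape[1] <= 2:
            raise InvalidConfigurationError(
                f"expected (n, 1) or (n, 2) audio, got shape {self.data.shape}"
            )
        if self.rate <= 0:
            raise InvalidConfigurationError("sampling rate must be positive")
        self.sides = tuple(self.sides[: self.data.shape[1]])
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=np.float64).ravel()
            if self.motion_rate is None or self.motion_rate <= 0:
                raise InvalidConfigurationError(
                    "motion trace requires a positive motion_rate"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel by index or by side name ('left'/'right')."""
        if isinstance(which, str):
            if which not in self.sides:
                raise KeyError(f"no channel labelled {which!r} in {self.sides}")
            which = self.sides.index(which)
        return self.data[:, which]


def write_wav(path: str | Path, recording: Recording) -> None:
    """Write a recording as float32 WAV (channel 0 = left thorax)."""
    wavfile.write(str(path), int(round(recording.rate)),
                  recording.data.astype(np.float32))


def read_wav(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read a mono or stereo WAV file; integer PCM is scaled to [-1, 1]."""
    rate, data = wavfile.read(str(path))
    data = np.atleast_2d(np.asarray(data))
    if data.shape[0] == 1:            # mono came back as (n,) -> (1, n)
        data = data.T
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(np.float64) / scale
    sid = subject_id if subject_id is not None else Path(path).stem
    return Recording(data=data, rate=float(rate), subject_id=sid)


def write_motion_csv(path: str | Path, motion: np.ndarray,
                     motion_rate: float) -> None:
    """Write a motion trace as a two-column CSV (time_s, value)."""
    t = np.arange(len(motion)) / motion_rate
    pd.DataFrame({"time_s": t, "value": motion}).to_csv(path, index=False)


def read_motion_csv(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a motion-trace CSV; returns (values, inferred rate in Hz)."""
    df = pd.read_csv(path)
    if "value" not in df.columns:
        raise InvalidConfigurationError(
            f"motion CSV {path} must have a 'value' column"
        )
    values = df["value"].to_numpy(dtype=np.float64)
    if "time_s" in df.columns and len(df) > 1:
        dt = float(np.median(np.diff(df["time_s"].to_numpy())))
        if dt <= 0:
            raise InvalidConfigurationError("motion timestamps must increase")
        rate = 1.0 / dt
    else:
        raise InvalidConfigurationError("motion CSV needs a 'time_s' column")
    return values, rate
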