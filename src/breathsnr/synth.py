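"""Synthetic bilateral lung-sound generator with ground-truth bookkeeping.

The generator realizes the received-signal model of a two-sensor chest
array: each thorax channel is the breath source convolved with a sparse
multipath filter (attenuation/delay taps), attenuated by fabric, plus
additive noise.  Noise has two parts: ambient background noise (always on,
broadband white) and obstruction-turbulence noise (band-limited, present
only while air is flowing, i.e. during breath-active intervals).

Severity model
--------------
Airflow obstruction has two acoustic consequences, both tied to the 1-10
health-scale score (10 = excellent health):

* turbulence noise power rises by 2 dB per health-scale step toward poor
  health (``default_turbulence_power``);
* the clean breath sound transmitted to the chest wall weakens (diminished
  breath sounds), by default spanning 16 dB across the scale
  (``default_breath_gain_db``).

Under this pairing both the ground-truth SNR and the quiet-interval SNR
estimate decrease monotonically with severity.  Turbulence occupies
100-1900 Hz — overlapping the 100-1000 Hz breath analysis band but broader,
as physical flow turbulence is.

Every simulated subject carries ground truth: the exact active/quiet
segmentation, the clean and noise waveform components, and per-channel SNR
computed from those components in the analysis band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import windows

from .config import BREATH_BAND
from .errors import InvalidConfigurationError
from .recording import Recording, write_motion_csv, write_wav
from .segment import DEPTH_DEEP, DEPTH_NORMAL, SegmentLabel
from .spectral import bandpass

log = logging.getLogger(__name__)

DEFAULT_RATE = 4000.0
#: obstruction turbulence band, Hz (overlaps but exceeds the breath band)
TURBULENCE_BAND = (100.0, 1900.0)
#: turbulence power at health scale 1, watts
TURBULENCE_P1 = 7.5e-3
#: turbulence power decrease per health-scale step, dB
TURBULENCE_SLOPE_DB = 2.0
#: clean breath-sound attenuation span across the health scale, dB
BREATH_SPAN_DB = 16.0
#: default ambient (background) noise power, watts
DEFAULT_AMBIENT_POWER = 0.01
#: SNR reported instead of +/- infinity in noise-free / signal-free limits, dB
SNR_CAP_DB = 60.0


def default_turbulence_power(health_scale: int) -> float:
    """Turbulence noise power (watts) for a 1-10 health scale.

    Strictly decreasing in health: 2 dB per step, anchored at
    ``TURBULENCE_P1`` for the sickest score.
    """
    return TURBULENCE_P1 * 10.0 ** (-(health_scale - 1) * TURBULENCE_SLOPE_DB / 10.0)


def default_breath_gain_db(health_scale: int) -> float:
    """Clean breath-sound gain (dB, <= 0) for a 1-10 health scale.

    0 dB at excellent health, ``-BREATH_SPAN_DB`` at the sickest score;
    models the diminished breath sounds of obstructed airflow.
    """
    return -(10 - health_scale) * BREATH_SPAN_DB / 9.0


@dataclass(frozen=True)
class BreathProgram:
    """A breathing-exercise protocol: rate, phase split and depth sequence.

    ``depth_sequence`` is an ordered list of (depth, duration_s) blocks with
    depth in {'normal', 'deep'}; within each block, breath cycles of period
    60/breath_rate start at the block boundary.  ``active_fraction`` of each
    cycle carries airflow sound (inspiration then expiration), the rest is
    the inter-breath pause.
    """

    breath_rate: float = 15.0                    # breaths / minute
    inspiration_fraction: float = 0.4            # of the active window
    depth_sequence: tuple[tuple[str, float], ...] = (
        ("normal", 40.0), ("deep", 20.0),
        ("normal", 40.0), ("deep", 20.0),
        ("normal", 40.0), ("deep", 20.0),
        ("normal", 40.0), ("deep", 20.0),
    )
    depth_gain_db: float = 6.0                   # deep over normal, amplitude dB
    active_fraction: float = 0.7                 # of each breath cycle

    def __post_init__(self) -> None:
        if self.breath_rate <= 0:
            raise InvalidConfigurationError("breath_rate must be positive")
        if not 0.0 < self.inspiration_fraction < 1.0:
            raise InvalidConfigurationError(
                "inspiration_fraction must be strictly between 0 and 1")
        if not 0.0 < self.active_fraction < 1.0:
            raise InvalidConfigurationError(
                "active_fraction must be strictly between 0 and 1")
        if not self.depth_sequence:
            raise InvalidConfigurationError("depth_sequence must be non-empty")
        for depth, dur in self.depth_sequence:
            if depth not in (DEPTH_NORMAL, DEPTH_DEEP):
                raise InvalidConfigurationError(f"unknown depth {depth!r}")
            if dur <= 0:
                raise InvalidConfigurationError("block durations must be positive")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.depth_sequence))

    @classmethod
    def default(cls) -> "BreathProgram":
        """The standard ~4-minute normal/deep alternating session."""
        return cls()

    @classmethod
    def short(cls, normal: float = 16.0, deep: float = 8.0) -> "BreathProgram":
        """A reduced-duration session with one normal and one deep block."""
        return cls(depth_sequence=(("normal", normal), ("deep", deep)))


@dataclass(frozen=True)
class ChannelModel:
    """Multipath + noise model of one chest-wall acoustic channel pair.

    ``taps_left`` / ``taps_right`` are (attenuation, delay_s) pairs of the
    sparse impulse responses shaping the breath source into the received
    left/right signals.  ``fabric_attenuation_db`` is a broadband loss from
    material between sensor and skin (applied to the breath signal before
    noise is added, so ambient noise is unattenuated).  Noise powers are
    variances in watts; turbulence noise is injected only while air flows.
    """

    taps_left: tuple[tuple[float, float], ...] = ((1.0, 0.0), (0.35, 0.004))
    taps_right: tuple[tuple[float, float], ...] = ((1.0, 0.00075), (0.30, 0.005))
    fabric_attenuation_db: float = 0.0
    ambient_noise_power: float = DEFAULT_AMBIENT_POWER
    turbulence_noise_power: float = 0.0
    turbulence_band: tuple[float, float] = TURBULENCE_BAND

    def __post_init__(self) -> None:
        for taps in (self.taps_left, self.taps_right):
            if len(taps) < 1:
                raise InvalidConfigurationError("each side needs >= 1 filter tap")
            for gain, delay in taps:
                if gain <= 0:
                    raise InvalidConfigurationError("tap attenuations must be > 0")
                if delay < 0:
                    raise InvalidConfigurationError("tap delays must be >= 0")
        if self.ambient_noise_power < 0 or self.turbulence_noise_power < 0:
            raise InvalidConfigurationError("noise powers must be >= 0")

    def taps(self, side: str) -> tuple[tuple[float, float], ...]:
        if side == "left":
            return self.taps_left
        if side == "right":
            return self.taps_right
        raise InvalidConfigurationError(f"side must be 'left'/'right', got {side!r}")


@dataclass(frozen=True)
class SimSubject:
    """One simulated participant.

    ``turbulence_noise_power`` and ``breath_gain_db`` default to the
    health-scale severity maps when left as ``None``.
    """

    subject_id: str
    health_scale: int
    group: str = "healthy"                      # 'healthy' | 'copd'
    turbulence_noise_power: float | None = None
    breath_gain_db: float | None = None
    seed: int = 0
    age: int | None = None
    gender: str | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.health_scale, (int, np.integer))
                and 1 <= self.health_scale <= 10):
            raise InvalidConfigurationError("health_scale must be an int in 1..10")
        if self.group not in ("healthy", "copd"):
            raise InvalidConfigurationError("group must be 'healthy' or 'copd'")

    @property
    def turbulence_power(self) -> float:
        if self.turbulence_noise_power is not None:
            return self.turbulence_noise_power
        return default_turbulence_power(self.health_scale)

    @property
    def breath_gain(self) -> float:
        if self.breath_gain_db is not None:
            return self.breath_gain_db
        return default_breath_gain_db(self.health_scale)


@dataclass
class SimOutput:
    """A simulated session together with its ground truth."""

    subject: SimSubject
    recording: Recording
    truth_segments: SegmentLabel
    truth_snr_db: dict[str, float]
    truth_powers: dict[str, tuple[float, float]]   # side -> (P_S, P_N), watts
    motion_burst_times: list[tuple[float, float]] = field(default_factory=list)
    components: dict[str, dict[str, np.ndarray]] | None = None


# ---------------------------------------------------------------------------
# breath source

def _breath_envelope(program: BreathProgram, rate: float
                     ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Amplitude envelope plus truth active intervals and their depths."""
    n_total = int(round(program.total_duration * rate))
    env = np.zeros(n_total)
    period = 60.0 / program.breath_rate
    intervals: list[tuple[int, int]] = []
    depths: list[str] = []
    block_start = 0.0
    for depth, dur in program.depth_sequence:
        gain = 10.0 ** (program.depth_gain_db / 20.0) if depth == DEPTH_DEEP else 1.0
        block_end = block_start + dur
        t = block_start
        while t < block_end - 1e-9:
            a0 = t
            a1 = min(t + program.active_fraction * period, block_end)
            s0 = int(round(a0 * rate))
            s1 = min(int(round(a1 * rate)), n_total)
            if s1 - s0 >= 2:
                m = s1 - s0
                # tapered burst (smooth on/off ramps) with a slightly quieter
                # expiration phase after the inspiration fraction
                bump = windows.tukey(m, alpha=0.3)
                u = np.linspace(0.0, 1.0, m)
                fi = program.inspiration_fraction
                expir = 1.0 - 0.15 / (1.0 + np.exp(-(u - fi) / 0.02))
                env[s0:s1] = gain * bump * expir
                intervals.append((s0, s1))
                depths.append(depth)
            t += period
        block_start = block_end
    return env, np.array(intervals, dtype=np.int64).reshape(-1, 2), depths


def simulate_breath_source(program: BreathProgram,
                           band: tuple[float, float] = BREATH_BAND,
                           rate: float = DEFAULT_RATE,
                           seed: int = 0,
                           amplitude: float = 1.0,
                           ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Generate the breath-sound source waveform l(t) (or r(t)).

    Band-limited unit-variance noise amplitude-modulated by a smooth breath
    envelope: tapered bursts during inspiration/expiration, near-silence in
    the inter-breath pauses, deep blocks boosted by ``depth_gain_db``.

    Returns
    -------
    waveform, active_intervals, depths:
        The source signal, (k, 2) half-open sample intervals of the
        breath-active windows, and the per-interval depth labels.
    """
    if rate <= 0:
        raise InvalidConfigurationError("rate must be positive")
    if not 0.0 <= band[0] < band[1] < rate / 2.0:
        raise InvalidConfigurationError(
            f"band {band} must lie strictly inside the Nyquist range")
    env, intervals, depths = _breath_envelope(program, rate)
    rng = np.random.default_rng(seed)
    carrier = bandpass(rng.standard_normal(env.size), rate, band)
    carrier /= max(float(np.std(carrier)), 1e-300)
    return amplitude * env * carrier, intervals, depths


# ---------------------------------------------------------------------------
# channel

def _delay_taps(source: np.ndarray, taps, rate: float) -> np.ndarray:
    out = np.zeros_like(source)
    for gain, delay in taps:
        d = int(round(delay * rate))
        if d >= source.size:
            raise InvalidConfigurationError(
                f"tap delay {delay} s exceeds the signal duration")
        if d == 0:
            out += gain * source
        else:
            out[d:] += gain * source[:-d]
    return out


def _active_mask(n: int, intervals: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
        mask[s:e] = True
    return mask


def _channel_components(source: np.ndarray, model: ChannelModel, side: str,
                        breath_active: np.ndarray, rate: float, seed: int,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Return (clean, noise) components of the received signal.

    clean = fabric-attenuated multipath sum of the source; noise = ambient
    white noise everywhere + band-limited turbulence inside active windows.
    """
    clean = _delay_taps(np.asarray(source, dtype=np.float64), model.taps(side), rate)
    clean *= 10.0 ** (-model.fabric_attenuation_db / 20.0)
    rng = np.random.default_rng(seed)
    noise = np.zeros_like(clean)
    if model.ambient_noise_power > 0:
        noise += rng.normal(0.0, np.sqrt(model.ambient_noise_power), clean.size)
    if model.turbulence_noise_power > 0:
        turb = bandpass(rng.standard_normal(clean.size), rate,
                        model.turbulence_band)
        turb /= max(float(np.std(turb)), 1e-300)
        turb *= np.sqrt(model.turbulence_noise_power)
        turb[~_active_mask(clean.size, breath_active)] = 0.0
        noise += turb
    return clean, noise


def apply_channel(source: np.ndarray, model: ChannelModel, side: str,
                  breath_active: np.ndarray, rate: float = DEFAULT_RATE,
                  seed: int = 0) -> np.ndarray:
    """Pass the breath source through one chest channel.

    Output = sum_j A_j * source(t - tau_j), fabric-attenuated, plus ambient
    noise everywhere and turbulence noise inside the breath-active windows.
    Delays are rounded to the nearest integer sample; the convolution tail
    is truncated so output length equals input length.
    """
    clean, noise = _channel_components(source, model, side, breath_active,
                                       rate, seed)
    return clean + noise


# ---------------------------------------------------------------------------
# heart sounds

def heart_sound_train(n_samples: int, rate: float, heart_rate: float = 70.0,
                      amplitude: float = 0.25, seed: int | None = None
                      ) -> np.ndarray:
    """Periodic S1/S2-like transients: two damped tone bursts per cycle.

    S1 (~45 Hz, stronger, longer) at each cycle onset, S2 (~65 Hz, weaker,
    shorter) at 35% of the cycle.  ``seed`` adds a small (< 2% of cycle)
    timing jitter; ``None`` gives a perfectly periodic train.
    """
    if heart_rate <= 0:
        raise InvalidConfigurationError("heart_rate must be positive")
    train = np.zeros(n_samples)
    if amplitude == 0.0:
        return train
    period = 60.0 / heart_rate
    rng = np.random.default_rng(seed) if seed is not None else None

    def burst(freq: float, dur: float, amp: float) -> np.ndarray:
        m = int(round(dur * rate))
        t = np.arange(m) / rate
        return amp * np.sin(2 * np.pi * freq * t) * np.exp(-t / (dur / 4.0))

    s1 = burst(45.0, 0.12, amplitude)
    s2 = burst(65.0, 0.09, 0.6 * amplitude)
    t0 = 0.0
    while t0 * rate < n_samples:
        jitter = 0.0 if rng is None else float(rng.normal(0.0, 0.015 * period))
        for offset, b in ((0.0, s1), (0.35 * period, s2)):
            i = int(round((t0 + offset + jitter) * rate))
            if 0 <= i < n_samples:
                j = min(i + b.size, n_samples)
                train[i:j] += b[: j - i]
        t0 += period
    return train


def add_heart_sounds(waveform: np.ndarray, rate: float,
                     heart_rate: float = 70.0, amplitude: float = 0.25,
                     seed: int | None = None) -> np.ndarray:
    """Superimpose an S1/S2 heart-sound train (left-thorax contamination)."""
    x = np.asarray(waveform, dtype=np.float64)
    if amplitude == 0.0:
        return x.copy()
    return x + heart_sound_train(x.size, rate, heart_rate=heart_rate,
                                 amplitude=amplitude, seed=seed)


# ---------------------------------------------------------------------------
# subject + cohort

MOTION_RATE = 50.0            # Hz of the simulated motion trace
MOTION_BASELINE_STD = 0.02    # baseline motion-trace noise
MOTION_SPIKE_AMPLITUDE = 0.4  # >> 5x baseline RMS
MOTION_BURST_DURATION = 0.3   # seconds


def _banded_power(x: np.ndarray, rate: float, band, mask: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    return float(np.mean(bandpass(x, rate, band)[mask] ** 2))


def _truth_snr(p_s: float, p_n: float, cap: float = SNR_CAP_DB) -> float:
    if p_n <= 0.0:
        return cap if p_s > 0 else -cap
    if p_s <= 0.0:
        return -cap
    return float(np.clip(10.0 * np.log10(p_s / p_n), -cap, cap))


def simulate_subject(subject: SimSubject,
                     program: BreathProgram | None = None,
                     left_model: ChannelModel | None = None,
                     right_model: ChannelModel | None = None,
                     rate: float = DEFAULT_RATE,
                     band: tuple[float, float] = BREATH_BAND,
                     heart_amplitude: float = 0.25,
                     heart_rate: float = 70.0,
                     heart_counts_as_signal: bool = True,
                     motion_burst_count: int | None = None,
                     keep_components: bool = True,
                     ) -> SimOutput:
    """Simulate one bilateral session with full ground truth.

    Both channels share the breath source (coherent by construction, so
    cross-channel alignment is well-posed) but have independent noise and
    distinct multipath taps.  Heart sounds contaminate the left channel; by
    default they count toward the truth signal power
    (``heart_counts_as_signal``), mirroring the elevated left-thorax SNR
    seen over the heart.  ``motion_burst_count=None`` draws 0-3 artifact
    bursts (simultaneous audio thump + motion-trace spike) at random times.
    """
    program = program or BreathProgram.default()
    turb = subject.turbulence_power
    if left_model is None:
        left_model = ChannelModel(turbulence_noise_power=turb)
    if right_model is None:
        right_model = ChannelModel(turbulence_noise_power=turb)

    ss = np.random.SeedSequence(subject.seed)
    seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(5)]
    amp = 10.0 ** (subject.breath_gain / 20.0)
    source, active, depths = simulate_breath_source(
        program, band=band, rate=rate, seed=seeds[0], amplitude=amp)
    n = source.size

    comps: dict[str, dict[str, np.ndarray]] = {}
    for side, model, chseed in (("left", left_model, seeds[1]),
                                ("right", right_model, seeds[2])):
        clean, noise = _channel_components(source, model, side, active,
                                           rate, chseed)
        comps[side] = {"clean": clean, "noise": noise}

    heart = heart_sound_train(n, rate, heart_rate=heart_rate,
                              amplitude=heart_amplitude, seed=seeds[3])
    if heart_counts_as_signal:
        comps["left"]["clean"] = comps["left"]["clean"] + heart
    else:
        comps["left"]["noise"] = comps["left"]["noise"] + heart

    # motion artifacts: audio thump on both channels + motion-trace spike
    rng = np.random.default_rng(seeds[4])
    n_bursts = (int(rng.integers(0, 4)) if motion_burst_count is None
                else int(motion_burst_count))
    burst_n = int(round(MOTION_BURST_DURATION * rate))
    motion = rng.normal(0.0, MOTION_BASELINE_STD,
                        int(round(n / rate * MOTION_RATE)))
    burst_times: list[tuple[float, float]] = []
    clean_rms = float(np.sqrt(np.mean(comps["left"]["clean"] ** 2)))
    for _ in range(n_bursts):
        s0 = int(rng.integers(0, max(1, n - burst_n)))
        thump = bandpass(rng.standard_normal(burst_n), rate, (20.0, 300.0))
        thump /= max(float(np.std(thump)), 1e-300)
        thump *= 6.0 * max(clean_rms, 1e-6) * windows.tukey(burst_n, alpha=0.5)
        for side, g in (("left", 1.0), ("right", 0.8)):
            comps[side]["noise"][s0:s0 + burst_n] += g * thump
        m0 = int(round(s0 / rate * MOTION_RATE))
        m1 = min(m0 + int(round(MOTION_BURST_DURATION * MOTION_RATE)) + 1,
                 motion.size)
        # spike sustained over the whole burst so gating sees every overlap
        decay = np.exp(-np.arange(m1 - m0) / (MOTION_RATE * 0.15))
        motion[m0:m1] += MOTION_SPIKE_AMPLITUDE * (0.5 + 0.5 * decay)
        burst_times.append((s0 / rate, (s0 + burst_n) / rate))

    truth_segments = SegmentLabel.from_active_intervals(active, n, depths)
    mask = truth_segments.sample_mask("active")
    # truth powers describe artifact-free breathing: burst windows (which the
    # analysis pipeline motion-rejects) are excluded from the bookkeeping
    for t0, t1 in burst_times:
        mask[int(t0 * rate):int(t1 * rate)] = False
    truth_snr: dict[str, float] = {}
    truth_powers: dict[str, tuple[float, float]] = {}
    for side in ("left", "right"):
        p_s = _banded_power(comps[side]["clean"], rate, band, mask)
        p_n = _banded_power(comps[side]["noise"], rate, band, mask)
        truth_powers[side] = (p_s, p_n)
        truth_snr[side] = _truth_snr(p_s, p_n)

    data = np.column_stack([comps["left"]["clean"] + comps["left"]["noise"],
                            comps["right"]["clean"] + comps["right"]["noise"]])
    rec = Recording(data=data, rate=rate, motion=motion,
                    motion_rate=MOTION_RATE, subject_id=subject.subject_id)
    return SimOutput(subject=subject, recording=rec,
                     truth_segments=truth_segments, truth_snr_db=truth_snr,
                     truth_powers=truth_powers,
                     motion_burst_times=burst_times,
                     components=comps if keep_components else None)


HEALTHY_SCALE_PROBS = {3: 0.01, 4: 0.02, 5: 0.05, 6: 0.09, 7: 0.15,
                       8: 0.22, 9: 0.26, 10: 0.20}
COPD_SCALE_PROBS = {4: 0.15, 5: 0.35, 6: 0.35, 7: 0.15}   # mean 5.5


def _draw_scales(rng: np.random.Generator, probs: dict[int, float],
                 n: int) -> np.ndarray:
    scales = np.array(list(probs.keys()))
    p = np.array(list(probs.values()), dtype=float)
    return rng.choice(scales, size=n, p=p / p.sum())


def simulate_cohort(n_healthy: int = 35, n_copd: int = 3, seed: int = 0,
                    scale_map=default_turbulence_power,
                    breath_gain_map=default_breath_gain_db,
                    program: BreathProgram | None = None,
                    rate: float = DEFAULT_RATE,
                    out_dir: str | Path | None = None,
                    keep_components: bool = False,
                    **subject_kwargs,
                    ) -> tuple[list[SimOutput], pd.DataFrame]:
    """Simulate a whole cohort, optionally writing WAV/CSV artifacts.

    Healthy subjects draw health scales skewed toward the top of the 1-10
    range (recreational runners); COPD subjects center near 5.5.
    ``scale_map`` / ``breath_gain_map`` translate the health scale into
    turbulence noise power and clean breath gain.  Fully reproducible from
    ``seed``.  Returns the list of simulations and the metadata table
    (subject_id, age, gender, group, health_scale, seed).
    """
    if n_healthy + n_copd < 2:
        raise InvalidConfigurationError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    child_seeds = [int(s) & 0x7FFFFFFF
                   for s in np.random.SeedSequence(seed).generate_state(
                       n_healthy + n_copd)]
    groups = ["healthy"] * n_healthy + ["copd"] * n_copd
    scales = np.concatenate([
        _draw_scales(rng, HEALTHY_SCALE_PROBS, n_healthy),
        _draw_scales(rng, COPD_SCALE_PROBS, n_copd),
    ]).astype(int)
    ages = np.concatenate([rng.integers(18, 76, n_healthy),
                           rng.integers(45, 81, n_copd)])
    genders = rng.choice(["male", "female"], size=n_healthy + n_copd,
                         p=[0.7, 0.3])

    outputs: list[SimOutput] = []
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    truth_frames = []
    for i, (group, h) in enumerate(zip(groups, scales)):
        sid = f"sub{i:03d}"
        subj = SimSubject(subject_id=sid, health_scale=int(h), group=group,
                          turbulence_noise_power=scale_map(int(h)),
                          breath_gain_db=breath_gain_map(int(h)),
                          seed=child_seeds[i], age=int(ages[i]),
                          gender=str(genders[i]))
        sim = simulate_subject(subj, program=program, rate=rate,
                               keep_components=keep_components,
                               **subject_kwargs)
        outputs.append(sim)
        rows.append({"subject_id": sid, "age": int(ages[i]),
                     "gender": str(genders[i]), "group": group,
                     "health_scale": int(h), "seed": child_seeds[i]})
        if out_path is not None:
            write_wav(out_path / f"{sid}.wav", sim.recording)
            write_motion_csv(out_path / f"{sid}.motion.csv",
                             sim.recording.motion, MOTION_RATE)
            for side in ("left", "right"):
                truth_frames.append(
                    sim.truth_segments.to_frame(subject_id=sid, channel=side)
                    .drop(columns="motion_rejected"))
    metadata = pd.DataFrame(rows)
    if out_path is not None:
        metadata.to_csv(out_path / "metadata.csv", index=False)
        pd.concat(truth_frames, ignore_index=True).to_csv(
            out_path / "truth_labels.csv", index=False)
    return outputs, metadata
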