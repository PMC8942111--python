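import numpy as np
import pytest

from breathsnr import BreathProgram

RATE = 4000.0


@pytest.fixture(scope="session")
def rate() -> float:
    return RATE


@pytest.fixture(scope="session")
def short_program() -> BreathProgram:
    """24 s session: one normal and one deep block."""
    return BreathProgram.short(normal=16.0, deep=8.0)


@pytest.fixture(scope="session")
def tiny_program() -> BreathProgram:
    """10 s single normal block at 15 breaths/min (2.5 nominal breaths)."""
    return BreathProgram(depth_sequence=(("normal", 10.0),))


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Interval Jaccard overlap |a & b| / |a | b|."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


def white_noise(n: int, sigma: float = 1.0, seed: int = 0) -> np.ndarray:
    return sigma * np.random.default_rng(seed).standard_normal(n)
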