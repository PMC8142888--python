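import numpy as np
import pytest

import isodetect as iso


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_step_signal():
    """The worked two-change example: 0 on [1,38], 2 on [39,77], 0 on [78,100]."""
    f = np.r_[np.zeros(38), 2.0 * np.ones(39), np.zeros(23)]
    return f, [38, 77]


@pytest.fixture
def wave_signal():
    """Continuous piecewise-linear wave: slopes +-1 alternating every 50, T=500."""
    return iso.gen_signal(iso.preset("wave"))


def random_step_signal(rng, n_changes=None, min_gap=30, max_gap=70):
    """Random noiseless piecewise-constant signal with well-separated jumps."""
    k = int(rng.integers(1, 6)) if n_changes is None else n_changes
    gaps = min_gap + rng.integers(0, max_gap - min_gap + 1, size=k + 1)
    cps = np.cumsum(gaps)[:k]
    T = int(np.cumsum(gaps)[-1])
    levels = [0.0]
    for _ in range(k):
        levels.append(levels[-1] + rng.choice([-1, 1]) * rng.uniform(1.0, 3.0))
    ext = [0] + [int(c) for c in cps] + [T]
    f = np.empty(T)
    for i in range(k + 1):
        f[ext[i]:ext[i + 1]] = levels[i]
    return f, [int(c) for c in cps]


def random_kink_signal(rng, n_changes=None, min_gap=40, max_gap=80):
    """Random noiseless continuous piecewise-linear signal with clear kinks."""
    k = int(rng.integers(1, 6)) if n_changes is None else n_changes
    gaps = min_gap + rng.integers(0, max_gap - min_gap + 1, size=k + 1)
    cps = [int(c) for c in np.cumsum(gaps)[:k]]
    T = int(np.cumsum(gaps)[-1])
    t = np.arange(1, T + 1, dtype=float)
    slope = rng.uniform(-1, 1)
    f = rng.uniform(-5, 5) + slope * t
    for c in cps:
        f = f + rng.choice([-1, 1]) * rng.uniform(0.3, 1.0) * np.maximum(t - c, 0.0)
    return f, cps
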