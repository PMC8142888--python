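"""Contrast statistics for single change-point detection on an interval.

Two mean structures are supported:

* piecewise-constant (``CONST``): the contrast is the absolute CUSUM
  statistic, which for a candidate split ``b`` of ``[s, e]`` compares the
  scaled means of ``x[s..b]`` and ``x[b+1..e]``;
* continuous piecewise-linear (``LINEAR``): the contrast is the absolute
  inner product of the data with a normalized "kinked" vector, obtained by
  Gram-Schmidt orthogonalization of ``(t - b)_+`` against the constant and
  linear vectors on ``[s, e]``, so that exactly-affine data score zero.

All indices in this module are 1-based and intervals are inclusive, matching
the usual change-point convention where a change-point ``r`` is the last
index of the left segment.  Every contrast is evaluated in O(1) from two
prefix-sum arrays (sum of x and sum of t*x), so that a full scan of an
interval costs O(interval length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class InvalidIntervalError(ValueError):
    """Raised when (s, e, b) does not satisfy the required ordering."""


class ModelKind(str, Enum):
    CONST = "const"
    LINEAR = "linear"


@dataclass(frozen=True)
class ContrastModel:
    """Which mean structure is assumed; selects contrast and admissibility.

    CONST admits splits ``b`` in ``[s, e-1]`` and needs at least 2 points;
    LINEAR admits ``b`` in ``[s+1, e-2]`` and needs at least 4 points so
    that both sides of the kink contain two points and the closed-form
    normalization is finite and nonzero.
    """

    kind: ModelKind

    @property
    def min_interval_len(self) -> int:
        return 2 if self.kind is ModelKind.CONST else 4

    def admissible_b(self, s: int, e: int) -> range:
        if self.kind is ModelKind.CONST:
            return range(s, e)
        return range(s + 1, e - 1)

    @classmethod
    def from_name(cls, name: str) -> "ContrastModel":
        return cls(ModelKind(str(name).lower()))


CONST = ContrastModel(ModelKind.CONST)
LINEAR = ContrastModel(ModelKind.LINEAR)


@dataclass
class PrefixSums:
    """Cumulative sums enabling O(1) window sums of x and t*x.

    ``s1[t] = sum_{u<=t} x_u`` and ``st[t] = sum_{u<=t} u * x_u`` with
    ``s1[0] = st[0] = 0`` (arrays of length T+1, 1-based indexing).
    """

    x: np.ndarray
    s1: np.ndarray = field(init=False)
    st: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 1:
            raise ValueError("series must be one-dimensional")
        self.x = x
        T = x.size
        self.s1 = np.concatenate(([0.0], np.cumsum(x)))
        self.st = np.concatenate(([0.0], np.cumsum(np.arange(1, T + 1) * x)))

    @property
    def T(self) -> int:
        return self.x.size

    def wsum(self, lo, hi):
        """Sum of x over the 1-based inclusive window [lo, hi]."""
        return self.s1[hi] - self.s1[np.asarray(lo) - 1]

    def wtsum(self, lo, hi):
        """Sum of t * x_t over the 1-based inclusive window [lo, hi]."""
        return self.st[hi] - self.st[np.asarray(lo) - 1]


def _check_interval(s: int, e: int, T: int) -> None:
    if not (1 <= s < e <= T):
        raise InvalidIntervalError(f"need 1 <= s < e <= T, got s={s}, e={e}, T={T}")


def _cusum_values(ps: PrefixSums, s: int, e: int, b: np.ndarray) -> np.ndarray:
    """Signed CUSUM statistic at every split in ``b`` (vectorized)."""
    n = e - s + 1
    left = b - s + 1.0
    right = e - b.astype(float)
    sum_left = ps.wsum(s, b)
    sum_right = ps.wsum(b + 1, e)
    return np.sqrt(right / (n * left)) * sum_left - np.sqrt(left / (n * right)) * sum_right


def _linear_values(ps: PrefixSums, s: int, e: int, b: np.ndarray) -> np.ndarray:
    """Signed inner product <x, phi_{s,e}^b> at every split in ``b``.

    phi is piecewise-linear in t on [s,b] and [b+1,e], so the inner product
    is a closed-form combination of window sums of x and t*x.
    """
    n = e - s + 1
    bf = b.astype(float)
    alpha = np.sqrt(
        6.0 / (n * (n * n - 1.0) * (1.0 + (e - bf + 1) * (bf - s + 1) + (e - bf) * (bf - s)))
    )
    beta = np.sqrt(((e - bf + 1) * (e - bf)) / ((bf - s + 1) * (bf - s)))
    left = (e + 2 * bf - 3 * s + 2) * ps.wtsum(s, b) - (
        bf * e + bf * s - 2.0 * s * s + 2.0 * s
    ) * ps.wsum(s, b)
    right = (3 * e - 2 * bf - s + 2) * ps.wtsum(b + 1, e) - (
        2.0 * e * e + 2.0 * e - bf * e - bf * s
    ) * ps.wsum(b + 1, e)
    return alpha * beta * left - (alpha / beta) * right


def cusum_contrast(x, s: int, e: int, b: int) -> float:
    """Absolute CUSUM contrast of x at split b within [s, e] (1-based)."""
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    _check_interval(s, e, ps.T)
    if not (s <= b < e):
        raise InvalidIntervalError(f"need s <= b < e, got s={s}, b={b}, e={e}")
    return float(abs(_cusum_values(ps, s, e, np.array([b]))[0]))


def linear_contrast(x, s: int, e: int, b: int) -> float:
    """Absolute kink contrast |<x, phi_{s,e}^b>| at split b within [s, e]."""
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    _check_interval(s, e, ps.T)
    if not (s + 1 <= b <= e - 2):
        raise InvalidIntervalError(
            f"linear split must satisfy s+1 <= b <= e-2, got s={s}, b={b}, e={e}"
        )
    return float(abs(_linear_values(ps, s, e, np.array([b]))[0]))


def contrast(x, s: int, e: int, b: int, model: ContrastModel) -> float:
    """Model-dispatching contrast C_{s,e}^b."""
    if model.kind is ModelKind.CONST:
        return cusum_contrast(x, s, e, b)
    return linear_contrast(x, s, e, b)


def argmax_contrast(x, s: int, e: int, model: ContrastModel):
    """Best split of [s, e]: ``(b*, value)`` maximizing the contrast.

    Ties break to the smallest b.  Returns ``(None, 0.0)`` when the interval
    is too short to admit any split.
    """
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    _check_interval(s, e, ps.T)
    rng = model.admissible_b(s, e)
    if e - s + 1 < model.min_interval_len or len(rng) == 0:
        return None, 0.0
    bs = np.arange(rng.start, rng.stop)
    if model.kind is ModelKind.CONST:
        vals = np.abs(_cusum_values(ps, s, e, bs))
    else:
        vals = np.abs(_linear_values(ps, s, e, bs))
    i = int(np.argmax(vals))  # np.argmax returns the first maximizer
    return int(bs[i]), float(vals[i])


# ---------------------------------------------------------------------------
# Brute-force oracles.  These deliberately avoid the prefix-sum path and are
# used in tests to certify the O(1) implementations.
# ---------------------------------------------------------------------------

def cusum_contrast_bruteforce(x, s: int, e: int, b: int) -> float:
    """Direct-summation CUSUM, independent of PrefixSums."""
    x = np.asarray(x, dtype=float)
    n = e - s + 1
    t1 = np.sqrt((e - b) / (n * (b - s + 1))) * x[s - 1 : b].sum()
    t2 = np.sqrt((b - s + 1) / (n * (e - b))) * x[b : e].sum()
    return float(abs(t1 - t2))


def phi_vector_gram_schmidt(s: int, e: int, b: int, T: int) -> np.ndarray:
    """Kink contrast vector built by explicit Gram-Schmidt (oracle).

    Orthogonalizes ``(t - b) for t > b`` against the constant and centered
    linear vectors supported on [s, e], then normalizes to unit length.
    """
    t = np.arange(1, T + 1, dtype=float)
    on = ((t >= s) & (t <= e)).astype(float)
    one = on / np.linalg.norm(on)
    gam = on * (t - (e + s) / 2.0)
    gam /= np.linalg.norm(gam)
    tilde = np.where((t >= b + 1) & (t <= e), t - b, 0.0)
    v = tilde - (tilde @ one) * one - (tilde @ gam) * gam
    return v / np.linalg.norm(v)


def linear_contrast_bruteforce(x, s: int, e: int, b: int) -> float:
    """|<x, phi>| with phi built by Gram-Schmidt (oracle path)."""
    x = np.asarray(x, dtype=float)
    return float(abs(x @ phi_vector_gram_schmidt(s, e, b, x.size)))
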