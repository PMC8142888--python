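"""The Isolate-Detect scan: interleaved expanding intervals and detection.

The search for multiple change-points is decoupled into single-change-point
problems by scanning, on the current interval ``[s, e]``, an interleaved
sequence of right-expanding intervals ``[s, c]`` (start fixed) and
left-expanding intervals ``[c', e]`` (end fixed), where the expansion
endpoints come from a global grid with step ``lambda_T``.  The first interval
whose maximum contrast exceeds the threshold ``zeta_T`` yields a detection;
the scan then continues on the remainder of ``[s, e]`` beyond that interval
(or beyond the estimate itself, in the restart-at-estimate variant), so each
change-point is tested while isolated from its neighbours.

Because the grid is global, an interval already cleared in an earlier phase
reappears unchanged in later phases; such intervals are skipped, so a run
with no detections examines at most ``2 * ceil(T / lambda_T)`` intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .contrasts import (
    CONST,
    ContrastModel,
    InvalidIntervalError,
    ModelKind,
    PrefixSums,
    argmax_contrast,
    contrast,
)

logger = logging.getLogger(__name__)


class RestartMode(str, Enum):
    #: restart from the endpoint of the interval where detection occurred
    ENDPOINT = "endpoint"
    #: restart from the estimated change-point itself (the ID_det variant)
    AT_ESTIMATE = "at_estimate"


class Direction(str, Enum):
    RIGHT = "right"
    LEFT = "left"


@dataclass(frozen=True)
class ExpansionGrid:
    """Global expansion anchors for a series of length T with step lambda_T.

    Right anchors are ``j*lambda_T`` for ``j < K`` and ``T`` for ``j = K``;
    left anchors are ``T - j*lambda_T + 1`` for ``j < K`` and ``1`` for
    ``j = K``, with ``K = ceil(T / lambda_T)``.  Anchors are fixed for the
    whole run and never recomputed from a sub-interval.
    """

    T: int
    lam: int

    def __post_init__(self) -> None:
        if self.T < 1 or self.lam < 1:
            raise ValueError("T and lambda_T must be positive integers")

    @property
    def K(self) -> int:
        return math.ceil(self.T / self.lam)

    @property
    def right_anchors(self) -> np.ndarray:
        a = np.arange(1, self.K + 1) * self.lam
        a[-1] = self.T
        return a

    @property
    def left_anchors(self) -> np.ndarray:
        a = self.T - np.arange(1, self.K + 1) * self.lam + 1
        a[-1] = 1
        return a


def expansion_points(s: int, e: int, grid: ExpansionGrid):
    """Endpoint sequences of the expanding intervals for the interval [s, e].

    Returns ``(right_ends, left_starts)``: the global right anchors strictly
    between s and e followed by e, and the global left anchors strictly
    between s and e followed by s.
    """
    if not (1 <= s < e <= grid.T):
        raise InvalidIntervalError(f"need 1 <= s < e <= T, got s={s}, e={e}")
    ra = grid.right_anchors
    la = grid.left_anchors
    right_ends = [int(a) for a in ra if s < a < e] + [e]
    left_starts = [int(a) for a in la if s < a < e] + [s]
    return right_ends, left_starts


@dataclass(frozen=True)
class DetectionConfig:
    """Tuning of one Isolate-Detect run.

    ``threshold`` is the detection cutoff zeta_T on the standardized scale;
    use :func:`isodetect.selection.default_threshold` for the calibrated
    ``C * sqrt(2 log T)`` default.  ``lam`` is the interval-expansion step.
    """

    model: ContrastModel = CONST
    lam: int = 3
    threshold: float = 1.0
    restart_mode: RestartMode = RestartMode.ENDPOINT
    window_len: int = 3000
    window_threshold_T: int = 12000

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda_T must be >= 1")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class Detection:
    """One detection event: the estimate and the interval that triggered it."""

    b: int
    value: float
    interval: tuple
    direction: Direction


@dataclass
class ScanStats:
    """Instrumentation: how many distinct intervals were examined."""

    intervals_examined: int = 0
    detections: list = field(default_factory=list)


def _continuation_start(b: int, model: ContrastModel) -> int:
    # After a RIGHT detection at b, points strictly in the next regime start
    # at b+1 for level changes; for continuous piecewise-linear signals the
    # kink point b itself lies on both segments, so it is shared.
    return b + 1 if model.kind is ModelKind.CONST else b


def isolate_detect(
    x,
    s: int | None = None,
    e: int | None = None,
    cfg: DetectionConfig = DetectionConfig(),
    stats: ScanStats | None = None,
    grid: ExpansionGrid | None = None,
) -> list[int]:
    """Run the Isolate-Detect scan on ``x[s..e]`` (1-based, inclusive).

    ``x`` is expected on (approximately) unit-noise scale; the threshold in
    ``cfg`` is compared directly against contrast values.  Returns the sorted
    list of detected change-points.  Deterministic: no randomness anywhere.
    """
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    T = ps.T
    s = 1 if s is None else s
    e = T if e is None else e
    model = cfg.model
    if e - s + 1 < model.min_interval_len:
        return []
    if grid is None:
        grid = ExpansionGrid(T, cfg.lam)
    if stats is None:
        stats = ScanStats()
    examined: set[tuple[int, int]] = set()
    found: list[int] = []

    while e - s + 1 >= model.min_interval_len:
        right_ends, left_starts = expansion_points(s, e, grid)
        detection = None
        for j in range(max(len(right_ends), len(left_starts))):
            candidates = []
            if j < len(right_ends):
                candidates.append((s, right_ends[j], Direction.RIGHT))
            if j < len(left_starts):
                candidates.append((left_starts[j], e, Direction.LEFT))
            for lo, hi, direction in candidates:
                if hi - lo + 1 < model.min_interval_len:
                    continue
                if (lo, hi) in examined:
                    continue
                examined.add((lo, hi))
                stats.intervals_examined += 1
                b, val = argmax_contrast(ps, lo, hi, model)
                logger.debug(
                    "interval [%d, %d] (%s): max contrast %.4f at %s",
                    lo, hi, direction.value, val, b,
                )
                if b is not None and val > cfg.threshold:
                    # If the maximizing split abuts the expanding end of the
                    # interval, the contrast is still growing in that
                    # direction and the change may not yet be expressible
                    # (e.g. a kink with a single point beyond it); defer to
                    # the next expansion step.  The full interval [s, e]
                    # always accepts.
                    rng = model.admissible_b(lo, hi)
                    deferred = (
                        (direction is Direction.RIGHT and b == rng.stop - 1 and hi != e)
                        or (direction is Direction.LEFT and b == rng.start and lo != s)
                    )
                    if not deferred:
                        detection = Detection(b, val, (lo, hi), direction)
                        break
                    logger.debug("detection at %d deferred: split at interval edge", b)
            if detection is not None:
                break
        if detection is None:
            break
        found.append(detection.b)
        stats.detections.append(detection)
        if detection.direction is Direction.RIGHT:
            if cfg.restart_mode is RestartMode.ENDPOINT:
                s = detection.interval[1]
            else:
                s = _continuation_start(detection.b, model)
        else:
            if cfg.restart_mode is RestartMode.ENDPOINT:
                e = detection.interval[0]
            else:
                e = detection.b
    return sorted(found)


def scan_family_max(x, lam: int = 1, model: ContrastModel = CONST) -> float:
    """Maximum contrast over the full expanding-interval family on [1, T].

    Scans every right-expanding interval [1, c_j^r] and left-expanding
    interval [c_j^l, T] of the global grid (2*ceil(T/lam) intervals), taking
    the maximum over all admissible splits in each.  With ``lam=1`` this is
    the maximum over every prefix and suffix interval — the family that
    governs the detector's false-positive behavior, and the statistic whose
    square stays below ``3 (1 + delta) log T`` with high probability under
    pure Gaussian noise.
    """
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    T = ps.T
    grid = ExpansionGrid(T, lam)
    best = 0.0
    for e in grid.right_anchors:
        if e - 1 + 1 >= model.min_interval_len and e > 1:
            _, v = argmax_contrast(ps, 1, int(e), model)
            best = max(best, v)
    for s in grid.left_anchors:
        if T - s + 1 >= model.min_interval_len and s < T:
            _, v = argmax_contrast(ps, int(s), T, model)
            best = max(best, v)
    return best


def id_windowed(
    x, cfg: DetectionConfig = DetectionConfig(), stats: ScanStats | None = None
) -> list[int]:
    """Isolate-Detect with uniform windowing for long signals.

    For ``T > cfg.window_threshold_T`` the series is split into consecutive
    windows of length ``cfg.window_len``; adjacent windows share their
    boundary point so that a change falling exactly on a window edge remains
    visible in the next window (a short final window is merged into the
    previous one).  The scan runs per window with window-local expansion
    grids, and the pooled detections are re-validated by one
    triplet-contrast pass to repair window-boundary artifacts.  For shorter
    series this is identical to :func:`isolate_detect`.
    """
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    T = ps.T
    if T <= cfg.window_threshold_T:
        return isolate_detect(ps, 1, T, cfg, stats=stats)
    starts = [1] + list(range(cfg.window_len, T, cfg.window_len))
    edges = [(lo, min(lo + cfg.window_len, T)) for lo in starts]
    edges[0] = (1, min(cfg.window_len, T))
    if len(edges) > 1 and edges[-1][1] - edges[-1][0] + 1 < cfg.model.min_interval_len:
        lo, _ = edges.pop()
        edges[-1] = (edges[-1][0], T)
    pooled: list[int] = []
    for lo, hi in edges:
        sub = ps.x[lo - 1 : hi]
        sub_cfg = replace(cfg, window_threshold_T=max(cfg.window_threshold_T, hi - lo + 2))
        dets = isolate_detect(sub, 1, hi - lo + 1, sub_cfg, stats=stats)
        pooled.extend(d + lo - 1 for d in dets)
    pooled = sorted(set(pooled))
    # triplet re-validation: drop pooled estimates whose contrast over the
    # interval bounded by their neighbours no longer clears the threshold
    kept: list[int] = []
    ext = [1] + pooled + [T]
    for i, b in enumerate(pooled):
        lo, hi = ext[i], ext[i + 2]
        rng = cfg.model.admissible_b(lo, hi)
        if rng.start <= b < rng.stop:
            val = contrast(ps, lo, hi, b, cfg.model)
        else:
            val = np.inf  # too close to a neighbour to re-test; keep
        if val > cfg.threshold:
            kept.append(b)
    return kept
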