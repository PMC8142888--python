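"""Stopping rules: calibrated thresholds, solution path, sSIC, hybrid.

Three ways to decide how many change-points to keep:

* **threshold**: a detection is kept whenever its contrast exceeds
  ``zeta_T = C * sqrt(2 log T)``, with constants calibrated for unit-variance
  Gaussian noise (C = 1.05 for level changes, 1.4 for slope changes);
* **sSIC**: deliberately overestimate with a lowered threshold (constants
  0.9 / 1.25), order the candidates into a solution path by greedily removing
  the one with the weakest contrast over the interval bounded by its
  neighbours, then pick the nested model minimizing the strengthened Schwarz
  Information Criterion ``-2 loglik + n_j (log T)^alpha`` with alpha just
  above 1;
* **hybrid**: threshold first with a fine expansion step; if it reports more
  than ``J* = 100`` change-points (a long signal with frequent changes, where
  thresholding excels) keep that answer, otherwise rerun with sSIC selection
  and a coarser step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .contrasts import CONST, ContrastModel, ModelKind, PrefixSums, contrast
from .core import DetectionConfig, RestartMode, ScanStats, id_windowed
from .evaluation import fit_signal

logger = logging.getLogger(__name__)

#: calibrated threshold constants for zeta_T = C sqrt(2 log T)
THRESHOLD_CONSTANT = {ModelKind.CONST: 1.05, ModelKind.LINEAR: 1.4}
#: lowered constants used for the overestimation stage of the sSIC approach
LOWERED_CONSTANT = {ModelKind.CONST: 0.9, ModelKind.LINEAR: 1.25}
#: reference constant for the triplet-removal test (diagnostics only)
REMOVAL_REFERENCE_CONSTANT = 2.0 * math.sqrt(2.0)

#: hybrid-rule defaults: fine step for the threshold stage, candidate-count
#: cutoff, and coarser step for the sSIC stage
HYBRID_LAMBDA_THRESHOLD = 3
HYBRID_J_STAR = 100
HYBRID_LAMBDA_SSIC = 10


def default_threshold(T: int, model: ContrastModel, lowered: bool = False) -> float:
    """zeta_T = C sqrt(2 log T) with the calibrated (or lowered) constant."""
    table = LOWERED_CONSTANT if lowered else THRESHOLD_CONSTANT
    return table[model.kind] * math.sqrt(2.0 * math.log(T))


@dataclass(frozen=True)
class SSICConfig:
    """Strengthened-SIC settings.

    ``alpha`` is the penalty exponent (> 1; 1.01 keeps the criterion close to
    the plain SIC).  ``count_locations_as_params`` decides whether each
    change-point location is itself a free parameter in the penalty
    (``n_j = 2j+1`` for level changes instead of ``j+1``); counting them is
    the default because only that convention makes the criterion strict
    enough to discard scan-selected spurious candidates on pure noise.
    ``likelihood`` selects the Gaussian log-likelihood form: ``"profiled"``
    profiles out a common unknown variance, giving
    ``-2 loglik = T log(RSS / T)`` up to a constant, while
    ``"unit_variance"`` takes sigma = 1 so ``-2 loglik = RSS``.  The RSS is
    floored at ``rss_floor_scale * T`` so noiseless fits stay well-defined.
    """

    alpha: float = 1.01
    count_locations_as_params: bool = True
    rss_floor_scale: float = 1e-12
    likelihood: str = "profiled"

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("sSIC requires alpha > 1")
        if self.likelihood not in ("profiled", "unit_variance"):
            raise ValueError("likelihood must be 'profiled' or 'unit_variance'")


@dataclass
class SolutionPath:
    """Reverse removal order of the overestimated candidates.

    ``b[0]`` survived the greedy pruning the longest (it is the strongest
    estimate); ``b[-1]`` was removed first.  ``model_at(j)`` gives the nested
    candidate model with j change-points, sorted.
    """

    b: list[int]
    removal_scores: list[float]

    def __len__(self) -> int:
        return len(self.b)

    def model_at(self, j: int) -> list[int]:
        return sorted(self.b[:j])


@dataclass
class ChangePointResult:
    """Estimated change-points plus everything needed to audit the fit."""

    changepoints: list[int]
    model: ContrastModel
    method: str
    threshold: float
    fitted: np.ndarray
    rss: float
    solution_path: SolutionPath | None = None
    ssic_trace: np.ndarray | None = None
    selected_j: int | None = None
    stats: ScanStats | None = None
    sigma: float | None = None

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)


def triplet_score(x, left: int, mid: int, right: int, model: ContrastModel) -> float:
    """Contrast of ``mid`` over the interval bounded by its neighbours.

    A mid too close to its neighbours to be an admissible split scores 0,
    which forces its removal first in the pruning pass.
    """
    if not (left < mid < right):
        raise ValueError(f"need left < mid < right, got {left}, {mid}, {right}")
    rng = model.admissible_b(left, right)
    if not (rng.start <= mid < rng.stop):
        logger.debug("triplet (%d, %d, %d) inadmissible for %s; score 0",
                     left, mid, right, model.kind.value)
        return 0.0
    return contrast(x, left, right, mid, model)


def build_solution_path(x, candidates, model: ContrastModel) -> SolutionPath:
    """Order candidates by greedy removal of the weakest triplet contrast.

    At each step the candidate with the smallest contrast over the interval
    bounded by its current neighbours (boundaries 1 and T at the extremes)
    is removed; ties break to the smallest index.  The returned path lists
    candidates in reverse removal order.
    """
    ps = x if isinstance(x, PrefixSums) else PrefixSums(np.asarray(x, dtype=float))
    T = ps.T
    remaining = sorted(set(int(c) for c in candidates))
    removed: list[int] = []
    scores: list[float] = []
    log_ref = REMOVAL_REFERENCE_CONSTANT * math.sqrt(math.log(T)) if T > 1 else 0.0
    while remaining:
        ext = [1] + remaining + [T]
        # a candidate colliding with a neighbour/boundary scores 0 and is
        # removed first
        cs = [
            triplet_score(ps, ext[i], ext[i + 1], ext[i + 2], model)
            if ext[i] < ext[i + 1] < ext[i + 2] else 0.0
            for i in range(len(remaining))
        ]
        i = int(np.argmin(cs))  # first minimizer -> smallest index on ties
        logger.debug(
            "solution path: removing %d (CS=%.4f, reference %.4f)",
            remaining[i], cs[i], log_ref,
        )
        removed.append(remaining[i])
        scores.append(float(cs[i]))
        remaining.pop(i)
    removed.reverse()
    scores.reverse()
    return SolutionPath(removed, scores)


def _n_params(j: int, model: ContrastModel, cfg: SSICConfig) -> int:
    base = j + 1 if model.kind is ModelKind.CONST else j + 2
    return base + (j if cfg.count_locations_as_params else 0)


def ssic(x, changepoints, model: ContrastModel, cfg: SSICConfig = SSICConfig()) -> float:
    """Strengthened SIC of the maximum-likelihood fit at the given knots."""
    x = np.asarray(x, dtype=float)
    T = x.size
    cps = sorted(int(c) for c in changepoints)
    if any(not (1 <= c <= T - 1) for c in cps):
        raise ValueError("change-points must lie in [1, T-1]")
    rss = fit_signal(x, cps, model).rss
    rss = max(rss, cfg.rss_floor_scale * T)
    if cfg.likelihood == "profiled":
        neg2ll = T * math.log(rss / T)
    else:
        neg2ll = rss
    return neg2ll + _n_params(len(cps), model, cfg) * math.log(T) ** cfg.alpha


def id_threshold(
    x,
    model: ContrastModel = CONST,
    lam: int = 3,
    threshold: float | None = None,
    restart_mode: RestartMode = RestartMode.ENDPOINT,
    stats: ScanStats | None = None,
) -> ChangePointResult:
    """Threshold-stopped Isolate-Detect with the calibrated default cutoff."""
    x = np.asarray(x, dtype=float)
    T = x.size
    if threshold is None:
        threshold = default_threshold(T, model)
    cfg = DetectionConfig(model=model, lam=lam, threshold=threshold,
                          restart_mode=restart_mode)
    stats = stats if stats is not None else ScanStats()
    cps = id_windowed(x, cfg, stats=stats)
    fit = fit_signal(x, cps, model)
    return ChangePointResult(cps, model, "threshold", threshold, fit.fitted,
                             fit.rss, stats=stats)


def id_ssic(
    x,
    model: ContrastModel = CONST,
    lam: int = 3,
    restart_mode: RestartMode = RestartMode.ENDPOINT,
    scfg: SSICConfig = SSICConfig(),
    stats: ScanStats | None = None,
) -> ChangePointResult:
    """Overestimate with the lowered threshold, prune, select by sSIC."""
    x = np.asarray(x, dtype=float)
    T = x.size
    low = default_threshold(T, model, lowered=True) if T > 1 else 1.0
    cfg = DetectionConfig(model=model, lam=lam, threshold=low,
                          restart_mode=restart_mode)
    stats = stats if stats is not None else ScanStats()
    candidates = id_windowed(x, cfg, stats=stats)
    path = build_solution_path(x, candidates, model)
    trace = np.array([ssic(x, path.model_at(j), model, scfg)
                      for j in range(len(path) + 1)])
    j_hat = int(np.argmin(trace))  # first minimizer -> smallest j on ties
    cps = path.model_at(j_hat)
    fit = fit_signal(x, cps, model)
    return ChangePointResult(cps, model, "ssic", low, fit.fitted, fit.rss,
                             solution_path=path, ssic_trace=trace,
                             selected_j=j_hat, stats=stats)


def id_hybrid(
    x,
    model: ContrastModel = CONST,
    scfg: SSICConfig = SSICConfig(),
    j_star: int = HYBRID_J_STAR,
    lam_threshold: int = HYBRID_LAMBDA_THRESHOLD,
    lam_ssic: int = HYBRID_LAMBDA_SSIC,
) -> ChangePointResult:
    """Hybrid stopping rule: threshold stage first, sSIC as fallback.

    Stage 1 runs the restart-at-estimate threshold variant with a fine
    expansion step (default 3); its answer is kept only when it reports more
    than ``j_star`` change-points.  Otherwise the sSIC approach reruns with
    a coarser step (default 10).  Pre-averaged runs pass steps rescaled by
    the averaging scale.
    """
    x = np.asarray(x, dtype=float)
    stage1 = id_threshold(x, model, lam=lam_threshold,
                          restart_mode=RestartMode.AT_ESTIMATE)
    if stage1.n_changepoints > j_star:
        return stage1
    return id_ssic(x, model, lam=lam_ssic,
                   restart_mode=RestartMode.AT_ESTIMATE, scfg=scfg)


def sdll_hook(x, model: ContrastModel, ranking_fn, **kwargs):
    """Extension hook for external model-selection rules (e.g. SDLL).

    Runs the overestimation stage and solution path, then delegates the
    choice of the number of change-points to ``ranking_fn(path, x)``, which
    must return the selected model size j.  No such rule ships with this
    package.
    """
    res = id_ssic(x, model, **kwargs)
    j = int(ranking_fn(res.solution_path, np.asarray(x, dtype=float)))
    cps = res.solution_path.model_at(j)
    fit = fit_signal(np.asarray(x, dtype=float), cps, model)
    return ChangePointResult(cps, model, "external", res.threshold, fit.fitted,
                             fit.rss, solution_path=res.solution_path,
                             selected_j=j)
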