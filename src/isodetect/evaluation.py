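"""Fitted-signal construction and segmentation accuracy metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contrasts import ContrastModel, ModelKind


@dataclass
class FitResult:
    """Least-squares signal estimate given a set of change-points.

    For level changes the fit is the per-segment sample mean; for continuous
    piecewise-linear signals it is the global least-squares fit over the
    linear-spline family with knots exactly at the change-points (global,
    not per-segment, so continuity is enforced).
    """

    fitted: np.ndarray
    rss: float
    segments: list


def _segment_bounds(changepoints, T: int):
    ext = [0] + sorted(int(c) for c in changepoints) + [T]
    return [(ext[i] + 1, ext[i + 1]) for i in range(len(ext) - 1)]


def fit_signal(x, changepoints, model: ContrastModel) -> FitResult:
    x = np.asarray(x, dtype=float)
    T = x.size
    cps = sorted(int(c) for c in changepoints)
    if any(not (1 <= c <= T - 1) for c in cps) or len(set(cps)) != len(cps):
        raise ValueError("change-points must be distinct and lie in [1, T-1]")
    bounds = _segment_bounds(cps, T)
    if model.kind is ModelKind.CONST:
        fitted = np.empty(T)
        segments = []
        for lo, hi in bounds:
            m = x[lo - 1 : hi].mean()
            fitted[lo - 1 : hi] = m
            segments.append((lo, hi, (m,)))
        rss = float(((x - fitted) ** 2).sum())
        return FitResult(fitted, rss, segments)
    # continuous linear spline on the truncated-power basis {1, t, (t-c)_+}
    t = np.arange(1, T + 1, dtype=float)
    cols = [np.ones(T), t] + [np.maximum(t - c, 0.0) for c in cps]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, x, rcond=None)
    fitted = X @ coef
    segments = []
    for k, (lo, hi) in enumerate(bounds):
        slope = coef[1] + sum(coef[2 + j] for j in range(k))
        intercept = fitted[lo - 1] - slope * lo
        segments.append((lo, hi, (intercept, slope)))
    rss = float(((x - fitted) ** 2).sum())
    return FitResult(fitted, rss, segments)


def mse(fhat, f) -> float:
    """Mean squared error T^{-1} sum (fhat_t - f_t)^2."""
    fhat = np.asarray(fhat, dtype=float)
    f = np.asarray(f, dtype=float)
    if fhat.shape != f.shape:
        raise ValueError("length mismatch between fitted and true signal")
    return float(np.mean((fhat - f) ** 2))


def hausdorff_scaled(r, rhat, T: int) -> float:
    """Hausdorff distance between change-point sets, scaled by the longest
    true segment (segment boundaries {0, r_1, ..., r_N, T}).

    If both sets are empty the distance is 0; if exactly one is empty the
    maximal value T / n_s is returned.
    """
    r = sorted(int(v) for v in r)
    rhat = sorted(int(v) for v in rhat)
    for v in r + rhat:
        if not (1 <= v <= T - 1):
            raise ValueError("change-points must lie in [1, T-1]")
    ext = [0] + r + [T]
    n_s = max(ext[i + 1] - ext[i] for i in range(len(ext) - 1))
    if not r and not rhat:
        return 0.0
    if not r or not rhat:
        return T / n_s
    a = np.asarray(r)[:, None]
    b = np.asarray(rhat)[None, :]
    d = np.abs(a - b)
    h = max(d.min(axis=1).max(), d.min(axis=0).max())
    return float(h) / n_s
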