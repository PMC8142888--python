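"""Model / Results front end for Isolate-Detect.

``IsolateDetect`` is constructed from a univariate series (array, Series, or
DataFrame column) and a mean-structure assumption; ``fit`` runs the full
pipeline — optional count transform, optional pre-averaging for heavy-tailed
noise, robust noise-scale estimation, standardization, detection with the
chosen stopping rule — and returns an ``IsolateDetectResults`` carrying the
estimated change-points, the fitted signal on the original scale, the
solution path and sSIC trace where applicable, and a ``summary()`` table.

Example
-------
>>> import numpy as np
>>> from isodetect import IsolateDetect
>>> rng = np.random.default_rng(0)
>>> x = np.r_[np.zeros(100), 2 * np.ones(100)] + rng.standard_normal(200)
>>> res = IsolateDetect(x, model="const").fit(selector="hybrid")
>>> res.changepoints
[100]
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .contrasts import ContrastModel, ModelKind
from .core import RestartMode
from .evaluation import fit_signal
from .selection import (
    ChangePointResult,
    SSICConfig,
    default_threshold,
    id_hybrid,
    id_ssic,
    id_threshold,
    triplet_score,
)

_SELECTORS = ("hybrid", "ssic", "threshold")


class IsolateDetect:
    """Multiple change-point model for a univariate series.

    Parameters
    ----------
    endog : array-like
        The observed series X_1, ..., X_T.  Must be finite.
    model : {"const", "linear"} or ContrastModel
        Mean structure: piecewise-constant level changes or continuous
        piecewise-linear slope changes.
    sigma : float, "mad-diff", "mad-raw", optional
        Known noise SD, or the MAD estimator variant to use (differenced by
        default, so the signal does not inflate the estimate).
    positions : array-like, optional
        Labels (dates, genomic coordinates) carried through to the summary.
    anscombe : bool
        Apply the 2*sqrt(x + 3/8) count transform before detection.
    preaverage : int
        Block-averaging scale for heavy-tailed noise (1 = off).  Detections
        on the averaged series are mapped back to the original resolution.
    """

    def __init__(self, endog, model="const", sigma="mad-diff", positions=None,
                 anscombe: bool = False, preaverage: int = 1):
        endog = np.asarray(
            endog.values if isinstance(endog, (pd.Series, pd.DataFrame)) else endog,
            dtype=float,
        ).ravel()
        if endog.size == 0:
            raise ValueError("empty series")
        if not np.all(np.isfinite(endog)):
            raise ValueError("series contains NaN or infinite values")
        self.endog = endog
        self.model = model if isinstance(model, ContrastModel) else ContrastModel.from_name(model)
        self.sigma = sigma
        self.positions = None if positions is None else np.asarray(positions)
        if self.positions is not None and self.positions.size != endog.size:
            raise ValueError("positions must match the series length")
        self.anscombe = bool(anscombe)
        self.preaverage = int(preaverage)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, column, positions=None, **kwargs):
        pos = data[positions].values if isinstance(positions, str) else positions
        return cls(data[column].values, positions=pos, **kwargs)

    @property
    def nobs(self) -> int:
        return self.endog.size

    def _working_series(self) -> np.ndarray:
        y = self.endog
        if self.anscombe:
            y = prep.anscombe(y)
        if self.preaverage > 1:
            y = prep.preaverage(y, self.preaverage)
        return y

    def _sigma_hat(self, y: np.ndarray) -> float:
        if isinstance(self.sigma, (int, float)) and not isinstance(self.sigma, bool):
            if self.sigma <= 0:
                raise ValueError("known sigma must be positive")
            return float(self.sigma)
        method = prep.MADMethod(str(self.sigma).replace("-", "_"))
        return prep.mad_sigma(y, self.model, method).sigma_hat

    def fit(self, selector: str = "hybrid", lam: int = 3,
            threshold: float | None = None,
            restart_mode: RestartMode = RestartMode.ENDPOINT,
            ssic_config: SSICConfig = SSICConfig()) -> "IsolateDetectResults":
        """Estimate the change-points with the requested stopping rule."""
        if selector not in _SELECTORS:
            raise ValueError(f"selector must be one of {_SELECTORS}")
        y = self._working_series()
        sigma = self._sigma_hat(y)
        z = prep.standardize(y, sigma)
        lam_eff = prep.rescale_lambda(lam, self.preaverage) if self.preaverage > 1 else lam
        if selector == "hybrid":
            from .selection import HYBRID_LAMBDA_SSIC, HYBRID_LAMBDA_THRESHOLD

            raw = id_hybrid(
                z, self.model, scfg=ssic_config,
                lam_threshold=prep.rescale_lambda(HYBRID_LAMBDA_THRESHOLD, self.preaverage),
                lam_ssic=prep.rescale_lambda(HYBRID_LAMBDA_SSIC, self.preaverage),
            )
        elif selector == "ssic":
            raw = id_ssic(z, self.model, lam=lam_eff, restart_mode=restart_mode,
                          scfg=ssic_config)
        else:
            thr = threshold if threshold is not None else default_threshold(z.size, self.model)
            raw = id_threshold(z, self.model, lam=lam_eff, threshold=thr,
                               restart_mode=restart_mode)
        cps = raw.changepoints
        if self.preaverage > 1:
            cps = sorted({min(prep.map_back(c, self.preaverage), self.nobs - 1)
                          for c in cps})
            raw = replace_changepoints(raw, cps)
        fit = fit_signal(self.endog if not self.anscombe else prep.anscombe(self.endog),
                         cps, self.model)
        return IsolateDetectResults(self, raw, sigma, fit.fitted, fit.rss)


def replace_changepoints(res: ChangePointResult, cps) -> ChangePointResult:
    from dataclasses import replace as dc_replace
    return dc_replace(res, changepoints=list(cps))


class IsolateDetectResults:
    """Fit results: estimates, diagnostics, and a text summary."""

    def __init__(self, model: IsolateDetect, raw: ChangePointResult,
                 sigma: float, fitted: np.ndarray, rss: float):
        self.model = model
        self._raw = raw
        self.sigma_hat = sigma
        self.fitted = fitted
        self.rss = rss

    @property
    def changepoints(self) -> list[int]:
        """Estimated change-points, 1-based last-index-of-left-segment."""
        return list(self._raw.changepoints)

    @property
    def n_changepoints(self) -> int:
        return len(self._raw.changepoints)

    @property
    def method(self) -> str:
        """Which stopping rule produced the estimate ('threshold'/'ssic')."""
        return self._raw.method

    @property
    def solution_path(self):
        return self._raw.solution_path

    @property
    def ssic_trace(self):
        return self._raw.ssic_trace

    @property
    def threshold(self) -> float:
        return self._raw.threshold

    @property
    def resid(self) -> np.ndarray:
        base = self.model.endog if not self.model.anscombe else prep.anscombe(self.model.endog)
        return base - self.fitted

    def changepoint_table(self) -> pd.DataFrame:
        """Per-change-point diagnostics: index, position label, and the
        contrast over the interval bounded by neighbouring estimates."""
        x = self.model.endog if not self.model.anscombe else prep.anscombe(self.model.endog)
        z = prep.standardize(x, self.sigma_hat)
        cps = self.changepoints
        ext = [1] + cps + [self.model.nobs]
        rows = []
        for i, c in enumerate(cps):
            score = triplet_score(z, ext[i], c, ext[i + 2], self.model.model) \
                if ext[i] < c < ext[i + 2] else np.nan
            row = {"index": c, "triplet_contrast": score}
            if self.model.positions is not None:
                row["position"] = self.model.positions[c - 1]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Isolate-Detect change-point estimation",
            "=" * 54,
            f"Mean structure:     {m.model.kind.value} "
            f"({'level changes' if m.model.kind is ModelKind.CONST else 'slope changes'})",
            f"Observations:       {m.nobs}",
            f"Noise SD:           {self.sigma_hat:.6g} "
            f"({'given' if isinstance(m.sigma, (int, float)) else m.sigma})",
            f"Stopping rule:      {self.method} (threshold {self.threshold:.4g})",
            f"Change-points:      {self.n_changepoints}",
            f"Residual SS:        {self.rss:.6g}",
        ]
        if self.ssic_trace is not None:
            lines.append(f"sSIC selected j:    {self._raw.selected_j} "
                         f"of path length {len(self.solution_path)}")
        tab = self.changepoint_table()
        if len(tab):
            lines.append("-" * 54)
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Quick-look figure: data, fitted signal, change-point markers."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.endog if not self.model.anscombe else prep.anscombe(self.model.endog)
        t = np.arange(1, x.size + 1)
        ax.plot(t, x, lw=0.5, alpha=0.6, label="data")
        ax.plot(t, self.fitted, lw=1.5, label="fitted signal")
        for c in self.changepoints:
            ax.axvline(c, color="k", ls=":", lw=0.8)
        ax.legend()
        return ax


def detect_changepoints(x, model="const", selector="hybrid", **kwargs):
    """One-call convenience wrapper: returns the results object."""
    fit_kwargs = {k: kwargs.pop(k) for k in
                  ("lam", "threshold", "restart_mode", "ssic_config")
                  if k in kwargs}
    return IsolateDetect(x, model=model, **kwargs).fit(selector=selector, **fit_kwargs)
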