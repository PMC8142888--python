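"""File readers and writers.

Input: plain text (one value per line), a named/indexed CSV column, or a
bedGraph-style 4-column genomic track (chrom, start, end, value; 0-based
half-open) where each row contributes one observation.  Output: TSV, BED
(0-based half-open single intervals at each change-point, when genomic
metadata exists), or JSON with the full diagnostics.

Coordinate contract: series indices are 1-based inclusive everywhere inside
the package (a change-point is the last index of the left segment); BED
output converts to 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SeriesDocument:
    """A series plus optional positional metadata from the source file."""

    values: np.ndarray
    #: per-observation (chrom, start, end) tuples for genomic tracks
    intervals: list | None = None
    #: generic per-observation position labels (e.g. dates)
    positions: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.positions is not None and len(self.positions) != self.values.size:
            raise ValueError("positions must match the number of observations")
        if self.intervals is not None and len(self.intervals) != self.values.size:
            raise ValueError("interval metadata must match the number of observations")


def read_series(path, fmt: str = "txt", column=None) -> SeriesDocument:
    """Read a univariate series.  ``fmt``: "txt", "csv_column", "bedgraph"."""
    path = str(path)
    if fmt == "txt":
        vals = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    vals.append(float(line))
                except ValueError:
                    raise ValueError(f"{path}:{i}: non-numeric value {line!r}") from None
        if not vals:
            raise ValueError(f"{path}: empty input")
        return SeriesDocument(np.array(vals), source=path)
    if fmt == "csv_column":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"{path}: empty input")
        col = df.columns[0] if column is None else (
            df.columns[int(column)] if str(column).isdigit() and column not in df.columns
            else column
        )
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            i = int(series.index[series.isna()][0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}:{i}: non-numeric value in column {col!r}")
        return SeriesDocument(series.to_numpy(float), source=path)
    if fmt == "bedgraph":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        if df.empty:
            raise ValueError(f"{path}: empty input")
        vals = pd.to_numeric(df["value"], errors="coerce")
        if vals.isna().any():
            i = int(vals.index[vals.isna()][0]) + 1
            raise ValueError(f"{path}:{i}: non-numeric signal value")
        intervals = list(zip(df["chrom"], df["start"].astype(int), df["end"].astype(int)))
        return SeriesDocument(vals.to_numpy(float), intervals=intervals, source=path)
    raise ValueError(f"unknown input format {fmt!r}")


def write_series(doc: SeriesDocument, path, fmt: str = "txt") -> None:
    path = str(path)
    if fmt == "txt":
        with open(path, "w") as fh:
            for v in doc.values:
                fh.write(f"{float(v):.17g}\n")
        return
    if fmt == "bedgraph":
        if doc.intervals is None:
            raise ValueError("bedGraph output requires genomic interval metadata")
        with open(path, "w") as fh:
            for (chrom, start, end), v in zip(doc.intervals, doc.values):
                fh.write(f"{chrom}\t{start}\t{end}\t{float(v):.17g}\n")
        return
    raise ValueError(f"unknown output format {fmt!r}")


def _detection_lookup(result):
    raw = getattr(result, "_raw", result)
    out = {}
    if raw.stats is not None:
        for d in raw.stats.detections:
            out[d.b] = (d.value, d.direction.value)
    return out


def write_changepoints(result, doc: SeriesDocument | None, path, fmt: str = "tsv") -> None:
    """Write estimated change-points.

    ``result`` is an ``IsolateDetectResults`` (or bare ``ChangePointResult``).
    TSV columns: 1-based series index, position (when metadata exists), the
    detection contrast and direction where the point arose from a threshold
    detection.  BED emits the source row's genomic interval at each
    change-point.  JSON serializes the full result including the solution
    path and sSIC trace.
    """
    path = str(path)
    cps = list(result.changepoints)
    lookup = _detection_lookup(result)
    if fmt == "tsv":
        has_pos = doc is not None and (doc.intervals is not None or doc.positions is not None)
        with open(path, "w") as fh:
            cols = ["index"] + (["position"] if has_pos else []) + ["contrast", "direction"]
            fh.write("\t".join(cols) + "\n")
            for c in cps:
                val, direction = lookup.get(c, (float("nan"), ""))
                row = [str(c)]
                if has_pos:
                    if doc.intervals is not None:
                        chrom, start, end = doc.intervals[c - 1]
                        row.append(f"{chrom}:{start}-{end}")
                    else:
                        row.append(str(doc.positions[c - 1]))
                row += [f"{val:.6g}", direction]
                fh.write("\t".join(row) + "\n")
        return
    if fmt == "bed":
        if doc is None or doc.intervals is None:
            raise ValueError("BED output requires genomic interval metadata")
        with open(path, "w") as fh:
            for c in cps:
                chrom, start, end = doc.intervals[c - 1]
                fh.write(f"{chrom}\t{start}\t{end}\n")
        return
    if fmt == "json":
        raw = getattr(result, "_raw", result)
        payload = {
            "changepoints": [int(c) for c in cps],
            "n_changepoints": len(cps),
            "method": raw.method,
            "threshold": raw.threshold,
            "model": raw.model.kind.value,
            "rss": getattr(result, "rss", raw.rss),
            "sigma_hat": getattr(result, "sigma_hat", None),
            "solution_path": None if raw.solution_path is None else {
                "b": [int(v) for v in raw.solution_path.b],
                "removal_scores": [float(v) for v in raw.solution_path.removal_scores],
            },
            "ssic_trace": None if raw.ssic_trace is None else
                          [float(v) for v in raw.ssic_trace],
            "selected_j": raw.selected_j,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return
    raise ValueError(f"unknown output format {fmt!r}")


def read_changepoints_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
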