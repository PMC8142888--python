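# isodetect

Multiple change-point detection for univariate series by **isolating each
change before detecting it** — the Isolate-Detect approach. The package
estimates the number and locations of level changes in piecewise-constant
signals and of slope changes (kinks) in continuous piecewise-linear
signals, for data such as epidemic curves, house-price indices, or genomic
coverage tracks.

## The method

Data are modelled as `X_t = f_t + sigma * eps_t`, `t = 1..T`, where `f` is
piecewise-constant or continuous piecewise-linear with change-points
`r_1 < ... < r_N` (a change-point is the last index of its left segment),
and `eps_t` is unit-variance noise. Detection scans an interleaved sequence
of *expanding intervals* with one endpoint fixed: right-expanding
`[s, j*lambda]` and left-expanding `[T - j*lambda + 1, e]`, growing by the
expansion step `lambda` (default 3). Because the intervals grow one step at
a time, the first interval on which evidence of a change appears contains —
with high probability — exactly one change-point, where the contrast
statistic has maximal power:

* level changes: the absolute CUSUM statistic
  `|sqrt((e-b)/(n(b-s+1))) * sum_{s..b} X  -  sqrt((b-s+1)/(n(e-b))) * sum_{b+1..e} X|`;
* slope changes: `|<X, phi_{s,e}^b>|`, with `phi` the unit-norm vector
  obtained by orthogonalizing a kinked ramp against the constant and linear
  vectors on `[s, e]`, so exactly-affine data score zero.

A change is declared when the maximal contrast exceeds
`zeta_T = C * sqrt(2 log T)` (calibrated constants `C = 1.05` for levels,
`1.4` for kinks); the scan then restarts beyond the detection and repeats.
A full no-detection scan examines at most `2 * ceil(T / lambda)` intervals,
which makes the method fast even for very long series.

Number-of-changes selection offers three stopping rules:

* **threshold** — keep every detection above `zeta_T`;
* **ssic** — deliberately overestimate with lowered constants (0.9 / 1.25),
  order candidates into a *solution path* by repeatedly removing the one
  with the weakest contrast between its neighbours, then minimize the
  strengthened Schwarz criterion `-2 loglik + n_j (log T)^alpha`
  (`alpha = 1.01`) over the nested models;
* **hybrid** (default) — threshold first with `lambda = 3`; accept if more
  than 100 change-points are found (frequent-change regimes where
  thresholding excels), otherwise rerun with sSIC selection and
  `lambda = 10`.

Supporting tools: robust noise-scale estimation (MAD on first or second
differences, constant 1.4826), block pre-averaging for heavy-tailed noise
with an index map back to the original resolution, the Anscombe transform
`2 sqrt(x + 3/8)` for counts, least-squares signal refitting, and the
accuracy metrics used in segmentation studies (MSE and the scaled Hausdorff
distance).

## Worked example

```python
import numpy as np
from isodetect import IsolateDetect

rng = np.random.default_rng(7)
f = np.r_[np.zeros(300), 2.0 * np.ones(200), 0.5 * np.ones(300)]
x = f + rng.standard_normal(800)

res = IsolateDetect(x, model="const").fit(selector="hybrid")
print(res.summary())
```

```
Isolate-Detect change-point estimation
======================================================
Mean structure:     const (level changes)
Observations:       800
Noise SD:           0.970931 (mad-diff)
Stopping rule:      ssic (threshold 3.291)
Change-points:      2
Residual SS:        712.122
sSIC selected j:    2 of path length 5
------------------------------------------------------
 index  triplet_contrast
   300         22.684513
   499         16.256175
```

The noise SD was estimated at 0.97 from differenced data (true value 1);
the hybrid rule fell through to its sSIC stage (2 candidates ≤ 100), whose
lowered-threshold scan produced 5 candidates pruned back to the two genuine
changes. The estimates 300 and 499 sit at/next to the true change-points
300 and 500; `res.fitted` holds the refitted step signal and
`res.solution_path` / `res.ssic_trace` the selection diagnostics.

The same interface runs from the shell:

```sh
isodetect detect series.txt --model linear --selector hybrid -o out.json --out-format json
isodetect simulate scenario.cfg -o results/sim
isodetect evaluate truth.txt estimate.txt -T 5200
```

bedGraph tracks are read with `--format bedgraph` and results can be
written as BED intervals for genome browsers.

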