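"""Per-pixel linear trends, Mann-Kendall significance, five-class trend maps,
productivity grades and scalar series summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import Grid, GridError, RasterCube

__all__ = [
    "TREND_CLASSES",
    "GRADE_EDGES",
    "ols_slope",
    "mann_kendall",
    "classify_trend",
    "trend_maps",
    "grade_proportions",
    "series_summary",
]

#: trend-class codes for the classified map
TREND_CLASSES = {1: "ESR", 2: "SR", 3: "NSC", 4: "SI", 5: "ESI"}
_CLASS_CODE = {v: k for k, v in TREND_CLASSES.items()}

#: productivity grade edges, gC m-2 yr-1, bins [lo, hi) with an open top
GRADE_EDGES = (0.0, 100.0, 200.0, 300.0, 400.0, np.inf)


def ols_slope(series) -> float:
    """Closed-form least-squares slope against the index i = 1..n."""
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 3:
        return float("nan")
    i = np.arange(1, n + 1, dtype=float)
    num = n * (i * y).sum() - i.sum() * y.sum()
    den = n * (i * i).sum() - i.sum() ** 2
    return float(num / den)


def mann_kendall(series) -> tuple[int, float, float]:
    """Mann-Kendall trend statistics (S, Var(S), Z).

    S is the pairwise sign sum; Var(S) uses the standard tie-corrected
    variance [n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)] / 18; Z is the
    three-branch standardized statistic (Z = 0 when S = 0).
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 4:
        raise GridError(f"Mann-Kendall requires n >= 4, got {n}")
    diff = np.sign(y[None, :] - y[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - (ties * (ties - 1) * (2 * ties + 5)).sum()) / 18.0
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    return s, float(var_s), float(z)


def classify_trend(slope: float, z: float) -> str:
    """Five-way significance classification of a (slope, Z) pair.

    Sign-inconsistent combinations (e.g. slope > 0 with strongly negative Z)
    fall back to NSC because the significant classes are defined only for
    sign-consistent pairs.
    """
    if not (np.isfinite(slope) and np.isfinite(z)):
        raise GridError("classify_trend requires finite slope and Z")
    if -1.96 <= z <= 1.96:
        return "NSC"
    if slope < 0 and z < -2.58:
        return "ESR"
    if slope < 0 and -2.58 < z < -1.96:
        return "SR"
    if slope > 0 and z > 2.58:
        return "ESI"
    if slope > 0 and 1.96 < z < 2.58:
        return "SI"
    return "NSC"  # sign conflict or boundary z = +-2.58 with wrong-sign slope


def _mk_z_vectorized(data: np.ndarray) -> np.ndarray:
    """Z statistic along axis 0 of a (time, pixels) array (no ties assumed
    beyond exact duplicates, which are handled pixelwise)."""
    n, _ = data.shape
    s = np.zeros(data.shape[1])
    for i in range(n - 1):
        s += np.sign(data[i + 1 :] - data[i]).sum(axis=0)
    # tie-corrected variance per pixel
    var = np.full(data.shape[1], n * (n - 1) * (2 * n + 5) / 18.0)
    sorted_vals = np.sort(data, axis=0)
    eq = sorted_vals[1:] == sorted_vals[:-1]
    if eq.any():
        for j in np.nonzero(eq.any(axis=0))[0]:
            _, counts = np.unique(sorted_vals[:, j], return_counts=True)
            ties = counts[counts > 1]
            var[j] -= (ties * (ties - 1) * (2 * ties + 5)).sum() / 18.0
    z = np.zeros_like(s)
    pos, neg = s > 0, s < 0
    z[pos] = (s[pos] - 1) / np.sqrt(var[pos])
    z[neg] = (s[neg] + 1) / np.sqrt(var[neg])
    return z


def trend_maps(annual: RasterCube) -> tuple[Grid, Grid, Grid]:
    """(slope, z, class) grids for an annual cube.

    Pixels with fewer than 4 valid years are masked.
    """
    stack = annual.stack()
    n, rows, cols = stack.shape
    flat = stack.reshape(n, -1)
    valid = ~np.ma.getmaskarray(flat).any(axis=0)
    data = np.asarray(flat.data[:, valid], dtype=float)

    i = np.arange(1, n + 1, dtype=float)
    num = n * (i[:, None] * data).sum(axis=0) - i.sum() * data.sum(axis=0)
    den = n * (i * i).sum() - i.sum() ** 2
    slopes = num / den
    z = _mk_z_vectorized(data)

    codes = np.full(valid.sum(), _CLASS_CODE["NSC"], dtype=np.int16)
    codes[(slopes < 0) & (z < -2.58)] = _CLASS_CODE["ESR"]
    codes[(slopes < 0) & (z > -2.58) & (z < -1.96)] = _CLASS_CODE["SR"]
    codes[(slopes > 0) & (z > 1.96) & (z < 2.58)] = _CLASS_CODE["SI"]
    codes[(slopes > 0) & (z > 2.58)] = _CLASS_CODE["ESI"]

    template = annual.layers[0]
    mask = ~valid.reshape(rows, cols)

    def as_grid(flat_vals, dtype):
        full = np.zeros(rows * cols, dtype=dtype)
        full[valid] = flat_vals
        return Grid(full.reshape(rows, cols), template.transform, mask.copy(), template.crs)

    return (
        as_grid(slopes.astype(np.float32), np.float32),
        as_grid(z.astype(np.float32), np.float32),
        as_grid(codes, np.int16),
    )


def grade_proportions(annual_npp: Grid, edges=GRADE_EDGES) -> dict[str, float]:
    """Area proportion of each productivity grade ([lo, hi) bins)."""
    vals = annual_npp.unmasked().astype(float)
    if vals.size == 0:
        raise GridError("grade_proportions on an empty grid")
    out = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        out[label] = float(((vals >= lo) & (vals < hi)).mean())
    return out


@dataclass(frozen=True)
class SeriesSummary:
    first: float
    last: float
    mean: float
    max: float
    min: float
    relative_change_pct: float | None
    max_anomaly: float
    min_anomaly: float
    slope: float
    r_squared: float
    p_value: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def series_summary(annual_means) -> SeriesSummary:
    """Scalar summary of an annual-mean series: endpoints, relative change
    100*(last-first)/first, extremes and their anomalies from the mean, and
    the OLS trend with R-squared and p-value."""
    y = np.asarray(annual_means, dtype=float)
    if len(y) < 2:
        raise GridError("series_summary requires at least 2 values")
    first, last = float(y[0]), float(y[-1])
    mean = float(y.mean())
    rel = None if first == 0 else 100.0 * (last - first) / first
    if len(y) >= 3:
        i = np.arange(1, len(y) + 1, dtype=float)
        reg = stats.linregress(i, y)
        slope, r2, p = float(reg.slope), float(reg.rvalue**2), float(reg.pvalue)
    else:
        slope, r2, p = last - first, 1.0, float("nan")
    return SeriesSummary(
        first=first,
        last=last,
        mean=mean,
        max=float(y.max()),
        min=float(y.min()),
        relative_change_pct=rel,
        max_anomaly=float(y.max()) - mean,
        min_anomaly=mean - float(y.min()),
        slope=slope,
        r_squared=r2,
        p_value=p,
    )
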