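"""Pixelwise second-order partial correlation between annual NPP and each
climate driver (controlling the other two), t-test significance and the
four-way significance classification."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .raster import Grid, GridError, RasterCube

__all__ = [
    "SIG_CLASSES",
    "pearson",
    "partial_corr_2nd_order",
    "partial_corr_precision",
    "pixelwise_partial_corr",
    "classify_significance",
    "significance_fractions",
]

#: codes for the significance map: sign x (p < alpha)
SIG_CLASSES = {1: "SNC", 2: "NSNC", 3: "NSPC", 4: "SPC"}
_CODE = {v: k for k, v in SIG_CLASSES.items()}


def pearson(x, y) -> float:
    """Product-moment correlation; NaN when either series has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise GridError("pearson requires aligned series of length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return float("nan")
    return float((xc * yc).sum() / den)


def _first_order(r_ab, r_ac, r_bc) -> float:
    den = np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
    if den == 0:
        return float("nan")
    return (r_ab - r_ac * r_bc) / den


def partial_corr_2nd_order(y, x1, x2, x3) -> float:
    """R_y1.23 by the first-order recursion: compose R_y1.2, R_y3.2, R_13.2
    and combine.  NaN on collinear controls."""
    series = [np.asarray(s, dtype=float) for s in (y, x1, x2, x3)]
    if len({len(s) for s in series}) != 1 or len(series[0]) < 5:
        raise GridError("partial correlation requires aligned series of length >= 5")
    y, x1, x2, x3 = series
    r_y1, r_y2, r_y3 = pearson(y, x1), pearson(y, x2), pearson(y, x3)
    r_12, r_13, r_23 = pearson(x1, x2), pearson(x1, x3), pearson(x2, x3)
    r_y1_2 = _first_order(r_y1, r_y2, r_12)
    r_y3_2 = _first_order(r_y3, r_y2, r_23)
    r_13_2 = _first_order(r_13, r_12, r_23)
    den = np.sqrt((1 - r_y3_2**2) * (1 - r_13_2**2))
    if not np.isfinite(den) or den == 0:
        return float("nan")
    return float((r_y1_2 - r_y3_2 * r_13_2) / den)


def partial_corr_precision(y, x1, x2, x3) -> float:
    """Independent oracle: r_y1.23 from the inverse of the 4x4 correlation
    matrix, r_ij = -p_ij / sqrt(p_ii p_jj)."""
    data = np.vstack([np.asarray(s, dtype=float) for s in (y, x1, x2, x3)])
    corr = np.corrcoef(data)
    p = np.linalg.inv(corr)
    return float(-p[0, 1] / np.sqrt(p[0, 0] * p[1, 1]))


def _annual_aggregate(cube: RasterCube, how: str) -> np.ma.MaskedArray:
    """(year, row, col) annual aggregate of a monthly or annual cube."""
    years = cube.years
    if all(len(t) == 1 for t in cube.times):
        return cube.stack()
    out = []
    for year in years:
        sub = cube.for_year(year).stack()
        out.append(sub.sum(axis=0) if how == "sum" else sub.mean(axis=0))
    return np.ma.stack(out)


def pixelwise_partial_corr(
    npp_annual: RasterCube,
    precip: RasterCube,
    temp: RasterCube,
    solrad: RasterCube,
) -> dict[str, Grid]:
    """Per-pixel partial correlation of annual NPP with each climate factor,
    controlling the other two.

    Monthly climate cubes are aggregated to annual values first (sums for
    precipitation and radiation, means for temperature).  Returns one grid
    per factor plus the regional means under both conventions (mean of
    pixel r, and r of regional-mean series) in the grids' metadata dict.
    """
    y = _annual_aggregate(npp_annual, "sum")
    drivers = {
        "precip": _annual_aggregate(precip, "sum"),
        "temp": _annual_aggregate(temp, "mean"),
        "solrad": _annual_aggregate(solrad, "sum"),
    }
    n_years = y.shape[0]
    if any(d.shape[0] != n_years for d in drivers.values()):
        raise GridError("all cubes must cover the same years")
    template = npp_annual.layers[0]
    rows, cols = template.shape

    names = list(drivers)
    flat = {k: np.asarray(v.data, dtype=float).reshape(n_years, -1) for k, v in drivers.items()}
    yflat = np.asarray(y.data, dtype=float).reshape(n_years, -1)
    mask_any = np.ma.getmaskarray(y).any(axis=0)
    for v in drivers.values():
        mask_any |= np.ma.getmaskarray(v).any(axis=0)
    valid = ~mask_any.reshape(-1)

    # standardize then use the precision-matrix identity per pixel (vectorized)
    def zscore(a):
        mu = a.mean(axis=0)
        sd = a.std(axis=0)
        sd = np.where(sd == 0, np.nan, sd)
        return (a - mu) / sd

    data = np.stack([zscore(yflat), zscore(flat["precip"]), zscore(flat["temp"]), zscore(flat["solrad"])])
    # correlation matrices per pixel: (4, 4, npix)
    corr = np.einsum("iyp,jyp->ijp", data, data) / n_years

    def first_order(r_ab, r_ac, r_bc):
        with np.errstate(invalid="ignore", divide="ignore"):
            return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))

    out = {}
    npix = rows * cols
    r_by_factor = np.full((3, npix), np.nan)
    for j, (a, b) in zip((1, 2, 3), ((2, 3), (1, 3), (1, 2))):
        r_y1_2 = first_order(corr[0, j], corr[0, a], corr[j, a])
        r_y3_2 = first_order(corr[0, b], corr[0, a], corr[a, b])
        r_13_2 = first_order(corr[j, b], corr[j, a], corr[a, b])
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (r_y1_2 - r_y3_2 * r_13_2) / np.sqrt((1 - r_y3_2**2) * (1 - r_13_2**2))
        r = np.where(valid, r, np.nan)
        r_by_factor[j - 1] = np.clip(r, -1.0, 1.0)

    for j, name in enumerate(names):
        vals = r_by_factor[j]
        grid_mask = (~np.isfinite(vals)).reshape(rows, cols)
        out[name] = Grid(
            np.nan_to_num(vals, nan=0.0).astype(np.float32).reshape(rows, cols),
            template.transform, grid_mask, template.crs,
        )
    return out


def regional_summary(r_grids: dict[str, Grid], npp_annual: RasterCube,
                     precip: RasterCube, temp: RasterCube, solrad: RasterCube) -> dict:
    """Regional coefficients under both conventions: area-mean of pixel r and
    partial correlation of the regional-mean annual series."""
    y = _annual_aggregate(npp_annual, "sum").mean(axis=(1, 2))
    p = _annual_aggregate(precip, "sum").mean(axis=(1, 2))
    t = _annual_aggregate(temp, "mean").mean(axis=(1, 2))
    s = _annual_aggregate(solrad, "sum").mean(axis=(1, 2))
    series = {"precip": (y, p, t, s), "temp": (y, t, p, s), "solrad": (y, s, p, t)}
    out = {}
    for name, grid in r_grids.items():
        out[f"mean_pixel_r_{name}"] = float(grid.unmasked().mean())
        out[f"regional_series_r_{name}"] = partial_corr_2nd_order(*series[name])
    return out


def classify_significance(r: Grid, n_years: int, alpha: float = 0.05) -> Grid:
    """Four-way class map from (sign of r, t-test at alpha).

    t = r sqrt((n - 2 - k) / (1 - r^2)) with k = 2 controls and df = n - 2 - k.
    """
    k = 2
    df = n_years - 2 - k
    if df < 1:
        raise GridError(f"need n_years > {2 + k}, got {n_years}")
    vals = r.values.astype(float)
    r2 = np.clip(vals**2, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = vals * np.sqrt(df / np.maximum(1 - r2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df)
    p[np.isclose(r2, 1.0)] = 0.0  # |r| = 1: significant by convention
    sig = p < alpha
    codes = np.where(vals >= 0,
                     np.where(sig, _CODE["SPC"], _CODE["NSPC"]),
                     np.where(sig, _CODE["SNC"], _CODE["NSNC"])).astype(np.int16)
    return Grid(codes, r.transform, r.mask.copy(), r.crs)


def significance_fractions(sig: Grid) -> dict[str, float]:
    vals = sig.unmasked()
    total = max(len(vals), 1)
    return {name: float((vals == code).sum()) / total for code, name in SIG_CLASSES.items()}
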