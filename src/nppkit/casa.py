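"""Monthly light-use-efficiency NPP model.

NPP(x, t) = APAR(x, t) x eps(x, t), with APAR = FPAR x SOL x 0.5 and
eps = T1 x T2 x W x eps_max(class).  FPAR is the mean of an NDVI-based and a
simple-ratio-based linear rescale onto [0.001, 0.95].

The temperature and moisture stress closures are the canonical regional
forms (Potter-style polynomial/logistic temperature terms; a
precipitation/net-radiation evapotranspiration ratio for moisture), with
the optimal temperature taken as the multi-year mean temperature of the
calendar month of peak NDVI.  The per-class constants (eps_max and NDVI
bounds) ship as an editable table of documented defaults; SR bounds are
derived from the NDVI bounds through the simple-ratio transform so the two
FPAR routes stay mutually consistent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import Grid, GridError, RasterCube

__all__ = [
    "FPAR_MAX",
    "FPAR_MIN",
    "VegClassParams",
    "default_params",
    "load_params",
    "sr_index",
    "fpar_from_ndvi",
    "fpar_from_sr",
    "fpar_combined",
    "apar",
    "optimal_temperature",
    "temperature_stress",
    "water_stress_ratio",
    "water_stress",
    "monthly_npp",
    "annual_npp",
    "run_casa_year",
    "total_npp_tgc",
]

FPAR_MAX = 0.95
FPAR_MIN = 0.001

_NDVI_CLIP_LO = -0.1
_NDVI_CLIP_HI = 0.997


def _sr(ndvi):
    nd = np.clip(ndvi, _NDVI_CLIP_LO, _NDVI_CLIP_HI)
    return (1.0 + nd) / (1.0 - nd)


@dataclass(frozen=True)
class VegClassParams:
    """Per-vegetation-class constants for the light-use-efficiency model."""

    class_id: int
    name: str
    eps_max: float      # gC MJ-1, class-specific LUE ceiling
    ndvi_min: float
    ndvi_max: float

    def __post_init__(self) -> None:
        if not 0 < self.eps_max <= 2.0:
            raise ValueError(f"eps_max must be in (0, 2], got {self.eps_max}")
        if not self.ndvi_min < self.ndvi_max:
            raise ValueError(f"need ndvi_min < ndvi_max, got {self.ndvi_min} >= {self.ndvi_max}")

    @property
    def sr_min(self) -> float:
        return float(_sr(self.ndvi_min))

    @property
    def sr_max(self) -> float:
        return float(_sr(self.ndvi_max))


# Editable defaults (documented assumptions following the common China
# calibration of per-class maximum LUE; not site-measured values).
_DEFAULT_PARAMS_CSV = """\
class_id,name,eps_max,ndvi_min,ndvi_max
1,farmland,0.542,0.023,0.634
2,woodland,0.692,0.023,0.647
3,grassland,0.542,0.023,0.608
4,water body,0.542,0.023,0.608
5,unused land,0.542,0.023,0.608
6,construction land,0.542,0.023,0.634
"""


def default_params() -> dict[int, VegClassParams]:
    return load_params(io.StringIO(_DEFAULT_PARAMS_CSV))


def load_params(source) -> dict[int, VegClassParams]:
    """Load a per-class parameter table (CSV with columns class_id, name,
    eps_max, ndvi_min, ndvi_max)."""
    df = pd.read_csv(source)
    required = {"class_id", "name", "eps_max", "ndvi_min", "ndvi_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parameter table missing columns: {sorted(missing)}")
    return {
        int(row.class_id): VegClassParams(
            int(row.class_id), str(row.name), float(row.eps_max),
            float(row.ndvi_min), float(row.ndvi_max),
        )
        for row in df.itertuples()
    }


def _per_class_fields(vegtype: Grid, params: dict[int, VegClassParams]):
    """(eps_max, ndvi_min, ndvi_max, sr_min, sr_max) arrays per pixel."""
    present = np.unique(vegtype.values[~vegtype.mask])
    missing = [int(c) for c in present if int(c) not in params]
    if missing:
        raise GridError(f"vegetation classes without parameters: {missing}")
    max_id = int(max(params)) + 1
    lut = np.zeros((5, max_id + 1))
    for cid, p in params.items():
        lut[:, cid] = (p.eps_max, p.ndvi_min, p.ndvi_max, p.sr_min, p.sr_max)
    idx = np.clip(vegtype.values.astype(int), 0, max_id)
    return tuple(lut[i][idx] for i in range(5))


# ---------------------------------------------------------------------------
# FPAR / APAR
# ---------------------------------------------------------------------------

def sr_index(ndvi: Grid) -> Grid:
    """Simple ratio SR = (1 + NDVI) / (1 - NDVI), NDVI clipped below 1."""
    return ndvi.copy_with(_sr(ndvi.values.astype(float)).astype(np.float32))


def _rescale_fpar(x, lo, hi):
    f = (x - lo) * (FPAR_MAX - FPAR_MIN) / (hi - lo) + FPAR_MIN
    return np.clip(f, FPAR_MIN, FPAR_MAX)


def fpar_from_ndvi(ndvi: Grid, vegtype: Grid, params: dict[int, VegClassParams]) -> Grid:
    ndvi.require_compatible(vegtype, "FPAR computation")
    _, lo, hi, _, _ = _per_class_fields(vegtype, params)
    nd = np.clip(ndvi.values.astype(float), _NDVI_CLIP_LO, _NDVI_CLIP_HI)
    f = _rescale_fpar(nd, lo, hi)
    f[nd < 0] = FPAR_MIN  # non-vegetated surfaces
    return Grid(f.astype(np.float32), ndvi.transform, ndvi.mask | vegtype.mask, ndvi.crs)


def fpar_from_sr(sr: Grid, vegtype: Grid, params: dict[int, VegClassParams]) -> Grid:
    sr.require_compatible(vegtype, "FPAR computation")
    _, _, _, lo, hi = _per_class_fields(vegtype, params)
    f = _rescale_fpar(sr.values.astype(float), lo, hi)
    return Grid(f.astype(np.float32), sr.transform, sr.mask | vegtype.mask, sr.crs)


def fpar_combined(fpar_ndvi: Grid, fpar_sr: Grid) -> Grid:
    fpar_ndvi.require_compatible(fpar_sr, "FPAR averaging")
    mean = (fpar_ndvi.values.astype(float) + fpar_sr.values.astype(float)) / 2.0
    return Grid(mean.astype(np.float32), fpar_ndvi.transform,
                fpar_ndvi.mask | fpar_sr.mask, fpar_ndvi.crs)


def apar(fpar: Grid, sol: Grid) -> Grid:
    """APAR = FPAR x SOL x 0.5 (0.5 = photosynthetically active fraction)."""
    fpar.require_compatible(sol, "APAR computation")
    if np.any(sol.values[~sol.mask] < 0):
        raise GridError("negative solar radiation")
    out = fpar.values.astype(float) * sol.values.astype(float) * 0.5
    return Grid(out.astype(np.float32), fpar.transform, fpar.mask | sol.mask, fpar.crs)


# ---------------------------------------------------------------------------
# Stress terms
# ---------------------------------------------------------------------------

def optimal_temperature(ndvi_cube: RasterCube, temp_cube: RasterCube) -> Grid:
    """Per-pixel optimal temperature: the multi-year mean temperature of the
    calendar month whose multi-year mean NDVI is maximal (ties -> earliest
    month)."""
    if ndvi_cube.times != temp_cube.times:
        raise GridError("NDVI and temperature cubes must cover the same months")
    months = sorted({t[1] for t in ndvi_cube.times})
    ndvi_monthly = []
    temp_monthly = []
    for m in months:
        sel_n = ndvi_cube.select(lambda t: t[1] == m).stack()
        sel_t = temp_cube.select(lambda t: t[1] == m).stack()
        ndvi_monthly.append(sel_n.mean(axis=0))
        temp_monthly.append(sel_t.mean(axis=0))
    ndvi_stack = np.ma.stack(ndvi_monthly)
    temp_stack = np.ma.stack(temp_monthly)
    best = np.ma.argmax(ndvi_stack, axis=0)  # first occurrence wins ties
    rows, cols = ndvi_cube.layers[0].shape
    topt = np.take_along_axis(temp_stack, best[None], axis=0)[0]
    mask = np.ma.getmaskarray(ndvi_stack).all(axis=0) | np.ma.getmaskarray(temp_stack).all(axis=0)
    template = temp_cube.layers[0]
    return Grid(np.asarray(np.ma.filled(topt, 0), dtype=np.float32),
                template.transform, mask, template.crs)


def temperature_stress(topt: Grid, temp: Grid) -> tuple[Grid, Grid]:
    """T1 = 0.8 + 0.02 Topt - 0.0005 Topt^2 (floored at 0, and 0 where the
    monthly temperature is at or below -10 degC); T2 is the double-logistic
    down-regulation around Topt."""
    topt.require_compatible(temp, "temperature stress")
    to = topt.values.astype(float)
    t = temp.values.astype(float)
    t1 = np.clip(0.8 + 0.02 * to - 0.0005 * to * to, 0.0, None)
    t1[t <= -10.0] = 0.0
    t2 = 1.1814 / ((1.0 + np.exp(0.2 * (to - 10.0 - t))) * (1.0 + np.exp(0.3 * (-to - 10.0 + t))))
    mask = topt.mask | temp.mask
    return (
        Grid(t1.astype(np.float32), topt.transform, mask.copy(), topt.crs),
        Grid(t2.astype(np.float32), topt.transform, mask.copy(), topt.crs),
    )


def water_stress_ratio(e_actual, e_potential):
    """W = 0.5 + 0.5 E/Ep, clipped to [0.5, 1]; 0.5 where Ep = 0."""
    e = np.asarray(e_actual, dtype=float)
    ep = np.asarray(e_potential, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(ep > 0, e / np.where(ep > 0, ep, 1.0), 0.0)
    return np.clip(0.5 + 0.5 * ratio, 0.5, 1.0)


def _thornthwaite_pet(temp_monthly: np.ndarray) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) from monthly temperature,
    Thornthwaite's formulation with the annual heat index."""
    t = np.clip(temp_monthly, 0.0, None)
    heat = ((t / 5.0) ** 1.514).sum(axis=0)
    heat = np.maximum(heat, 1e-6)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    return 16.0 * (10.0 * t / heat) ** a


def water_stress(precip_cube: RasterCube, temp_cube: RasterCube,
                 sol_cube: RasterCube | None = None) -> RasterCube:
    """Monthly moisture stress cube.

    Estimated actual ET comes from the precipitation/net-radiation
    complementary formula with net radiation approximated from potential ET
    and precipitation; potential ET is the mean of local potential ET and the
    estimated actual ET.  The radiation cube is accepted for interface
    symmetry but the adopted closure is driven by precipitation and
    temperature alone.
    """
    if precip_cube.times != temp_cube.times:
        raise GridError("precipitation and temperature cubes must share months")
    years = precip_cube.years
    template = precip_cube.layers[0]
    layers, times = [], []
    for year in years:
        p_year = precip_cube.for_year(year)
        t_year = temp_cube.for_year(year)
        p = np.stack([np.clip(g.values.astype(float), 0, None) for g in p_year.layers])
        t = np.stack([g.values.astype(float) for g in t_year.layers])
        pet_local = _thornthwaite_pet(t)
        with np.errstate(invalid="ignore", divide="ignore"):
            rn = np.where(p > 0,
                          np.sqrt(pet_local * p) * (0.369 + 0.598 * np.sqrt(
                              np.where(p > 0, pet_local / np.where(p > 0, p, 1.0), 0.0))),
                          0.0)
            denom = (p + rn) * (p * p + rn * rn)
            e_act = np.where(denom > 0, p * rn * (p * p + rn * rn + p * rn) / np.where(denom > 0, denom, 1.0), 0.0)
        e_pot = (e_act + pet_local) / 2.0
        w = water_stress_ratio(e_act, e_pot)
        mask_any = np.zeros(template.shape, dtype=bool)
        for gp, gt in zip(p_year.layers, t_year.layers):
            mask_any |= gp.mask | gt.mask
        for m, (gp, time) in enumerate(zip(p_year.layers, p_year.times)):
            layers.append(Grid(w[m].astype(np.float32), template.transform,
                               (gp.mask | mask_any).copy(), template.crs))
            times.append(time)
    return RasterCube(layers, times)


# ---------------------------------------------------------------------------
# NPP assembly
# ---------------------------------------------------------------------------

def monthly_npp(fpar: Grid, sol: Grid, t1: Grid, t2: Grid, w: Grid,
                vegtype: Grid, params: dict[int, VegClassParams]) -> Grid:
    """NPP = APAR x T1 x T2 x W x eps_max(class), nonnegative, masked where
    any input is masked."""
    ap = apar(fpar, sol)
    eps_max, *_ = _per_class_fields(vegtype, params)
    out = ap.values.astype(float) * t1.values * t2.values * w.values * eps_max
    mask = ap.mask | t1.mask | t2.mask | w.mask | vegtype.mask
    return Grid(np.clip(out, 0.0, None).astype(np.float32), ap.transform, mask, ap.crs)


def annual_npp(monthly: RasterCube) -> Grid:
    """Per-pixel sum of 12 monthly layers (gC m-2 yr-1)."""
    if len(monthly) != 12:
        raise GridError(f"annual total needs exactly 12 monthly layers, got {len(monthly)}")
    stack = monthly.stack()
    total = stack.sum(axis=0)
    template = monthly.layers[0]
    # a pixel is masked if any month is masked (mask propagation)
    mask = np.ma.getmaskarray(stack).any(axis=0)
    return Grid(np.asarray(np.ma.filled(total, 0), dtype=np.float32),
                template.transform, mask, template.crs)


def run_casa_year(ndvi: RasterCube, sol: RasterCube, temp: RasterCube,
                  precip: RasterCube, vegtype: Grid,
                  params: dict[int, VegClassParams] | None = None,
                  topt: Grid | None = None) -> tuple[RasterCube, Grid]:
    """Run the model for one year of monthly cubes; returns (monthly NPP cube,
    annual NPP grid).  ``topt`` may be precomputed over the full record."""
    params = params or default_params()
    if topt is None:
        topt = optimal_temperature(ndvi, temp)
    w_cube = water_stress(precip, temp, sol)
    layers, times = [], []
    for g_ndvi, g_sol, g_temp, g_w, time in zip(
            ndvi.layers, sol.layers, temp.layers, w_cube.layers, ndvi.times):
        f_n = fpar_from_ndvi(g_ndvi, vegtype, params)
        f_s = fpar_from_sr(sr_index(g_ndvi), vegtype, params)
        fpar = fpar_combined(f_n, f_s)
        t1, t2 = temperature_stress(topt, g_temp)
        layers.append(monthly_npp(fpar, g_sol, t1, t2, g_w, vegtype, params))
        times.append(time)
    cube = RasterCube(layers, times)
    return cube, annual_npp(cube)


def total_npp_tgc(npp_annual: Grid) -> float:
    """Regional total NPP in TgC: sum(pixel gC m-2 x pixel m^2) x 1e-12."""
    pixel_m2 = npp_annual.pixel_area_km2 * 1e6
    return float(npp_annual.unmasked().astype(float).sum() * pixel_m2 * 1e-12)
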