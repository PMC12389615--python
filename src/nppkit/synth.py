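"""Synthetic study-scenario generator.

Builds raster cubes and static layers with *known, recoverable* structure:
north-south gradients, seasonal cycles, prescribed per-pixel linear trends,
a prescribed partial-correlation structure between annual productivity and
the three climate drivers (via a joint Gaussian), latent vegetation strata
that explain a controllable share of the response variance, and an exact
land-use transition plan.  Every generator parameter is the ground truth
for a downstream recovery test.

Determinism: all randomness flows from ``ScenarioConfig.seed`` through named
child streams, so an identical config reproduces identical rasters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import Grid, GridTransform, RasterCube

__all__ = [
    "ScenarioConfig",
    "TransitionStep",
    "driver_correlation_matrix",
    "analytic_partial_correlations",
    "generate_climate_cubes",
    "generate_ndvi_cube",
    "generate_static_layers",
    "generate_landuse_series",
    "generate_reference_npp",
    "response_base_field",
    "strata_labels",
    "generate_scenario",
]

# Named RNG sub-streams (stable identifiers; do not reorder).
_STREAM_LATENT = 11
_STREAM_CLIMATE = 12
_STREAM_NDVI = 13
_STREAM_STATIC = 14
_STREAM_LANDUSE = 15
_STREAM_STRATA = 16

LANDUSE_CLASSES = {
    1: "farmland",
    2: "woodland",
    3: "grassland",
    4: "water body",
    5: "unused land",
    6: "construction land",
}


@dataclass(frozen=True)
class TransitionStep:
    """One planned land-use conversion: ``area_km2`` moves from one class to
    another starting at ``year`` (inclusive)."""

    from_class: int
    to_class: int
    area_km2: float
    year: int


@dataclass
class ScenarioConfig:
    shape: tuple[int, int] = (120, 120)
    pixel_size_m: float = 500.0
    year_start: int = 2001
    year_end: int = 2020
    seed: int = 0
    n_veg_classes: int = 6
    crs: str = "EPSG:3395"
    origin: tuple[float, float] = (1_000_000.0, 5_000_000.0)

    # Ground-truth targets -------------------------------------------------
    #: per-pixel NPP trend, gC m-2 yr-1 per yr (scalar or (rows, cols) array)
    trend_slope: float | np.ndarray = 0.0
    #: target partial correlations of annual NPP with (precip, temp, solrad)
    partial_corr_targets: tuple[float, float, float] = (0.30, 0.17, 0.09)
    #: share of response variance explained by the vegetation strata
    strata_q_target: float = 0.5
    transition_plan: list[TransitionStep] = field(default_factory=list)

    # Shape of the synthetic world ----------------------------------------
    strata_block: int = 8            # strata piecewise-constant on blocks (px)
    npp_anomaly_scale: float = 12.0  # sd of the annual NPP anomaly, gC m-2 yr-1

    precip_base: float = 30.0        # mm per month
    precip_gradient: float = 10.0    # north-south swing
    precip_seasonal: float = 20.0
    precip_annual_sd: float = 40.0   # sd of the annual-total anomaly, mm
    precip_month_sd: float = 4.0

    temp_base: float = 8.0           # deg C
    temp_gradient: float = 4.0
    temp_seasonal: float = 15.0
    temp_annual_sd: float = 0.6      # sd of the annual-mean anomaly
    temp_month_sd: float = 1.0

    solrad_base: float = 450.0       # MJ m-2 per month
    solrad_gradient: float = 30.0
    solrad_seasonal: float = 180.0
    solrad_annual_sd: float = 150.0  # sd of the annual-total anomaly
    solrad_month_sd: float = 10.0

    # climate trends per year (annual-aggregate units)
    precip_trend: float = 0.0
    temp_trend: float = 0.0
    solrad_trend: float = 0.0

    ndvi_base: float = 0.15
    ndvi_precip_weight: float = 0.35
    ndvi_temp_weight: float = 0.10
    ndvi_month_sd: float = 0.01
    #: NDVI trend per unit NPP trend (yr-1 per gC m-2 yr-1)
    ndvi_trend_per_npp: float = 0.001

    def __post_init__(self) -> None:
        for name, t in zip(("precipitation", "temperature", "radiation"), self.partial_corr_targets):
            if not -1 < t < 1:
                raise ValueError(f"partial correlation target for {name} must lie in (-1, 1), got {t}")
        if not 0 <= self.strata_q_target <= 1:
            raise ValueError(f"strata_q_target must lie in [0, 1], got {self.strata_q_target}")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")

    # -- derived ----------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def transform(self) -> GridTransform:
        return GridTransform(self.origin[0], self.origin[1], self.pixel_size_m, self.pixel_size_m)

    def trend_field(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.trend_slope, dtype=float), self.shape)

    def grid(self, values: np.ndarray, mask: np.ndarray | None = None) -> Grid:
        return Grid(values, self.transform, mask, self.crs)


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _ns_gradient(cfg: ScenarioConfig, amplitude: float) -> np.ndarray:
    """Linear north(-)-to-south(+) gradient in [-amplitude, +amplitude]."""
    rows, cols = cfg.shape
    ramp = np.linspace(-1.0, 1.0, rows)[:, None]
    return np.broadcast_to(amplitude * ramp, (rows, cols)).copy()


# ---------------------------------------------------------------------------
# Correlated annual anomalies
# ---------------------------------------------------------------------------

def driver_correlation_matrix(targets: tuple[float, float, float]) -> np.ndarray:
    """4x4 correlation matrix of (NPP, precip, temp, solrad) annual anomalies
    whose second-order partial correlations of NPP with each driver equal the
    prescribed targets.

    Built from a precision matrix with unit diagonal, ``-target`` in the NPP
    row/column and conditionally independent drivers, so the targets are
    exact by the precision-matrix identity r_ij·rest = -p_ij/sqrt(p_ii p_jj).
    """
    t = np.asarray(targets, dtype=float)
    precision = np.eye(4)
    precision[0, 1:] = -t
    precision[1:, 0] = -t
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError:
        worst = ("precipitation", "temperature", "radiation")[int(np.argmax(np.abs(t)))]
        raise ValueError(
            f"partial-correlation targets {tuple(t)} are infeasible (correlation matrix "
            f"not positive definite); reduce the {worst} target"
        ) from None
    cov = np.linalg.inv(precision)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def analytic_partial_correlations(corr: np.ndarray) -> np.ndarray:
    """Partial correlations of variable 0 with 1..3 given the rest, from the
    inverse correlation (precision) matrix."""
    p = np.linalg.inv(corr)
    return np.array([-p[0, j] / np.sqrt(p[0, 0] * p[j, j]) for j in range(1, corr.shape[0])])


def latent_annual_anomalies(cfg: ScenarioConfig) -> np.ndarray:
    """(n_years, rows, cols, 4) standardized anomalies of
    (NPP, precip, temp, solrad) with the prescribed correlation structure."""
    corr = driver_correlation_matrix(cfg.partial_corr_targets)
    chol = np.linalg.cholesky(corr)
    rng = _rng(cfg, _STREAM_LATENT)
    z = rng.standard_normal((cfg.n_years, *cfg.shape, 4))
    return z @ chol.T


def _zero_mean_monthly_noise(rng: np.random.Generator, sd: float, n_years: int, shape) -> np.ndarray:
    """(years, 12, rows, cols) noise whose within-year mean is exactly zero,
    so monthly texture never perturbs the prescribed annual aggregates."""
    eps = rng.standard_normal((n_years, 12, *shape)) * sd
    return eps - eps.mean(axis=1, keepdims=True)


def generate_climate_cubes(cfg: ScenarioConfig) -> tuple[RasterCube, RasterCube, RasterCube]:
    """Monthly precipitation (mm), temperature (degC) and solar radiation
    (MJ m-2) cubes.

    Each has a north-south gradient, a sinusoidal seasonal cycle, a linear
    interannual trend and pixel noise; the *annual aggregates* (total precip,
    mean temp, total radiation) carry the prescribed correlation structure
    exactly because monthly noise is constrained to zero within-year mean.
    """
    anom = latent_annual_anomalies(cfg)
    rng = _rng(cfg, _STREAM_CLIMATE)
    months = np.arange(12)
    season = np.sin(2 * np.pi * (months - 3) / 12)  # peak around July

    specs = {
        "precip": (cfg.precip_base, cfg.precip_gradient, cfg.precip_seasonal,
                   cfg.precip_annual_sd, cfg.precip_month_sd, cfg.precip_trend, 1, "sum"),
        "temp": (cfg.temp_base, cfg.temp_gradient, cfg.temp_seasonal,
                 cfg.temp_annual_sd, cfg.temp_month_sd, cfg.temp_trend, 2, "mean"),
        "solrad": (cfg.solrad_base, cfg.solrad_gradient, cfg.solrad_seasonal,
                   cfg.solrad_annual_sd, cfg.solrad_month_sd, cfg.solrad_trend, 3, "sum"),
    }
    cubes = {}
    for name, (base, grad, seas, annual_sd, month_sd, trend, idx, agg) in specs.items():
        gradient = _ns_gradient(cfg, grad)
        noise = _zero_mean_monthly_noise(rng, month_sd, cfg.n_years, cfg.shape)
        layers, times = [], []
        for yi, year in enumerate(cfg.years):
            annual_anom = anom[yi, :, :, idx] * annual_sd
            # distribute the annual anomaly so the aggregate matches exactly
            per_month_anom = annual_anom / 12 if agg == "sum" else annual_anom
            per_month_trend = trend * yi / 12 if agg == "sum" else trend * yi
            for m in range(12):
                vals = base + gradient + seas * season[m] + per_month_trend \
                    + per_month_anom + noise[yi, m]
                layers.append(cfg.grid(vals.astype(np.float32)))
                times.append((year, m + 1))
        cubes[name] = RasterCube(layers, times)
    return cubes["precip"], cubes["temp"], cubes["solrad"]


# ---------------------------------------------------------------------------
# Strata / response base field
# ---------------------------------------------------------------------------

def strata_labels(cfg: ScenarioConfig) -> np.ndarray:
    """Vegetation-stratum labels (1..n_veg_classes), constant on
    ``strata_block``-sized blocks."""
    rng = _rng(cfg, _STREAM_STRATA)
    rows, cols = cfg.shape
    b = cfg.strata_block
    br = -(-rows // b)
    bc = -(-cols // b)
    blocks = rng.integers(1, cfg.n_veg_classes + 1, size=(br, bc))
    return np.kron(blocks, np.ones((b, b), dtype=np.int16))[:rows, :cols].astype(np.int16)


def response_base_field(cfg: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """(labels, base) where the strata explain exactly ``strata_q_target`` of
    the population variance of the base response field.

    Stratum means are fixed offsets; within-stratum Gaussian noise variance is
    calibrated against the realized between-strata variance so that
    between/(between+within) equals the target.
    """
    labels = strata_labels(cfg)
    q = cfg.strata_q_target
    if q == 0:
        means = np.zeros(cfg.n_veg_classes + 1)
        base_between = 60.0  # no between-strata signal; noise carries all variance
        sigma_within = base_between
    else:
        means = np.arange(cfg.n_veg_classes + 1) * 55.0
        stratum_mean = means[labels]
        between_var = float(stratum_mean.var())
        sigma_within = np.sqrt(between_var * (1 - q) / q) if q < 1 else 0.0
    rng = _rng(cfg, _STREAM_STATIC)
    noise = rng.standard_normal(cfg.shape) * sigma_within
    base = 80.0 + means[labels] + noise
    return labels, base


def generate_static_layers(cfg: ScenarioConfig) -> dict[str, Grid]:
    """Static layers: vegtype, elevation, slope, aspect, soil_moisture, gdp,
    popdens.  vegtype carries the q-calibrated strata; slope/aspect derive
    from elevation by central differences."""
    labels, base = response_base_field(cfg)
    rng = _rng(cfg, _STREAM_STATIC + 100)
    rows, cols = cfg.shape
    rr, cc = np.mgrid[0:rows, 0:cols]

    elevation = (
        600.0
        + 1600.0 * (rr / max(rows - 1, 1))          # rises to the south
        + 250.0 * np.sin(2 * np.pi * cc / max(cols, 1))
        + ndimage.gaussian_filter(rng.standard_normal(cfg.shape), sigma=8) * 120.0
    )
    gy, gx = np.gradient(elevation, cfg.pixel_size_m)
    gy = -gy  # row index increases southwards; flip to northing gradient
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = (np.degrees(np.arctan2(-gx, -gy))) % 360.0  # downslope compass direction

    base_norm = (base - base.min()) / max(np.ptp(base), 1e-9)
    soil_moisture = np.clip(
        0.08 + 0.45 * base_norm + ndimage.gaussian_filter(rng.standard_normal(cfg.shape), 4) * 0.03,
        0.0, 1.0,
    )
    gdp = np.exp(1.5 * ndimage.gaussian_filter(rng.standard_normal(cfg.shape), 10)) * 50.0
    popdens = np.exp(1.2 * ndimage.gaussian_filter(rng.standard_normal(cfg.shape), 12)) * 20.0

    return {
        "vegtype": cfg.grid(labels),
        "elevation": cfg.grid(elevation.astype(np.float32)),
        "slope": cfg.grid(slope.astype(np.float32)),
        "aspect": cfg.grid(aspect.astype(np.float32)),
        "soil_moisture": cfg.grid(soil_moisture.astype(np.float32)),
        "gdp": cfg.grid(gdp.astype(np.float32)),
        "popdens": cfg.grid(popdens.astype(np.float32)),
    }


# ---------------------------------------------------------------------------
# NDVI and reference NPP
# ---------------------------------------------------------------------------

def generate_ndvi_cube(cfg: ScenarioConfig, temp: RasterCube, precip: RasterCube) -> RasterCube:
    """Monthly NDVI responding monotonically to precipitation and (growing
    season) temperature, with a prescribed per-pixel interannual trend.

    The response terms are nonnegative saturating functions of the drivers,
    so increasing a response weight can never decrease NDVI.
    """
    if temp.times != precip.times:
        raise ValueError("temperature and precipitation cubes must share the same months")
    trend = cfg.trend_field() * cfg.ndvi_trend_per_npp
    rng = _rng(cfg, _STREAM_NDVI)
    layers, times = [], []
    year0 = temp.times[0][0]
    for grid_t, grid_p, (year, month) in zip(temp.layers, precip.layers, temp.times):
        p = np.maximum(grid_p.values.astype(float), 0.0)
        t = grid_t.values.astype(float)
        p_resp = cfg.ndvi_precip_weight * p / (p + 40.0)
        t_resp = cfg.ndvi_temp_weight * np.clip(t, 0.0, None) / (np.clip(t, 0.0, None) + 15.0)
        season_shape = np.sin(2 * np.pi * (month - 4) / 12) * 0.5 + 0.5
        vals = (
            cfg.ndvi_base
            + season_shape * (p_resp + t_resp)
            + trend * (year - year0)
            + rng.standard_normal(cfg.shape) * cfg.ndvi_month_sd
        )
        layers.append(cfg.grid(np.clip(vals, -0.1, 0.95).astype(np.float32)))
        times.append((year, month))
    return RasterCube(layers, times)


def generate_reference_npp(cfg: ScenarioConfig) -> RasterCube:
    """Annual reference NPP cube (gC m-2 yr-1): strata-driven base field +
    prescribed per-pixel linear trend + correlated annual anomaly.

    This is the ground-truth response used by the trend-recovery,
    partial-correlation-recovery and detector-recovery tests, and serves as
    the reference product in the validation regression.
    """
    _, base = response_base_field(cfg)
    anom = latent_annual_anomalies(cfg)[:, :, :, 0] * cfg.npp_anomaly_scale
    trend = cfg.trend_field()
    layers, times = [], []
    for yi, year in enumerate(cfg.years):
        vals = base + trend * yi + anom[yi]
        layers.append(cfg.grid(vals.astype(np.float32)))
        times.append((year,))
    return RasterCube(layers, times)


# ---------------------------------------------------------------------------
# Land use
# ---------------------------------------------------------------------------

def base_landuse(cfg: ScenarioConfig) -> np.ndarray:
    """Initial 6-class land-use map, blockwise like the strata."""
    rng = _rng(cfg, _STREAM_LANDUSE)
    rows, cols = cfg.shape
    b = cfg.strata_block
    br, bc = -(-rows // b), -(-cols // b)
    probs = np.array([0.12, 0.06, 0.42, 0.04, 0.30, 0.06])
    blocks = rng.choice(np.arange(1, 7), size=(br, bc), p=probs)
    return np.kron(blocks, np.ones((b, b), dtype=np.int16))[:rows, :cols].astype(np.int16)


def generate_landuse_series(cfg: ScenarioConfig) -> RasterCube:
    """Annual 6-class land-use cube applying the transition plan exactly.

    Each planned step converts ``floor(area / pixel_area)`` pixels of the
    source class starting at its year; pixels are chosen by seeded sampling,
    so the realized transition matrix equals the plan deterministically.
    """
    current = base_landuse(cfg)
    rng = _rng(cfg, _STREAM_LANDUSE + 1)
    pixel_area = cfg.transform.pixel_area_km2
    layers, times = [], []
    plan_by_year: dict[int, list[TransitionStep]] = {}
    for step in cfg.transition_plan:
        if step.from_class not in LANDUSE_CLASSES or step.to_class not in LANDUSE_CLASSES:
            raise ValueError(f"unknown land-use class in plan step {step}")
        plan_by_year.setdefault(step.year, []).append(step)

    for year in cfg.years:
        for step in plan_by_year.get(year, []):
            n_pixels = int(step.area_km2 / pixel_area)
            candidates = np.flatnonzero(current == step.from_class)
            if len(candidates) < n_pixels:
                raise ValueError(
                    f"transition {step}: requested {n_pixels} pixels but only "
                    f"{len(candidates)} available in class {step.from_class}"
                )
            chosen = rng.choice(candidates, size=n_pixels, replace=False)
            current.flat[chosen] = step.to_class
        layers.append(cfg.grid(current.copy()))
        times.append((year,))
    return RasterCube(layers, times)


# ---------------------------------------------------------------------------
# Full scenario bundle
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    config: ScenarioConfig
    precip: RasterCube
    temp: RasterCube
    solrad: RasterCube
    ndvi: RasterCube
    landuse: RasterCube
    static: dict[str, Grid]
    reference_npp: RasterCube


def generate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate the complete layer set for one synthetic study."""
    precip, temp, solrad = generate_climate_cubes(cfg)
    ndvi = generate_ndvi_cube(cfg, temp, precip)
    return Scenario(
        config=cfg,
        precip=precip,
        temp=temp,
        solrad=solrad,
        ndvi=ndvi,
        landuse=generate_landuse_series(cfg),
        static=generate_static_layers(cfg),
        reference_npp=generate_reference_npp(cfg),
    )


def scenario_manifest(cfg: ScenarioConfig) -> dict:
    """Ground-truth parameters of a scenario, for the synthesize CLI manifest."""
    d = dataclasses.asdict(cfg)
    d["trend_slope"] = float(np.mean(cfg.trend_field()))
    d["transition_plan"] = [dataclasses.asdict(s) for s in cfg.transition_plan]
    return d
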