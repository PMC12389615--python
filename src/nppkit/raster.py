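"""Grid / cube data model and GeoTIFF plumbing.

A :class:`Grid` is a single 2-D georeferenced raster layer in a projected,
metric CRS: values, an axis-aligned geotransform, a nodata mask and a CRS
label.  Row 0 is the northernmost row and all coordinate math uses pixel
centers.  A :class:`RasterCube` is an ordered, time-indexed stack of
mutually aligned grids.

GeoTIFF exchange is implemented on top of :mod:`tifffile` with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory, GDAL nodata),
which keeps the on-disk files readable by GDAL-based tools without pulling a
GDAL dependency into the runtime.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "GridTransform",
    "RasterCube",
    "read_grid",
    "write_grid",
    "align",
    "aggregate",
    "monthly_max_composite",
]

# TIFF tag codes used for georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

# GeoKey ids.
_KEY_MODEL_TYPE = 1024          # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025         # 1 = PixelIsArea
_KEY_CITATION = 1026
_KEY_PROJECTED_CS_TYPE = 3072

_FLOAT_NODATA = -9999.0
_INT_NODATA = -32768


class GridError(ValueError):
    """Raised for malformed grids or incompatible grid operations."""


@dataclass(frozen=True)
class GridTransform:
    """Axis-aligned geotransform: origin at the NW corner of pixel (0, 0).

    ``dx``/``dy`` are pixel sizes in meters and strictly positive; y
    decreases with increasing row index (row 0 = northernmost row).
    """

    origin_x: float
    origin_y: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0):
            raise GridError(f"pixel size must be strictly positive, got ({self.dx}, {self.dy})")

    @property
    def pixel_area_km2(self) -> float:
        return abs(self.dx * self.dy) / 1e6

    def x_centers(self, ncols: int) -> np.ndarray:
        return self.origin_x + (np.arange(ncols) + 0.5) * self.dx

    def y_centers(self, nrows: int) -> np.ndarray:
        return self.origin_y - (np.arange(nrows) + 0.5) * self.dy

    def scaled(self, factor: int) -> "GridTransform":
        return GridTransform(self.origin_x, self.origin_y, self.dx * factor, self.dy * factor)


def _looks_geographic(crs_label: str) -> bool:
    label = crs_label.strip().upper()
    if label.startswith("EPSG:"):
        try:
            code = int(label.split(":", 1)[1])
        except ValueError:
            return False
        return 4000 <= code <= 4999
    return "LONGLAT" in label or "WGS84 GEOGRAPHIC" in label


@dataclass
class Grid:
    """One georeferenced raster layer (values + transform + mask + CRS)."""

    values: np.ndarray
    transform: GridTransform
    mask: np.ndarray | None = None
    crs: str = "EPSG:3395"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridError(f"grid values must be 2-D, got shape {self.values.shape}")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise GridError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if _looks_geographic(self.crs):
            raise GridError(
                f"geographic CRS {self.crs!r} rejected: grids must use a projected metric CRS"
            )

    # -- basic properties -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_km2(self) -> float:
        return self.transform.pixel_area_km2

    @property
    def is_categorical(self) -> bool:
        return np.issubdtype(self.values.dtype, np.integer)

    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)

    def unmasked(self) -> np.ndarray:
        """1-D array of valid pixel values."""
        return self.values[~self.mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        return Grid(values, self.transform, self.mask.copy() if mask is None else mask, self.crs)

    # -- compatibility ----------------------------------------------------
    def compatible_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.transform == other.transform
            and self.crs == other.crs
        )

    def require_compatible(self, other: "Grid", what: str = "operation") -> None:
        if not self.compatible_with(other):
            raise GridError(
                f"{what} requires identical shape/transform/CRS: "
                f"{self.shape}/{self.transform} vs {other.shape}/{other.transform}"
            )


@dataclass
class RasterCube:
    """Time-indexed stack of aligned grids.

    ``times`` entries are ``(year,)`` for annual stacks or ``(year, month)``
    for monthly stacks, strictly increasing with no duplicates.
    """

    layers: list[Grid]
    times: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.times):
            raise GridError("layers and times must have equal length")
        if not self.layers:
            raise GridError("cube must contain at least one layer")
        first = self.layers[0]
        for layer in self.layers[1:]:
            first.require_compatible(layer, "cube stacking")
        times = [tuple(t) for t in self.times]
        if any(len(t) != len(times[0]) for t in times):
            raise GridError("mixed time-index arity")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise GridError(f"time index must be strictly increasing: {times}")
        self.times = times

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    @property
    def years(self) -> list[int]:
        return sorted({t[0] for t in self.times})

    def stack(self) -> np.ma.MaskedArray:
        """(time, row, col) masked array view of the cube."""
        values = np.stack([g.values for g in self.layers])
        mask = np.stack([g.mask for g in self.layers])
        return np.ma.MaskedArray(values, mask=mask)

    def select(self, predicate) -> "RasterCube":
        pairs = [(g, t) for g, t in zip(self.layers, self.times) if predicate(t)]
        if not pairs:
            raise GridError("selection produced an empty cube")
        return RasterCube([p[0] for p in pairs], [p[1] for p in pairs])

    def for_year(self, year: int) -> "RasterCube":
        return self.select(lambda t: t[0] == year)

    def layer_at(self, time: tuple[int, ...]) -> Grid:
        time = tuple(time)
        return self.layers[self.times.index(time)]


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def _crs_geokeys(crs: str) -> tuple[list[int], str]:
    """Build a GeoKeyDirectory (projected model) plus ASCII citation."""
    ascii_params = crs + "|"
    epsg = 32767  # user-defined
    label = crs.strip().upper()
    if label.startswith("EPSG:"):
        try:
            epsg = int(label.split(":", 1)[1])
        except ValueError:
            pass
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 1),
        (_KEY_RASTER_TYPE, 0, 1, 1),
        (_KEY_CITATION, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0),
        (_KEY_PROJECTED_CS_TYPE, 0, 1, epsg),
    ]
    directory = [1, 1, 0, len(keys)]
    for k in keys:
        directory.extend(k)
    return directory, ascii_params


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as a single-band GeoTIFF.

    Integer layers are stored as int16 (bit-faithful); continuous layers as
    float32.  Masked pixels are written as the nodata value recorded in the
    GDAL nodata tag.
    """
    path = Path(path)
    if grid.is_categorical:
        nodata: float | int = _INT_NODATA
        data = grid.values.astype(np.int16).copy()
    else:
        nodata = _FLOAT_NODATA
        data = grid.values.astype(np.float32).copy()
    data[grid.mask] = nodata

    directory, ascii_params = _crs_geokeys(grid.crs)
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(t.dx), float(t.dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(t.origin_x), float(t.origin_y), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(directory), tuple(directory)),
        (_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", len(str(nodata)) + 1, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_grid(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF written by :func:`write_grid` (or GDAL)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = {tag.code: tag.value for tag in page.tags.values()}
    except (OSError, tifffile.TiffFileError) as exc:
        raise GridError(f"cannot read GeoTIFF {path}: {exc}") from exc

    if data.ndim != 2:
        raise GridError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise GridError(f"{path}: missing geotransform tags (not a GeoTIFF?)")

    sx, sy = float(tags[_TAG_MODEL_PIXEL_SCALE][0]), float(tags[_TAG_MODEL_PIXEL_SCALE][1])
    tie = tags[_TAG_MODEL_TIEPOINT]
    # Tiepoint maps raster (i, j) -> model (x, y); normalize to raster origin.
    origin_x = float(tie[3]) - float(tie[0]) * sx
    origin_y = float(tie[4]) + float(tie[1]) * sy
    transform = GridTransform(origin_x, origin_y, sx, sy)

    crs = "unknown-projected"
    if _TAG_GEO_KEY_DIRECTORY in tags:
        directory = list(tags[_TAG_GEO_KEY_DIRECTORY])
        nkeys = directory[3]
        keys = {}
        for i in range(nkeys):
            kid, loc, _count, val = directory[4 + 4 * i : 8 + 4 * i]
            keys[kid] = (loc, val)
        if keys.get(_KEY_MODEL_TYPE, (0, 1))[1] == 2:
            raise GridError(f"{path}: geographic CRS rejected; reproject to a metric CRS first")
        if _KEY_PROJECTED_CS_TYPE in keys:
            epsg = keys[_KEY_PROJECTED_CS_TYPE][1]
            if epsg != 32767:
                crs = f"EPSG:{epsg}"
    if crs == "unknown-projected" and _TAG_GEO_ASCII_PARAMS in tags:
        crs = str(tags[_TAG_GEO_ASCII_PARAMS]).split("|")[0].strip() or crs

    mask = np.zeros(data.shape, dtype=bool)
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        except ValueError:
            nodata = None
        if nodata is not None:
            if np.isnan(nodata):
                mask = np.isnan(data)
            else:
                mask = data == nodata
    if np.issubdtype(data.dtype, np.floating):
        mask |= np.isnan(data)
        data = data.astype(np.float32)
    return Grid(data, transform, mask, crs)


# ---------------------------------------------------------------------------
# Alignment / resampling
# ---------------------------------------------------------------------------

def _sample_nearest(grid: Grid, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ri = np.round(rows - 0.5).astype(int)
    ci = np.round(cols - 0.5).astype(int)
    nr, nc = grid.shape
    out_of_range = (ri < 0) | (ri >= nr) | (ci < 0) | (ci >= nc)
    ri = np.clip(ri, 0, nr - 1)
    ci = np.clip(ci, 0, nc - 1)
    values = grid.values[ri, ci]
    mask = grid.mask[ri, ci] | out_of_range
    return values, mask


def _sample_bilinear(grid: Grid, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # rows/cols are fractional pixel-center coordinates (0.5 = first center)
    fr = rows - 0.5
    fc = cols - 0.5
    r0 = np.floor(fr).astype(int)
    c0 = np.floor(fc).astype(int)
    tr = fr - r0
    tc = fc - c0
    nr, nc = grid.shape
    r0c = np.clip(r0, 0, nr - 1)
    r1c = np.clip(r0 + 1, 0, nr - 1)
    c0c = np.clip(c0, 0, nc - 1)
    c1c = np.clip(c0 + 1, 0, nc - 1)
    v = grid.values.astype(np.float64)
    out = (
        v[r0c, c0c] * (1 - tr) * (1 - tc)
        + v[r0c, c1c] * (1 - tr) * tc
        + v[r1c, c0c] * tr * (1 - tc)
        + v[r1c, c1c] * tr * tc
    )
    m = grid.mask
    mask = m[r0c, c0c] | m[r0c, c1c] | m[r1c, c0c] | m[r1c, c1c]
    out_of_range = (fr < -0.5) | (fr > nr - 0.5) | (fc < -0.5) | (fc > nc - 0.5)
    return out.astype(np.float32), mask | out_of_range


def align(grids: Sequence[Grid], target: Grid, method: str = "bilinear") -> list[Grid]:
    """Resample grids onto the target's shape and transform.

    ``method`` is ``"nearest"`` or ``"bilinear"``; categorical (integer)
    layers must use nearest.  All grids must share the target's CRS
    (reprojection between CRSs is out of scope).
    """
    if method not in ("nearest", "bilinear"):
        raise GridError(f"unknown resampling method {method!r}")
    nrows, ncols = target.shape
    xs = target.transform.x_centers(ncols)
    ys = target.transform.y_centers(nrows)
    out = []
    for grid in grids:
        if grid.crs != target.crs:
            raise GridError(f"CRS mismatch: {grid.crs} vs {target.crs} (no reprojection)")
        if method == "bilinear" and grid.is_categorical:
            raise GridError("bilinear resampling requested for a categorical layer; use nearest")
        if grid.compatible_with(target):
            out.append(Grid(grid.values.copy(), target.transform, grid.mask.copy(), grid.crs))
            continue
        t = grid.transform
        cols = (xs[None, :] - t.origin_x) / t.dx  # fractional pixel coords
        rows = (t.origin_y - ys[:, None]) / t.dy
        rows_b = np.broadcast_to(rows, (nrows, ncols))
        cols_b = np.broadcast_to(cols, (nrows, ncols))
        if method == "nearest":
            values, mask = _sample_nearest(grid, rows_b, cols_b)
            values = values.astype(grid.values.dtype)
        else:
            values, mask = _sample_bilinear(grid, rows_b, cols_b)
        out.append(Grid(values, target.transform, mask, grid.crs))
    return out


# ---------------------------------------------------------------------------
# Aggregation / compositing
# ---------------------------------------------------------------------------

def _pad_to_multiple(values: np.ndarray, mask: np.ndarray, factor: int):
    nr, nc = values.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    if pr or pc:
        values = np.pad(values, ((0, pr), (0, pc)), constant_values=0)
        mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=True)
    return values, mask


def aggregate(grid: Grid, factor: int, stat: str = "mean") -> Grid:
    """Block-aggregate a grid by an integer factor.

    ``mean`` ignores masked cells; ``mode`` (for categorical layers) breaks
    ties deterministically toward the lowest class id.  An output cell is
    masked only if every contributing input cell is masked.
    """
    if factor < 1 or int(factor) != factor:
        raise GridError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return Grid(grid.values.copy(), grid.transform, grid.mask.copy(), grid.crs)
    if factor > max(grid.shape):
        raise GridError(f"factor {factor} exceeds grid extent {grid.shape}")
    if stat not in ("mean", "mode"):
        raise GridError(f"unknown aggregation stat {stat!r}")

    values, mask = _pad_to_multiple(grid.values, grid.mask, factor)
    nr, nc = values.shape
    br, bc = nr // factor, nc // factor

    if stat == "mean":
        v = values.astype(np.float64).copy()
        v[mask] = 0.0
        valid = (~mask).astype(np.float64)
        vsum = v.reshape(br, factor, bc, factor).sum(axis=(1, 3))
        count = valid.reshape(br, factor, bc, factor).sum(axis=(1, 3))
        out_mask = count == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(out_mask, 0.0, vsum / np.maximum(count, 1))
        out = out.astype(np.float32)
    else:
        if not grid.is_categorical:
            raise GridError("mode aggregation requires a categorical (integer) layer")
        blocks = values.reshape(br, factor, bc, factor).transpose(0, 2, 1, 3).reshape(br, bc, -1)
        bmask = mask.reshape(br, factor, bc, factor).transpose(0, 2, 1, 3).reshape(br, bc, -1)
        classes = np.unique(blocks[~bmask]) if (~bmask).any() else np.array([0], dtype=blocks.dtype)
        counts = np.zeros((br, bc, len(classes)), dtype=np.int32)
        for k, cls in enumerate(classes):
            counts[:, :, k] = ((blocks == cls) & ~bmask).sum(axis=2)
        # argmax picks the first (lowest class id) on ties: classes is sorted
        best = counts.argmax(axis=2)
        out = classes[best].astype(grid.values.dtype)
        out_mask = bmask.all(axis=2)
        out[out_mask] = 0

    return Grid(out, grid.transform.scaled(factor), out_mask, grid.crs)


def monthly_max_composite(cube: RasterCube) -> Grid:
    """Per-pixel maximum over the cube's layers (maximum-value compositing).

    A pixel is masked only where every layer masks it.
    """
    stack = cube.stack()
    out = stack.max(axis=0)
    template = cube.layers[0]
    return Grid(
        np.asarray(out.filled(0), dtype=np.float32),
        template.transform,
        np.ma.getmaskarray(out).copy(),
        template.crs,
    )


def total_area_km2(grid: Grid) -> float:
    """Total unmasked area of a grid in km²."""
    return float((~grid.mask).sum()) * grid.pixel_area_km2
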