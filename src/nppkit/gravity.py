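"""Value-weighted centroid of a raster field and its migration trajectory."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Grid, GridError

__all__ = ["Centroid", "MigrationStep", "weighted_centroid", "migration", "trajectory"]


@dataclass(frozen=True)
class Centroid:
    x: float            # easting, m
    y: float            # northing, m
    epoch: int | None
    total_weight: float
    crs: str


@dataclass(frozen=True)
class MigrationStep:
    from_epoch: int | None
    to_epoch: int | None
    distance_m: float
    azimuth_deg: float  # clockwise from north, [0, 360)


def weighted_centroid(grid: Grid, epoch: int | None = None) -> Centroid:
    """Weighted centroid X = sum(w x)/sum(w), Y likewise, using pixel-center
    coordinates in projected meters.  Negative weights are rejected."""
    w = np.where(grid.mask, 0.0, grid.values.astype(float))
    if np.any(w < 0):
        raise GridError("negative weights in centroid computation")
    total = w.sum()
    if total <= 0:
        raise GridError("centroid undefined: no positive-weight unmasked pixels")
    nrows, ncols = grid.shape
    xs = grid.transform.x_centers(ncols)
    ys = grid.transform.y_centers(nrows)
    x = float((w.sum(axis=0) * xs).sum() / total)
    y = float((w.sum(axis=1) * ys).sum() / total)
    return Centroid(x=x, y=y, epoch=epoch, total_weight=float(total), crs=grid.crs)


def migration(c1: Centroid, c2: Centroid) -> MigrationStep:
    """Planar distance (m) and compass azimuth (deg clockwise from north)
    from c1 to c2."""
    if c1.crs != c2.crs:
        raise GridError(f"centroid CRS mismatch: {c1.crs} vs {c2.crs}")
    de = c2.x - c1.x
    dn = c2.y - c1.y
    distance = float(np.hypot(de, dn))
    azimuth = float(np.degrees(np.arctan2(de, dn)) % 360.0)
    return MigrationStep(c1.epoch, c2.epoch, distance, azimuth)


def trajectory(grids: list[Grid], epochs: list[int]) -> tuple[list[Centroid], list[MigrationStep]]:
    """Centroid per epoch plus the consecutive migration steps."""
    if len(grids) != len(epochs):
        raise GridError("need one epoch label per grid")
    centroids = [weighted_centroid(g, e) for g, e in zip(grids, epochs)]
    steps = [migration(a, b) for a, b in zip(centroids, centroids[1:])]
    return centroids, steps
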