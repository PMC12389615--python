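"""Land-use transition matrices, per-class mean NPP, transition-based NPP
change accounting (TgC) and generic zonal statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Grid, GridError
from .synth import LANDUSE_CLASSES

__all__ = [
    "TransitionMatrix",
    "transition_matrix",
    "class_mean_npp",
    "npp_change_from_transitions",
    "zonal_mean",
]


@dataclass
class TransitionMatrix:
    """Areas (km2) converting between classes over an epoch pair; entry
    (i, j) is the area moving from class i to class j."""

    classes: list[int]
    area_km2: np.ndarray
    epoch_pair: tuple[int, int] | None = None
    labels: dict[int, str] = field(default_factory=lambda: dict(LANDUSE_CLASSES))

    @property
    def row_totals(self) -> np.ndarray:
        """Class areas at the first epoch."""
        return self.area_km2.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Class areas at the second epoch."""
        return self.area_km2.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.area_km2.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [self.labels.get(c, str(c)) for c in self.classes]
        return pd.DataFrame(self.area_km2, index=names, columns=names)


def transition_matrix(lu_a: Grid, lu_b: Grid,
                      classes=tuple(LANDUSE_CLASSES),
                      epoch_pair: tuple[int, int] | None = None) -> TransitionMatrix:
    """Cross-tabulate two aligned categorical grids into an area matrix.

    Pixels masked in either grid are excluded from both marginals.
    """
    lu_a.require_compatible(lu_b, "transition matrix")
    if not (lu_a.is_categorical and lu_b.is_categorical):
        raise GridError("transition matrix requires categorical grids")
    classes = [int(c) for c in classes]
    valid = ~(lu_a.mask | lu_b.mask)
    a = lu_a.values[valid].astype(int)
    b = lu_b.values[valid].astype(int)
    known = set(classes)
    unknown = sorted((set(np.unique(a).tolist()) | set(np.unique(b).tolist())) - known)
    if unknown:
        raise GridError(f"unknown land-use class codes: {unknown}")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, (np.vectorize(index.get)(a), np.vectorize(index.get)(b)), 1)
    return TransitionMatrix(classes, counts * lu_a.pixel_area_km2, epoch_pair)


def class_mean_npp(npp: Grid, lu: Grid, classes=tuple(LANDUSE_CLASSES)) -> dict[int, float]:
    """Arithmetic mean NPP over each class's unmasked pixels (NaN if empty)."""
    npp.require_compatible(lu, "class means")
    valid = ~(npp.mask | lu.mask)
    out = {}
    for c in classes:
        sel = valid & (lu.values == c)
        out[int(c)] = float(npp.values[sel].mean()) if sel.any() else float("nan")
    return out


def npp_change_from_transitions(t: TransitionMatrix, means: dict[int, float]) -> pd.DataFrame:
    """Per-class NPP change ledger in TgC.

    Contribution of transition i->j = area(i, j) km2 x 1e6 m2/km2 x
    (mean_j - mean_i) gC m-2 x 1e-12 TgC/gC.  Two attribution conventions
    are reported: ``net_delta_tgc`` credits each off-diagonal contribution to
    the destination class; ``net_delta_tgc_source`` charges it to the source.
    Their class sums are identical by construction.
    """
    for c in t.classes:
        if t.area_km2[t.classes.index(c)].sum() > 0 or t.area_km2[:, t.classes.index(c)].sum() > 0:
            if not np.isfinite(means.get(c, float("nan"))):
                raise GridError(f"missing mean NPP for transitioning class {c}")
    k = len(t.classes)
    m = np.array([means[c] for c in t.classes], dtype=float)
    delta = t.area_km2 * 1e6 * (m[None, :] - m[:, None]) * 1e-12  # TgC per cell
    off = delta.copy()
    np.fill_diagonal(off, 0.0)
    gain_area = t.area_km2.sum(axis=0) - np.diag(t.area_km2)
    loss_area = t.area_km2.sum(axis=1) - np.diag(t.area_km2)
    rows = []
    for i, c in enumerate(t.classes):
        rows.append({
            "class_id": c,
            "class_name": t.labels.get(c, str(c)),
            "gain_area_km2": float(gain_area[i]),
            "loss_area_km2": float(loss_area[i]),
            "mean_npp": means[c],
            "net_delta_tgc": float(off[:, i].sum()),        # destination attribution
            "net_delta_tgc_source": float(off[i, :].sum()),  # source attribution
        })
    return pd.DataFrame(rows)


def zonal_mean(npp: Grid, zones: Grid, edges=None) -> pd.DataFrame:
    """Per-zone mean NPP and pixel count.

    ``zones`` is an integer band-code grid (e.g. elevation or slope bands);
    optional ``edges`` are echoed into the output for traceability.
    """
    npp.require_compatible(zones, "zonal statistics")
    valid = ~(npp.mask | zones.mask)
    codes = np.unique(zones.values[valid])
    rows = []
    for i, code in enumerate(codes):
        sel = valid & (zones.values == code)
        row = {
            "zone": int(code),
            "mean_npp": float(npp.values[sel].mean()),
            "count": int(sel.sum()),
        }
        if edges is not None and int(code) < len(edges) - 1:
            row["lo"], row["hi"] = edges[int(code)], edges[int(code) + 1]
        rows.append(row)
    return pd.DataFrame(rows)


def bands_from_grid(grid: Grid, edges) -> Grid:
    """Discretize a continuous grid into integer bands by fixed edges
    ([lo, hi) bins, final bin closed)."""
    codes = np.clip(np.digitize(grid.values, edges[1:-1]), 0, len(edges) - 2)
    return Grid(codes.astype(np.int16), grid.transform, grid.mask.copy(), grid.crs)
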