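"""Optimal-parameter geographic detector.

Measures the explanatory power of spatial factors for a response field with
the variance-decomposition q-statistic, choosing the analysis scale (by the
90% quantile of q across factors), the discretization method (five methods)
and the partition count (3..8) that maximize q, then runs factor and
interaction detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Grid, GridError, aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "StratifiedSample",
    "DetectorResult",
    "InteractionResult",
    "DISCRETIZATION_METHODS",
    "q_statistic",
    "q_decomposition",
    "q_significance",
    "discretize",
    "jenks_breaks",
    "optimize_discretization",
    "sample_at_scale",
    "select_scale",
    "factor_detector",
    "interaction_detector",
    "aspect_sectors",
]

DISCRETIZATION_METHODS = (
    "equal_interval",
    "natural_breaks",
    "quantile",
    "geometric_interval",
    "std_dev",
)

MIN_STRATUM_SIZE = 2


@dataclass
class StratifiedSample:
    """Response values with an integer stratum label per sample.

    Strata with fewer than MIN_STRATUM_SIZE samples are dropped from both
    the numerator and the denominator of q (each drop is logged).
    """

    y: np.ndarray
    strata: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.strata = np.asarray(self.strata)
        if self.y.shape != self.strata.shape or self.y.ndim != 1:
            raise GridError("y and strata must be aligned 1-D arrays")

    def filtered(self) -> "StratifiedSample":
        labels, counts = np.unique(self.strata, return_counts=True)
        small = labels[counts < MIN_STRATUM_SIZE]
        if small.size == 0:
            return self
        keep = ~np.isin(self.strata, small)
        logger.info("dropping %d strata with < %d samples (%d samples removed)",
                    small.size, MIN_STRATUM_SIZE, int((~keep).sum()))
        return StratifiedSample(self.y[keep], self.strata[keep], dropped=int(small.size))


def q_decomposition(sample: StratifiedSample) -> tuple[float, float, float, int, int]:
    """(q, SSW, SST, N, L) with population (denominator-N) variances so the
    decomposition is exact."""
    s = sample.filtered()
    n = len(s.y)
    if n < 2:
        raise GridError("q-statistic requires at least 2 samples after filtering")
    sst = float(((s.y - s.y.mean()) ** 2).sum())
    if sst == 0:
        raise GridError("q-statistic undefined: response variance is zero")
    labels = np.unique(s.strata)
    ssw = 0.0
    for h in labels:
        yh = s.y[s.strata == h]
        ssw += float(((yh - yh.mean()) ** 2).sum())
    return 1.0 - ssw / sst, ssw, sst, n, len(labels)


def q_statistic(sample: StratifiedSample) -> float:
    """q = 1 - sum_h N_h var_h / (N var), in [0, 1]."""
    return q_decomposition(sample)[0]


def q_significance(sample: StratifiedSample, mode: str = "noncentral") -> float:
    """p-value of q via the F-transformation.

    F = ((N - L)/(L - 1)) q/(1 - q), compared against a noncentral
    F(L-1, N-L; lambda) with lambda = (sum N_h m_h^2 - (sum sqrt(N_h) m_h)^2 / N) / var
    (``mode="central"`` falls back to the central F distribution).
    """
    s = sample.filtered()
    q, _, sst, n, l = q_decomposition(s)
    if l < 2:
        return 1.0
    if q >= 1.0:
        return 0.0
    var = sst / n
    f_stat = (n - l) / (l - 1) * q / (1 - q)
    if mode == "central":
        return float(stats.f.sf(f_stat, l - 1, n - l))
    labels = np.unique(s.strata)
    m = np.array([s.y[s.strata == h].mean() for h in labels])
    n_h = np.array([(s.strata == h).sum() for h in labels], dtype=float)
    lam = (np.sum(n_h * m**2) - (np.sum(np.sqrt(n_h) * m)) ** 2 / n) / var
    return float(stats.ncf.sf(f_stat, l - 1, n - l, max(lam, 0.0)))


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def jenks_breaks(x: np.ndarray, k: int, max_points: int = 2000) -> np.ndarray:
    """Break values (length k+1 edges) minimizing within-class sum of squared
    deviations, by dynamic programming over the sorted sample (deterministic).
    Large inputs are thinned deterministically to ``max_points``."""
    x = np.sort(np.asarray(x, dtype=float))
    if len(x) > max_points:
        x = x[np.linspace(0, len(x) - 1, max_points).astype(int)]
    n = len(x)
    k = min(k, len(np.unique(x)))
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i_arr: np.ndarray, j: int) -> np.ndarray:
        cnt = j - i_arr
        s = cs[j] - cs[i_arr]
        return (cs2[j] - cs2[i_arr]) - s * s / cnt

    dp = np.full((k + 1, n + 1), np.inf)
    dp[0, 0] = 0.0
    back = np.zeros((k + 1, n + 1), dtype=int)
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            i_arr = np.arange(m - 1, j)
            costs = dp[m - 1, i_arr] + sse(i_arr, j)
            b = int(np.argmin(costs))
            dp[m, j] = costs[b]
            back[m, j] = i_arr[b]
    bounds = [n]
    for m in range(k, 0, -1):
        bounds.append(back[m, bounds[-1]])
    bounds = bounds[::-1]  # 0 = first index, n = last
    edges = [x[0]]
    for b in bounds[1:-1]:
        edges.append((x[b - 1] + x[b]) / 2.0)
    edges.append(x[-1])
    return np.asarray(edges)


def _method_edges(x: np.ndarray, method: str, k: int) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if method == "equal_interval":
        return np.linspace(lo, hi, k + 1)
    if method == "quantile":
        return np.quantile(x, np.linspace(0, 1, k + 1))
    if method == "natural_breaks":
        return jenks_breaks(x, k)
    if method == "geometric_interval":
        # geometric progression of edge values on a positive-shifted axis;
        # the common ratio has the closed form (hi'/lo')**(1/k)
        shift = 0.0 if lo > 0 else -lo + (hi - lo) * 1e-6 + 1e-12
        ratio = ((hi + shift) / (lo + shift)) ** (1.0 / k)
        return (lo + shift) * ratio ** np.arange(k + 1) - shift
    if method == "std_dev":
        mu, sd = float(x.mean()), float(x.std())
        internal = mu + (np.arange(1, k) - k / 2.0) * sd
        internal = internal[(internal > lo) & (internal < hi)]
        if len(internal) < k - 1:
            logger.info("std_dev edges trimmed to data range: %d classes instead of %d",
                        len(internal) + 1, k)
        return np.concatenate([[lo], internal, [hi]])
    raise GridError(f"unknown discretization method {method!r}")


def discretize(x, method: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(labels, edges) for a continuous sample; bins are left-closed/right-open
    with the last bin closed.  Degenerate inputs collapse to fewer bins with a
    log line; constant input yields a single stratum."""
    x = np.asarray(x, dtype=float)
    if k < 2:
        raise GridError(f"need k >= 2 partitions, got {k}")
    if x.min() == x.max():
        logger.warning("constant input: single stratum returned")
        return np.zeros(len(x), dtype=int), np.array([x.min(), x.max()])
    edges = np.unique(_method_edges(x, method, k))
    if len(edges) - 1 < k:
        logger.info("%s produced %d bins instead of %d (duplicate edges)",
                    method, len(edges) - 1, k)
    labels = np.clip(np.digitize(x, edges[1:-1], right=False), 0, len(edges) - 2)
    return labels.astype(int), edges


def optimize_discretization(y, x, methods=DISCRETIZATION_METHODS,
                            k_range=range(3, 9)) -> tuple[str, int, float]:
    """Evaluate q over every (method, k) pair and return the argmax; ties break
    toward fewer bins, then method order as listed."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    best: tuple[float, int, int] | None = None  # (-q, k, method_index)
    best_combo = None
    for mi, method in enumerate(methods):
        for k in k_range:
            labels, _ = discretize(x, method, k)
            try:
                q = q_statistic(StratifiedSample(y, labels))
            except GridError:
                continue
            key = (-q, k, mi)
            if best is None or key < best:
                best = key
                best_combo = (method, k, q)
    if best_combo is None:
        raise GridError("all discretization combinations were degenerate")
    return best_combo


# ---------------------------------------------------------------------------
# Sampling grids at an analysis scale
# ---------------------------------------------------------------------------

def aspect_sectors(aspect: Grid, slope: Grid | None = None,
                   flat_threshold_deg: float = 1.0) -> Grid:
    """Categorize an aspect grid (compass degrees) into 8 sectors, with an
    extra 'flat' class (code 0) where slope is below the threshold."""
    sector = ((aspect.values.astype(float) + 22.5) // 45.0).astype(np.int16) % 8 + 1
    if slope is not None:
        sector[slope.values < flat_threshold_deg] = 0
    return Grid(sector, aspect.transform, aspect.mask.copy(), aspect.crs)


def sample_at_scale(response: Grid, factors: dict[str, tuple[Grid, str]],
                    factor_px: int) -> pd.DataFrame:
    """Aggregate the response (mean) and each factor (mean for continuous,
    mode for categorical) to the analysis scale; one row per valid cell."""
    y_agg = aggregate(response, factor_px, "mean")
    cols = {"y": y_agg}
    for name, (grid, kind) in factors.items():
        if kind == "categorical":
            cols[name] = aggregate(grid, factor_px, "mode")
        else:
            cols[name] = aggregate(grid, factor_px, "mean")
    mask = np.zeros(y_agg.shape, dtype=bool)
    for g in cols.values():
        mask |= g.mask
    data = {name: g.values[~mask] for name, g in cols.items()}
    return pd.DataFrame(data)


def select_scale(response: Grid, factors: dict[str, tuple[Grid, str]],
                 scales_km, pixel_size_m: float,
                 k_range=range(3, 9)) -> tuple[float, pd.DataFrame]:
    """Pick the analysis scale maximizing the 90% quantile (linear
    interpolation) of the per-factor optimized q across scales."""
    if len(factors) < 2:
        raise GridError("scale selection needs at least 2 factors")
    records = []
    min_samples = 2 * max(k_range)
    for scale in scales_km:
        factor_px = max(int(round(scale * 1000.0 / pixel_size_m)), 1)
        table = sample_at_scale(response, factors, factor_px)
        if len(table) < min_samples:
            logger.warning("skipping %s km scale: only %d sample cells (< %d)",
                           scale, len(table), min_samples)
            continue
        for name, (_, kind) in factors.items():
            if kind == "categorical":
                q = q_statistic(StratifiedSample(table["y"].to_numpy(),
                                                 table[name].to_numpy().astype(int)))
                method, k = "categorical", int(pd.unique(table[name]).size)
            else:
                method, k, q = optimize_discretization(
                    table["y"].to_numpy(), table[name].to_numpy(), k_range=k_range)
            records.append({"scale_km": scale, "factor": name, "q": q,
                            "method": method, "k": k})
    if not records:
        raise GridError("no analysis scale left a usable number of sample cells")
    q_table = pd.DataFrame(records)
    quantiles = q_table.groupby("scale_km")["q"].quantile(0.9, interpolation="linear")
    best_scale = float(quantiles.idxmax())
    return best_scale, q_table


# ---------------------------------------------------------------------------
# Factor / interaction detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorResult:
    factor: str
    q: float
    p_value: float
    best_method: str
    best_k: int
    scale_km: float | None = None


@dataclass(frozen=True)
class InteractionResult:
    factor_a: str
    factor_b: str
    q1: float
    q2: float
    q12: float
    category: str


def factor_detector(table: pd.DataFrame, kinds: dict[str, str],
                    scale_km: float | None = None,
                    k_range=range(3, 9)) -> tuple[list[DetectorResult], dict[str, np.ndarray]]:
    """Optimized q per factor on a sample table (column 'y' + one column per
    factor); returns results sorted by descending q plus the stratum labels
    actually used (for interaction detection)."""
    y = table["y"].to_numpy(dtype=float)
    results = []
    labelings: dict[str, np.ndarray] = {}
    for name, kind in kinds.items():
        x = table[name].to_numpy()
        if kind == "categorical":
            labels = x.astype(int)
            method, k = "categorical", int(len(np.unique(labels)))
        else:
            method, k, _ = optimize_discretization(y, x.astype(float), k_range=k_range)
            labels, _ = discretize(x.astype(float), method, k)
        sample = StratifiedSample(y, labels)
        q = q_statistic(sample)
        p = q_significance(sample)
        labelings[name] = labels
        results.append(DetectorResult(name, q, p, method, k, scale_km))
    results.sort(key=lambda r: -r.q)
    return results, labelings


_INTERACTION_TOL = 1e-9


def interaction_detector(y, labels_a, labels_b, name_a="x1", name_b="x2") -> InteractionResult:
    """q of the cross-classification of two stratifications, categorized
    against the single-factor q values."""
    y = np.asarray(y, dtype=float)
    la = np.asarray(labels_a).astype(int)
    lb = np.asarray(labels_b).astype(int)
    q1 = q_statistic(StratifiedSample(y, la))
    q2 = q_statistic(StratifiedSample(y, lb))
    cross = la * (lb.max() + 1) + lb
    sample = StratifiedSample(y, cross).filtered()
    if len(sample.y) < 2:
        raise GridError("interaction produced only singleton strata; use coarser bins")
    q12 = q_statistic(sample)
    lo, hi = min(q1, q2), max(q1, q2)
    if abs(q12 - (q1 + q2)) <= _INTERACTION_TOL:
        category = "independent"
    elif q12 > q1 + q2:
        category = "nonlinear_enhance"
    elif q12 > hi:
        category = "bifactor_enhance"
    elif q12 >= lo:
        if q12 == hi:
            logger.info("interaction %s*%s: q12 equals max(q1, q2) exactly", name_a, name_b)
        category = "single_weaken"
    else:
        category = "nonlinear_weaken"
    return InteractionResult(name_a, name_b, q1, q2, q12, category)


def interaction_matrix(table: pd.DataFrame, labelings: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise interactions over a labeled sample table."""
    y = table["y"].to_numpy(dtype=float)
    names = list(labelings)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            try:
                res = interaction_detector(y, labelings[a], labelings[b], a, b)
            except GridError as exc:
                logger.warning("skipping interaction %s*%s: %s", a, b, exc)
                continue
            rows.append(res.__dict__)
    return pd.DataFrame(rows)
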