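"""Per-cell climate summaries and the two global environmental axes.

Monthly temperature and precipitation series are reduced to six per-cell
statistics — mean, variability, and Colwell predictability of each
variable — and a principal component analysis over land cells yields two
composite axes: temperature harshness (TH, PC1: cold, variable,
unpredictable temperature scores high) and aridity index (AI, PC2: arid,
variable, unpredictable precipitation scores high).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Raster

__all__ = ["ClimateSummary", "EnvAxes", "colwell_P", "summarize_series", "env_pca"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "temp_mean",
    "temp_variability",
    "temp_predictability",
    "precip_mean",
    "precip_variability",
    "precip_predictability",
]


@dataclass
class ClimateSummary:
    """Six climate statistics per land cell, plus the cell index map."""

    table: pd.DataFrame  # one row per land cell, SUMMARY_COLUMNS
    cells: np.ndarray  # (n_cells, 2) row/col indices into the grid
    grid: Raster  # geometry carrier (lats/lons/land_mask)


@dataclass
class EnvAxes:
    """Temperature-harshness and aridity-index component surfaces."""

    th: Raster
    ai: Raster
    loadings: pd.DataFrame  # 6 variables x [TH, AI]
    explained_variance: np.ndarray  # fractions for [TH, AI]
    scores: pd.DataFrame  # per land cell, columns TH / AI
    cells: np.ndarray


def colwell_P(
    series: np.ndarray, n_states: int = 11
) -> tuple[float, float, float]:
    """Colwell's predictability of a monthly series.

    The series is discretized into ``n_states`` equal-width bins spanning
    its min-max range and cross-tabulated by calendar month, giving a
    12 x n_states frequency matrix. Information-theoretic decomposition of
    that table yields predictability P = constancy C + contingency M, each
    in [0, 1]. A constant series has zero entropy in every month and
    returns (P, C, M) = (1, 1, 0) by convention.

    Returns
    -------
    (P, C, M)
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size % 12 != 0 or series.size == 0:
        raise ValueError("series length must be a positive multiple of 12")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    lo, hi = series.min(), series.max()
    if hi - lo <= 0:
        return 1.0, 1.0, 0.0
    states = np.minimum(
        ((series - lo) / (hi - lo) * n_states).astype(int), n_states - 1
    )
    months = np.arange(series.size) % 12
    counts = np.zeros((12, n_states))
    np.add.at(counts, (months, states), 1.0)

    z = counts.sum()
    col = counts.sum(axis=0)  # per-state totals (X)
    row = counts.sum(axis=1)  # per-month totals (Y)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0] / z
        return float(-(p * np.log(p)).sum())

    hx = entropy(col)
    hy = entropy(row)
    hxy = entropy(counts.ravel())
    logs = np.log(n_states)
    constancy = 1.0 - hx / logs
    contingency = (hx + hy - hxy) / logs
    predictability = 1.0 - (hxy - hy) / logs
    return float(predictability), float(constancy), float(contingency)


def summarize_series(
    temperature: Raster, precipitation: Raster, n_states: int = 11
) -> ClimateSummary:
    """Reduce monthly stacks to the six per-cell climate statistics.

    Temperature variability is the standard deviation of monthly values;
    precipitation variability is the coefficient of variation. Colwell
    predictability uses ``n_states`` equal-width bins on raw temperature
    and on log1p-transformed precipitation. Cells with any non-finite
    month are excluded with a logged count.
    """
    t, p = temperature.values, precipitation.values
    if t.ndim != 3 or p.shape != t.shape:
        raise ValueError("expected matching (n_months, n_lat, n_lon) stacks")
    if t.shape[0] < 120:
        raise ValueError("need at least 10 years of monthly data")

    land = temperature.land_mask
    rows, cells = [], []
    n_dropped = 0
    for i, j in np.argwhere(land):
        ts, ps = t[:, i, j], p[:, i, j]
        if not (np.isfinite(ts).all() and np.isfinite(ps).all()):
            n_dropped += 1
            continue
        pt, _, _ = colwell_P(ts, n_states)
        pp, _, _ = colwell_P(np.log1p(ps), n_states)
        p_mean = ps.mean()
        rows.append(
            {
                "temp_mean": ts.mean(),
                "temp_variability": ts.std(),
                "temp_predictability": pt,
                "precip_mean": p_mean,
                "precip_variability": ps.std() / p_mean if p_mean > 0 else 0.0,
                "precip_predictability": pp,
            }
        )
        cells.append((i, j))
    if n_dropped:
        logger.warning("summarize_series: excluded %d cells with non-finite months", n_dropped)
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return ClimateSummary(table, np.asarray(cells, dtype=int), temperature)


def env_pca(summary: ClimateSummary) -> EnvAxes:
    """Global PCA of the six climate statistics over land cells.

    Columns are standardized (correlation PCA); zero-variance columns are
    dropped with a warning. The first two components are sign-anchored so
    that harsh (cold) temperature regimes score high on TH and arid
    precipitation regimes score high on AI: a component is flipped if the
    loading of ``temp_mean`` (PC1) or ``precip_mean`` (PC2) is positive.
    """
    table = summary.table
    if len(table) < 6:
        raise ValueError("need at least 6 land cells for the climate PCA")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(table.columns, keep) if not k]
        logger.warning("env_pca: dropping zero-variance columns %s", dropped)
    cols = [c for c, k in zip(table.columns, keep) if k]
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    n = xs.shape[0]
    scores = u[:, :2] * s[:2]
    loadings = vt[:2].T * s[:2] / np.sqrt(n - 1)
    evr = (s**2 / (s**2).sum())[:2]

    anchor = {0: "temp_mean", 1: "precip_mean"}
    load_df = pd.DataFrame(loadings, index=cols, columns=["TH", "AI"])
    for comp, var in anchor.items():
        if var in load_df.index and load_df.iloc[:, comp][var] > 0:
            load_df.iloc[:, comp] *= -1
            scores[:, comp] *= -1

    grid = summary.grid
    th_grid = np.full((grid.n_lat, grid.n_lon), np.nan)
    ai_grid = np.full((grid.n_lat, grid.n_lon), np.nan)
    ii, jj = summary.cells[:, 0], summary.cells[:, 1]
    th_grid[ii, jj] = scores[:, 0]
    ai_grid[ii, jj] = scores[:, 1]

    return EnvAxes(
        th=Raster(th_grid, grid.lats, grid.lons, grid.land_mask),
        ai=Raster(ai_grid, grid.lats, grid.lons, grid.land_mask),
        loadings=load_df,
        explained_variance=evr,
        scores=pd.DataFrame(scores, columns=["TH", "AI"]),
        cells=summary.cells,
    )
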