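"""Barrier magnitudes around centres of agricultural origin.

Societies inside areas of independent domestication are the focal units.
For each focal society, barrier metrics are averaged over its k nearest
neighbours (close range) and over its k nearest neighbours at least
``min_km`` away (long range, 2500 km in the full design), so each
starting location contributes one datapoint per range. Varimax-rotated
PCAs (3 close-range, 4 long-range components) summarize the aggregate
metrics, and each component is compared across origin areas with a
variance-weighted linear model — augmented with semi-parametric spatial
filter eigenvectors when residuals are spatially dependent — followed by
pairwise Tukey honest significant differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cost_paths import BARRIER_COLUMNS, compute_pair_barriers, geodesic_km_matrix
from .sharing_models import varimax_components

__all__ = [
    "FocalBarriers",
    "OriginComponents",
    "CorridorComparison",
    "neighbor_sets",
    "average_barriers",
    "focal_barrier_table",
    "origin_pca",
    "spatial_filter_eigenvectors",
    "fit_weighted_lm",
    "paleo_rerun",
]

logger = logging.getLogger(__name__)


def neighbor_sets(
    focal_id: str,
    societies: pd.DataFrame,
    k: int = 100,
    min_km: float = 0.0,
    dist: np.ndarray | None = None,
) -> list[str]:
    """Ids of the k geodesic-nearest societies at least ``min_km`` away."""
    ids = societies["id"].to_numpy()
    if dist is None:
        dist = geodesic_km_matrix(
            societies["lat"].to_numpy(), societies["lon"].to_numpy()
        )
    i = int(np.flatnonzero(ids == focal_id)[0])
    d = dist[i].copy()
    d[i] = -1.0
    eligible = np.flatnonzero((d >= min_km) & (d >= 0))
    order = eligible[np.argsort(d[eligible], kind="stable")]
    chosen = order[:k]
    if len(chosen) < k:
        logger.warning(
            "neighbor_sets: %s has only %d eligible neighbours (k=%d)",
            focal_id,
            len(chosen),
            k,
        )
    return [ids[j] for j in chosen]


def average_barriers(
    focal_id: str, neighbor_ids: list[str], barriers: pd.DataFrame
) -> pd.Series:
    """Mean barrier metrics over the focal society's neighbour pairs."""
    mask = ((barriers["id_a"] == focal_id) & barriers["id_b"].isin(neighbor_ids)) | (
        (barriers["id_b"] == focal_id) & barriers["id_a"].isin(neighbor_ids)
    )
    sub = barriers.loc[mask, BARRIER_COLUMNS]
    out = sub.mean()
    out["n_neighbors"] = float(len(sub))
    out.name = focal_id
    return out


def focal_barrier_table(
    societies: pd.DataFrame,
    graph,
    th: np.ndarray,
    ai: np.ndarray,
    elev: np.ndarray,
    k: int = 100,
    min_km: float = 0.0,
    barriers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row of averaged barrier metrics per focal (origin-area) society.

    Focal societies are those with a non-null ``origin_area`` label; their
    neighbour pools draw on *all* societies. Pair barriers are computed on
    demand for exactly the focal-neighbour pairs unless a precomputed
    ``barriers`` table is passed.
    """
    focal = societies[societies["origin_area"].notna()]
    dist = geodesic_km_matrix(
        societies["lat"].to_numpy(), societies["lon"].to_numpy()
    )
    sets = {
        fid: neighbor_sets(fid, societies, k=k, min_km=min_km, dist=dist)
        for fid in focal["id"]
    }
    if barriers is None:
        pair_rows = sorted(
            {tuple(sorted((fid, nid))) for fid, nids in sets.items() for nid in nids}
        )
        pairs = pd.DataFrame(pair_rows, columns=["id_a", "id_b"])
        barriers = compute_pair_barriers(societies, pairs, graph, th, ai, elev)
    rows = []
    for fid, nids in sets.items():
        row = average_barriers(fid, nids, barriers)
        row["id"] = fid
        row["origin_area"] = focal.set_index("id").at[fid, "origin_area"]
        rows.append(row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return out[["id", "origin_area"] + BARRIER_COLUMNS + ["n_neighbors"]]


@dataclass
class OriginComponents:
    """Rotated barrier components over focal societies for one range."""

    range_label: str  # "close" | "long"
    scores: pd.DataFrame  # focal society x components (+ id, origin_area)
    loadings: pd.DataFrame


def origin_pca(focal: pd.DataFrame, range_label: str) -> OriginComponents:
    """Varimax PCA of the focal aggregate metrics: 3 (close) / 4 (long) PCs."""
    if range_label not in ("close", "long"):
        raise ValueError("range_label must be 'close' or 'long'")
    n_comp = 3 if range_label == "close" else 4
    comps = varimax_components(focal[BARRIER_COLUMNS], n_components=n_comp)
    prefix = "cr" if range_label == "close" else "lr"
    names = [f"{prefix}PC{c + 1}" for c in range(n_comp)]
    scores = comps.scores.copy()
    scores.columns = names
    loadings = comps.loadings.copy()
    loadings.columns = names
    scores.insert(0, "id", focal["id"].to_numpy())
    scores.insert(1, "origin_area", focal["origin_area"].to_numpy())
    return OriginComponents(range_label, scores, loadings)


def _global_morans_i(values: np.ndarray, w: np.ndarray) -> float:
    r = values - values.mean()
    denom = r @ r
    s0 = w.sum()
    if denom <= 0 or s0 <= 0:
        return np.nan
    return float(len(values) / s0 * (r @ w @ r) / denom)


def _morans_perm_p(
    values: np.ndarray, w: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    obs = _global_morans_i(values, w)
    if not np.isfinite(obs):
        return np.nan
    count = sum(
        _global_morans_i(rng.permutation(values), w) >= obs for _ in range(n_perm)
    )
    return (count + 1) / (n_perm + 1)


def knn_weights(coords: pd.DataFrame, k: int = 5) -> np.ndarray:
    """Symmetrized, row-standardized k-nearest-neighbour spatial weights."""
    dist = geodesic_km_matrix(coords["lat"].to_numpy(), coords["lon"].to_numpy())
    n = dist.shape[0]
    w = np.zeros((n, n))
    for i in range(n):
        d = dist[i].copy()
        d[i] = np.inf
        w[i, np.argsort(d, kind="stable")[: min(k, n - 1)]] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return (w + w.T) / 2.0


def spatial_filter_eigenvectors(
    coords: pd.DataFrame,
    y: np.ndarray,
    design: np.ndarray,
    k: int = 5,
    alpha_stop: float = 0.1,
    n_perm: int = 199,
    seed: int = 0,
    max_vectors: int | None = None,
) -> np.ndarray:
    """Semi-parametric spatial filtering: greedy MWM eigenvector selection.

    Candidates are eigenvectors (positive eigenvalues) of M W M, where W
    is the symmetrized kNN weight matrix and M the residual-maker of the
    current design. Vectors are added one at a time, each step taking the
    candidate that most reduces |Moran's I| of the residuals, and stops
    when the residual Moran's I permutation p-value exceeds
    ``alpha_stop`` or no candidate improves. Returns an (n, m) matrix of
    selected eigenvectors (m may be 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        logger.warning("spatial filtering skipped: n=%d < 10", n)
        return np.empty((n, 0))
    rng = np.random.default_rng(seed)
    w = knn_weights(coords, k=k)
    x = np.asarray(design, dtype=float)
    m = np.eye(n) - x @ np.linalg.pinv(x)
    evals, evecs = np.linalg.eigh(m @ w @ m)
    order = np.argsort(evals)[::-1]
    cand = [order[i] for i in range(n) if evals[order[i]] > 1e-8]
    if max_vectors is None:
        max_vectors = len(cand)

    selected: list[int] = []

    def residuals(extra: list[int]) -> np.ndarray:
        xx = np.column_stack([x] + [evecs[:, e] for e in extra]) if extra else x
        beta, *_ = np.linalg.lstsq(xx, y, rcond=None)
        return y - xx @ beta

    res = residuals(selected)
    current_i = abs(_global_morans_i(res, w))
    while len(selected) < max_vectors:
        p = _morans_perm_p(res, w, n_perm, rng)
        if not np.isfinite(p) or p > alpha_stop:
            break
        best, best_i = None, current_i
        for e in cand:
            if e in selected:
                continue
            trial = abs(_global_morans_i(residuals(selected + [e]), w))
            if trial < best_i - 1e-12:
                best, best_i = e, trial
        if best is None:
            break
        selected.append(best)
        res = residuals(selected)
        current_i = best_i
    return evecs[:, selected] if selected else np.empty((n, 0))


@dataclass
class CorridorComparison:
    """Cross-area comparison of one barrier component."""

    component: str
    group_stats: pd.DataFrame  # area, n, mean, sd, weighted_mean, se, df
    tukey_diff: pd.DataFrame  # |difference| matrix (symmetric, NaN diagonal)
    tukey_p: pd.DataFrame
    significant: pd.DataFrame  # boolean flags at alpha
    n_eigenvectors: int = 0
    dropped_areas: list[str] = field(default_factory=list)
    alpha: float = 0.05


def fit_weighted_lm(
    scores: pd.Series | np.ndarray,
    areas: pd.Series | np.ndarray,
    coords: pd.DataFrame | None = None,
    eigenvectors: np.ndarray | None = None,
    spatial_filter: bool = False,
    alpha: float = 0.05,
    component: str = "PC",
    seed: int = 0,
) -> CorridorComparison:
    """Variance-weighted area comparison with Tukey HSD contrasts.

    Two-stage fit: OLS on area indicators, per-area residual variances,
    WLS refit with weights 1/variance-hat. Optionally, spatial filter
    eigenvectors (computed from ``coords`` when ``spatial_filter`` is
    set, or passed precomputed) join the design as covariates. Pairwise
    area contrasts use the Tukey-Kramer studentized-range test with
    Welch-Satterthwaite effective degrees of freedom. Areas with fewer
    than 2 rows are dropped (their variance cannot be estimated).
    """
    y = np.asarray(scores, dtype=float)
    area = pd.Series(np.asarray(areas, dtype=object))
    counts = area.value_counts()
    dropped = sorted(counts[counts < 2].index)
    keep = ~area.isin(dropped).to_numpy()
    if dropped:
        logger.info("fit_weighted_lm: dropped areas with <2 rows: %s", dropped)
    y = y[keep]
    area = area[keep].reset_index(drop=True)
    if coords is not None:
        coords = coords.reset_index(drop=True).loc[keep].reset_index(drop=True)
    levels = sorted(area.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 areas with >= 2 societies")
    g = np.array([levels.index(a) for a in area])
    dummies = np.eye(len(levels))[g]  # cell-means coding

    def stage_fit(xmat: np.ndarray, wts: np.ndarray | None):
        if wts is None:
            wts = np.ones(len(y))
        sw = np.sqrt(wts)
        beta, *_ = np.linalg.lstsq(xmat * sw[:, None], y * sw, rcond=None)
        resid = y - xmat @ beta
        return beta, resid

    # stage 1: OLS, per-area residual variance
    _, resid = stage_fit(dummies, None)
    var_hat = np.array(
        [max(resid[g == j].var(ddof=1), 1e-12) for j in range(len(levels))]
    )
    wts = 1.0 / var_hat[g]

    xmat = dummies
    n_eig = 0
    if eigenvectors is None and spatial_filter and coords is not None:
        eigenvectors = spatial_filter_eigenvectors(
            coords, y, dummies, seed=seed
        )
    if eigenvectors is not None and eigenvectors.shape[1] > 0:
        xmat = np.column_stack([dummies, eigenvectors])
        n_eig = eigenvectors.shape[1]

    beta, resid_w = stage_fit(xmat, wts)
    means = beta[: len(levels)]  # adjusted area means (eigenvectors ~ centered)
    counts_l = np.array([(g == j).sum() for j in range(len(levels))])
    se = np.sqrt(var_hat / counts_l)
    dfs = counts_l - 1.0

    k = len(levels)
    diff = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            d = abs(means[i] - means[j])
            sed = np.sqrt((se[i] ** 2 + se[j] ** 2) / 2.0)
            nu = (se[i] ** 2 + se[j] ** 2) ** 2 / (
                se[i] ** 4 / dfs[i] + se[j] ** 4 / dfs[j]
            )
            qstat = d / sed
            p = float(stats.studentized_range.sf(qstat, k, max(nu, 2.0)))
            diff[i, j] = diff[j, i] = d
            pmat[i, j] = pmat[j, i] = p

    group_stats = pd.DataFrame(
        {
            "area": levels,
            "n": counts_l,
            "mean": [y[g == j].mean() for j in range(k)],
            "sd": np.sqrt(var_hat),
            "weighted_mean": means,
            "se": se,
            "df": dfs,
        }
    )
    diff_df = pd.DataFrame(diff, index=levels, columns=levels)
    p_df = pd.DataFrame(pmat, index=levels, columns=levels)
    return CorridorComparison(
        component=component,
        group_stats=group_stats,
        tukey_diff=diff_df,
        tukey_p=p_df,
        significant=p_df < alpha,
        n_eigenvectors=n_eig,
        dropped_areas=dropped,
        alpha=alpha,
    )


def compare_components(
    origin: OriginComponents,
    coords: pd.DataFrame,
    spatial_filter: bool = True,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, CorridorComparison]:
    """One variance-weighted comparison per rotated component."""
    out = {}
    pc_cols = [c for c in origin.scores.columns if c not in ("id", "origin_area")]
    for pc in pc_cols:
        out[pc] = fit_weighted_lm(
            origin.scores[pc],
            origin.scores["origin_area"],
            coords=coords,
            spatial_filter=spatial_filter,
            alpha=alpha,
            component=pc,
            seed=seed,
        )
    return out


def paleo_rerun(
    timepoint_climates: dict[str, tuple],
    societies: pd.DataFrame,
    graph,
    elev: np.ndarray,
    k: int = 100,
    min_km_long: float = 2500.0,
    spatial_filter: bool = True,
    seed: int = 0,
) -> dict[str, dict]:
    """Repeat the corridor comparison under reconstructed paleo climates.

    ``timepoint_climates`` maps a label (e.g. ``"12kya"``) to a
    (temperature, precipitation) stack pair. Per timepoint the TH/AI axes
    and the environment-derived barrier columns are recomputed, while the
    topographic and geodesic columns do not depend on climate and are
    reused unchanged (they are recomputed identically from the same
    terrain). Returns, per timepoint, close- and long-range comparison
    bundles.
    """
    from .climate_components import env_pca, summarize_series
    from .cost_paths import node_env_values

    out: dict[str, dict] = {}
    for label, (temp, precip) in timepoint_climates.items():
        axes = env_pca(summarize_series(temp, precip))
        th = node_env_values(graph, axes.th)
        ai = node_env_values(graph, axes.ai)
        bundle: dict[str, object] = {"env_axes": axes}
        for range_label, min_km in (("close", 0.0), ("long", min_km_long)):
            focal = focal_barrier_table(
                societies, graph, th, ai, elev, k=k, min_km=min_km
            )
            origin = origin_pca(focal, range_label)
            coords = societies.set_index("id").loc[origin.scores["id"], ["lat", "lon"]]
            coords = coords.reset_index(drop=True)
            bundle[range_label] = {
                "focal": focal,
                "components": origin,
                "comparisons": compare_components(
                    origin, coords, spatial_filter=spatial_filter, seed=seed
                ),
            }
        out[label] = bundle
    return out
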