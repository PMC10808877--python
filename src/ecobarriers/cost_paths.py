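"""Raster graphs, geodesics, and least-cost paths between societies.

The barrier metrics rest on three kinds of routes over a lat/lon raster:

* *environmental* least-cost paths, where each cell's cost is its absolute
  TH (or AI) difference from the **starting** cell — the cost surface is
  start-relative, so A→B and B→A paths generally differ and the pair
  metric averages the two directions;
* *topographic* least-cost paths, penalizing rise-over-run slope along the
  step;
* great-circle geodesics.

Edges carry great-circle step lengths between cell centers, which is the
geographic correction for the latitude-dependent distortion of the WGS 84
lat/lon lattice. Shortest paths are computed with Dijkstra's algorithm on
a sparse edge matrix; a per-source pass over the predecessor tree yields
accumulated cost and path length to every destination at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .grids import Raster

__all__ = [
    "EARTH_RADIUS_KM",
    "RasterGraph",
    "PathResult",
    "geodesic_km",
    "geodesic_km_matrix",
    "build_graph",
    "env_cost_path",
    "topo_cost_path",
    "node_env_values",
    "pair_barriers",
    "compute_pair_barriers",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius
TIE_EPS = 1e-9  # per-km tie-break toward shortest paths on zero-cost surfaces

BARRIER_COLUMNS = [
    "th_dissim",
    "ai_dissim",
    "th_cost",
    "th_len",
    "ai_cost",
    "ai_len",
    "topo_cost",
    "topo_len",
    "geodesic_km",
]


def geodesic_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance (haversine) on the mean-radius sphere, in km."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_km_matrix(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix for point sets."""
    return geodesic_km(
        lats[:, None], lons[:, None], lats[None, :], lons[None, :]
    )


@dataclass
class RasterGraph:
    """Neighbor graph over land cells with great-circle step lengths."""

    grid: Raster  # geometry carrier
    node_of_cell: np.ndarray  # (n_lat, n_lon) -> node index or -1
    cells: np.ndarray  # (n_nodes, 2) row/col per node
    edges: np.ndarray  # (n_edges, 2) node pairs, each undirected edge once
    step_km: np.ndarray  # (n_edges,)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    @property
    def edge_index(self) -> dict[tuple[int, int], int]:
        """Directed (u, v) -> undirected edge id lookup (built once)."""
        if not hasattr(self, "_edge_index"):
            lut: dict[tuple[int, int], int] = {}
            for k, (a, b) in enumerate(self.edges):
                lut[(int(a), int(b))] = k
                lut[(int(b), int(a))] = k
            self._edge_index = lut
        return self._edge_index

    def node_at(self, lat: float, lon: float, max_snap_cells: int = 2) -> int:
        """Node of the land cell containing/nearest (lat, lon).

        Coordinates falling on a masked cell are snapped to the nearest
        land cell within ``max_snap_cells`` Chebyshev cells (logged), else
        an error is raised.
        """
        i, j = self.grid.cell_of(lat, lon)
        if self.node_of_cell[i, j] >= 0:
            return int(self.node_of_cell[i, j])
        ii, jj = self.cells[:, 0], self.cells[:, 1]
        cheb = np.maximum(np.abs(ii - i), np.abs(jj - j))
        order = np.argmin(cheb)
        if cheb[order] > max_snap_cells:
            raise ValueError(
                f"coordinate ({lat}, {lon}) is more than {max_snap_cells} "
                "cells from land"
            )
        logger.info("snapped (%s, %s) to land cell %s", lat, lon, self.cells[order])
        return int(order)

    def sparse_weights(self, per_cell_cost: np.ndarray | None = None) -> csr_matrix:
        """Symmetric sparse edge-weight matrix.

        With ``per_cell_cost`` (one value per node), edge weight is
        ``step_km * (c_u + c_v) / 2 + TIE_EPS * step_km``; without, it is
        plain ``step_km``.
        """
        u, v = self.edges[:, 0], self.edges[:, 1]
        if per_cell_cost is None:
            w = self.step_km
        else:
            c = np.asarray(per_cell_cost, dtype=float)
            w = self.step_km * (c[u] + c[v]) / 2.0 + TIE_EPS * self.step_km
        data = np.concatenate([w, w])
        rows = np.concatenate([u, v])
        cols = np.concatenate([v, u])
        n = self.n_nodes
        return csr_matrix((data, (rows, cols)), shape=(n, n))


def build_graph(grid: Raster, connectivity: int = 8) -> RasterGraph:
    """Lattice graph over the land cells of ``grid``.

    ``connectivity`` is 4, 8 (default) or 16 (knight moves added).
    """
    if connectivity not in (4, 8, 16):
        raise ValueError("connectivity must be 4, 8 or 16")
    land = grid.land_mask
    if land.sum() < 2:
        raise ValueError("need at least 2 land cells")
    n_lat, n_lon = land.shape
    node_of_cell = np.full((n_lat, n_lon), -1, dtype=int)
    cells = np.argwhere(land)
    node_of_cell[cells[:, 0], cells[:, 1]] = np.arange(len(cells))

    offsets = [(0, 1), (1, 0)]
    if connectivity >= 8:
        offsets += [(1, 1), (1, -1)]
    if connectivity == 16:
        offsets += [(1, 2), (2, 1), (2, -1), (1, -2)]

    e_u, e_v = [], []
    for di, dj in offsets:
        i0 = np.arange(max(0, -di), min(n_lat, n_lat - di))
        j0 = np.arange(max(0, -dj), min(n_lon, n_lon - dj))
        ii, jj = np.meshgrid(i0, j0, indexing="ij")
        a = node_of_cell[ii, jj]
        b = node_of_cell[ii + di, jj + dj]
        ok = (a >= 0) & (b >= 0)
        e_u.append(a[ok].ravel())
        e_v.append(b[ok].ravel())
    edges = np.stack([np.concatenate(e_u), np.concatenate(e_v)], axis=1)
    lat_c = grid.lats[cells[:, 0]]
    lon_c = grid.lons[cells[:, 1]]
    step = geodesic_km(
        lat_c[edges[:, 0]], lon_c[edges[:, 0]], lat_c[edges[:, 1]], lon_c[edges[:, 1]]
    )
    return RasterGraph(grid, node_of_cell, cells, edges, np.asarray(step))


@dataclass
class PathResult:
    """A least-cost route: cost in surface units, length in km, node chain."""

    accumulated_cost: float
    length_km: float
    nodes: list[int]
    reachable: bool = True


class _SourceCosts:
    """Accumulated cost / length / predecessors from one source to all nodes."""

    __slots__ = ("source", "weight", "cost", "length", "pred")

    def __init__(self, source, weight, cost, length, pred):
        self.source = source
        self.weight = weight
        self.cost = cost
        self.length = length
        self.pred = pred

    def path_to(self, target: int) -> PathResult:
        if not np.isfinite(self.weight[target]):
            return PathResult(np.inf, np.inf, [], reachable=False)
        nodes = [int(target)]
        while nodes[-1] != self.source:
            nodes.append(int(self.pred[nodes[-1]]))
        nodes.reverse()
        return PathResult(
            float(self.cost[target]), float(self.length[target]), nodes
        )


def _edge_arrays(graph: RasterGraph, per_cell_cost, topo_elev):
    """Per-directed-edge (cost, length) lookup dictionaries as dense maps."""
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    step = graph.step_km
    if per_cell_cost is not None:
        c = np.asarray(per_cell_cost, dtype=float)
        cost = step * (c[u] + c[v]) / 2.0
    else:
        elev = np.asarray(topo_elev, dtype=float)
        cost = step * (1.0 + np.abs(elev[u] - elev[v]) / (step * 1000.0))
    return cost, step


def _source_costs(
    graph: RasterGraph,
    source: int,
    per_cell_cost: np.ndarray | None = None,
    topo_elev: np.ndarray | None = None,
) -> _SourceCosts:
    """Dijkstra from ``source``; accumulate cost/length along its tree."""
    if per_cell_cost is not None:
        wmat = graph.sparse_weights(per_cell_cost)
    else:
        elev = np.asarray(topo_elev, dtype=float)
        u, v = graph.edges[:, 0], graph.edges[:, 1]
        w = graph.step_km * (1.0 + np.abs(elev[u] - elev[v]) / (graph.step_km * 1000.0))
        data = np.concatenate([w, w])
        rows = np.concatenate([u, v])
        cols = np.concatenate([v, u])
        wmat = csr_matrix((data, (rows, cols)), shape=(graph.n_nodes,) * 2)
    dist, pred = dijkstra(
        wmat, directed=False, indices=source, return_predecessors=True
    )
    ecost, estep = _edge_arrays(graph, per_cell_cost, topo_elev)
    lut = graph.edge_index

    cost = np.full(graph.n_nodes, np.inf)
    length = np.full(graph.n_nodes, np.inf)
    cost[source] = 0.0
    length[source] = 0.0
    order = np.argsort(dist)
    for node in order:
        p = pred[node]
        if node == source or p < 0:
            continue
        if not np.isfinite(dist[node]):
            break
        k = lut[(int(p), int(node))]
        cost[node] = cost[p] + ecost[k]
        length[node] = length[p] + estep[k]
    return _SourceCosts(source, dist, cost, length, pred)


def env_cost_path(
    graph: RasterGraph, env_values: np.ndarray, start: int, end: int
) -> PathResult:
    """Start-relative environmental least-cost path between two nodes.

    Per-cell cost is ``|env(v) - env(start)|``; edge weight averages the
    endpoint costs times the great-circle step, plus a tiny per-km
    tie-break so zero-cost surfaces resolve to minimum-length paths. The
    reported accumulated cost excludes the tie-break term.
    """
    env = np.asarray(env_values, dtype=float)
    if not np.isfinite(env).all():
        raise ValueError("environmental surface has non-finite land values")
    c = np.abs(env - env[start])
    return _source_costs(graph, start, per_cell_cost=c).path_to(end)


def topo_cost_path(
    graph: RasterGraph, elev_values: np.ndarray, start: int, end: int
) -> PathResult:
    """Slope-penalized travel path: edge weight = step x (1 + |rise|/run)."""
    return _source_costs(graph, start, topo_elev=elev_values).path_to(end)


def node_env_values(graph: RasterGraph, surface: Raster) -> np.ndarray:
    """Surface values sampled at graph nodes."""
    return surface.values[graph.cells[:, 0], graph.cells[:, 1]]


def pair_barriers(
    graph: RasterGraph,
    a: tuple[float, float],
    b: tuple[float, float],
    th: np.ndarray,
    ai: np.ndarray,
    elev: np.ndarray,
) -> pd.Series:
    """Symmetric pairwise barrier metrics for one society pair.

    Runs the start-relative TH and AI paths in both directions, averages
    cost and length, takes the (symmetric) topographic path once, and
    log1p-transforms all cost/length fields. Returns a Series with
    ``BARRIER_COLUMNS``. Disconnected pairs yield all-NaN with
    ``reachable`` False (handled by callers).
    """
    rows = compute_pair_barriers(
        pd.DataFrame({"id": ["A", "B"], "lat": [a[0], b[0]], "lon": [a[1], b[1]]}),
        pd.DataFrame({"id_a": ["A"], "id_b": ["B"]}),
        graph,
        th,
        ai,
        elev,
    )
    return rows.iloc[0][BARRIER_COLUMNS].astype(float)


def compute_pair_barriers(
    societies: pd.DataFrame,
    pairs: pd.DataFrame,
    graph: RasterGraph,
    th: np.ndarray,
    ai: np.ndarray,
    elev: np.ndarray,
) -> pd.DataFrame:
    """Barrier metrics for a table of unordered society pairs.

    ``societies`` needs columns id/lat/lon; ``pairs`` needs id_a/id_b.
    ``th``, ``ai``, ``elev`` are per-node surface values (see
    :func:`node_env_values`). One Dijkstra per society per surface serves
    all of that society's pairs. Disconnected pairs are excluded with a
    logged reason.
    """
    soc = societies.set_index("id")
    node = {sid: graph.node_at(soc.at[sid, "lat"], soc.at[sid, "lon"]) for sid in soc.index}

    env_caches: dict[str, dict[str, _SourceCosts]] = {"th": {}, "ai": {}}
    topo_cache: dict[str, _SourceCosts] = {}
    surfaces = {"th": np.asarray(th, float), "ai": np.asarray(ai, float)}

    def env_from(sid: str, which: str) -> _SourceCosts:
        cache = env_caches[which]
        if sid not in cache:
            vals = surfaces[which]
            c = np.abs(vals - vals[node[sid]])
            cache[sid] = _source_costs(graph, node[sid], per_cell_cost=c)
        return cache[sid]

    def topo_from(sid: str) -> _SourceCosts:
        if sid not in topo_cache:
            topo_cache[sid] = _source_costs(graph, node[sid], topo_elev=elev)
        return topo_cache[sid]

    records = []
    n_disconnected = 0
    for id_a, id_b in pairs[["id_a", "id_b"]].itertuples(index=False):
        sa, sb = sorted((id_a, id_b))
        na, nb = node[sa], node[sb]
        lat_a, lon_a = soc.at[sa, "lat"], soc.at[sa, "lon"]
        lat_b, lon_b = soc.at[sb, "lat"], soc.at[sb, "lon"]
        rec = {"id_a": sa, "id_b": sb}
        reachable = True
        for which in ("th", "ai"):
            fwd = env_from(sa, which)
            rev = env_from(sb, which)
            if not (np.isfinite(fwd.weight[nb]) and np.isfinite(rev.weight[na])):
                reachable = False
                break
            cost = 0.5 * (fwd.cost[nb] + rev.cost[na])
            length = 0.5 * (fwd.length[nb] + rev.length[na])
            rec[f"{which}_cost"] = np.log1p(cost)
            rec[f"{which}_len"] = np.log1p(length)
            vals = surfaces[which]
            rec[f"{which}_dissim"] = abs(vals[na] - vals[nb])
        if reachable:
            tp = topo_from(sa)
            if not np.isfinite(tp.weight[nb]):
                reachable = False
        if not reachable:
            n_disconnected += 1
            continue
        rec["topo_cost"] = np.log1p(tp.cost[nb])
        rec["topo_len"] = np.log1p(tp.length[nb])
        rec["geodesic_km"] = float(geodesic_km(lat_a, lon_a, lat_b, lon_b))
        records.append(rec)
    if n_disconnected:
        logger.warning("compute_pair_barriers: %d disconnected pairs excluded", n_disconnected)
    out = pd.DataFrame.from_records(records)
    return out[["id_a", "id_b"] + BARRIER_COLUMNS] if len(out) else out
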