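"""Pairwise geographic and environmental distance matrices.

Four kinds of between-population distances:

* straight-line (planar or great-circle haversine, Earth radius 6371 km);
* per-variable environmental distances (absolute differences);
* least-cost distance (LCD) over a resistance raster with the eight-neighbor
  connection scheme;
* circuit distance (CD): effective electrical resistance on the same grid
  graph, integrating all paths rather than only the cheapest one.

The resistance surface derives from a habitat-suitability raster in [0, 1].
The suitability-to-cost transform is a modeling choice, not a fact of the
data: the default maps suitability directly to conductance (good habitat
conducts), the alternative maps resistance = 1 - suitability + eps; the two
rank cells in reverse order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import splu

from .core import PairwiseMatrix
from .rasters import Grid

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
SQRT2 = float(np.sqrt(2.0))

__all__ = [
    "ResistanceRaster",
    "euclidean_matrix",
    "env_distance_matrices",
    "suitability_to_resistance",
    "least_cost_distance",
    "circuit_distance",
]


@dataclass
class ResistanceRaster:
    """Per-cell conductance on a grid; resistance is its reciprocal."""

    grid: Grid                 # data = conductance, NaN = nodata

    def __post_init__(self) -> None:
        cond = self.grid.data
        valid = np.isfinite(cond)
        if not valid.any():
            raise ValueError("resistance raster has no valid cells")
        if (cond[valid] <= 0).any():
            raise ValueError("conductance must be positive on all valid cells")

    @property
    def conductance(self) -> np.ndarray:
        return self.grid.data

    @property
    def resistance(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 1.0 / self.grid.data


def euclidean_matrix(pop_table: pd.DataFrame, mode: str = "planar") -> PairwiseMatrix:
    """Straight-line distances between populations.

    ``planar`` uses x/y columns in raw map units; ``great-circle`` uses
    lon/lat columns (degrees) with the haversine formula, returning km.
    """
    labels = list(pop_table.index.astype(str))
    if mode == "planar":
        cols = ("x", "y") if "x" in pop_table.columns else ("lon", "lat")
        xy = pop_table[list(cols)].to_numpy(dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        vals = np.sqrt((diff ** 2).sum(axis=-1))
    elif mode == "great-circle":
        cols = ("lon", "lat") if "lon" in pop_table.columns else ("x", "y")
        lon = np.radians(pop_table[cols[0]].to_numpy(dtype=float))
        lat = np.radians(pop_table[cols[1]].to_numpy(dtype=float))
        if np.any(np.abs(lat) > np.pi / 2 + 1e-12):
            raise ValueError("latitude outside [-90, 90] degrees")
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        vals = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    else:
        raise ValueError("mode must be 'planar' or 'great-circle'")
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(labels=labels, values=vals, kind="geographic-euclidean")


def env_distance_matrices(env_table: pd.DataFrame) -> dict[str, PairwiseMatrix]:
    """One |x_i - x_j| matrix per environmental variable."""
    if env_table.isna().any().any():
        bad = env_table.stack(future_stack=True)
        bad = bad[bad.isna()].index.tolist()[:5]
        raise ValueError(f"missing environmental values: {bad}")
    labels = list(env_table.index.astype(str))
    out = {}
    for var in env_table.columns:
        v = env_table[var].to_numpy(dtype=float)
        out[str(var)] = PairwiseMatrix(
            labels=labels,
            values=np.abs(v[:, None] - v[None, :]),
            kind=f"environmental:{var}",
        )
    return out


def suitability_to_resistance(
    suitability: Grid, method: str = "conductance", epsilon: float = 1e-3
) -> ResistanceRaster:
    """Turn a habitat-suitability raster (values in [0, 1]) into conductances.

    ``conductance``: conductance = max(suitability, epsilon).
    ``complement``: resistance = 1 - suitability + epsilon.
    """
    s = suitability.data
    valid = np.isfinite(s)
    if ((s[valid] < 0) | (s[valid] > 1)).any():
        raise ValueError("suitability values must lie in [0, 1]")
    if method == "conductance":
        cond = np.maximum(s, epsilon)
    elif method == "complement":
        cond = 1.0 / (1.0 - s + epsilon)
    else:
        raise ValueError("method must be 'conductance' or 'complement'")
    cond = np.where(valid, cond, np.nan)
    return ResistanceRaster(
        grid=Grid(data=cond, cell_size=suitability.cell_size, origin=suitability.origin)
    )


def _grid_graph(rr: ResistanceRaster, weight: str) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Sparse 8-neighbor graph over valid cells.

    ``weight='cost'``: edge weight = mean cell resistance * cell size
    (* sqrt(2) for diagonals) — for least-cost paths.
    ``weight='conductance'``: edge weight = mean cell conductance / distance
    factor — for the circuit Laplacian.

    Returns the symmetric adjacency and the flat-index -> node-id map
    (-1 for nodata cells).
    """
    cond = rr.conductance
    nrows, ncols = cond.shape
    valid = np.isfinite(cond)
    node_id = -np.ones(cond.shape, dtype=int)
    node_id[valid] = np.arange(valid.sum())
    res = 1.0 / cond
    rows_i, cols_j, weights = [], [], []
    # four forward neighbor offsets cover each undirected edge once
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        r0 = slice(0, nrows - dr)
        r1 = slice(dr, nrows)
        if dc >= 0:
            c0, c1 = slice(0, ncols - dc), slice(dc, ncols)
        else:
            c0, c1 = slice(-dc, ncols), slice(0, ncols + dc)
        ok = valid[r0, c0] & valid[r1, c1]
        a = node_id[r0, c0][ok]
        b = node_id[r1, c1][ok]
        factor = SQRT2 if diag else 1.0
        if weight == "cost":
            w = (
                0.5 * (res[r0, c0][ok] + res[r1, c1][ok])
                * rr.grid.cell_size * factor
            )
        elif weight == "conductance":
            w = 0.5 * (cond[r0, c0][ok] + cond[r1, c1][ok]) / factor
        else:
            raise ValueError(weight)
        rows_i.append(a); cols_j.append(b); weights.append(w)
    i = np.concatenate(rows_i); j = np.concatenate(cols_j)
    w = np.concatenate(weights)
    n = int(valid.sum())
    adj = sparse.coo_matrix((w, (i, j)), shape=(n, n))
    adj = (adj + adj.T).tocsr()
    return adj, node_id


def _pop_nodes(rr: ResistanceRaster, pop_table: pd.DataFrame, node_id: np.ndarray):
    labels = list(pop_table.index.astype(str))
    nodes = []
    for _, rec in pop_table.iterrows():
        if "row" in pop_table.columns and np.isfinite(
            rr.conductance[int(rec["row"]), int(rec["col"])]
        ):
            r, c = int(rec["row"]), int(rec["col"])
        else:
            r, c = rr.grid.snap(float(rec["x"]), float(rec["y"]))
        nodes.append(int(node_id[r, c]))
    return labels, np.asarray(nodes, dtype=int)


def least_cost_distance(rr: ResistanceRaster, pop_table: pd.DataFrame) -> PairwiseMatrix:
    """Least-cost distances between populations over the resistance grid.

    Edge cost between adjacent cells is the arithmetic mean of the two cell
    resistances times the cell size (times sqrt(2) for diagonal moves);
    shortest paths via Dijkstra from each population cell.
    """
    adj, node_id = _grid_graph(rr, weight="cost")
    labels, nodes = _pop_nodes(rr, pop_table, node_id)
    dist = dijkstra(adj, directed=False, indices=nodes)
    vals = dist[:, nodes]
    if not np.all(np.isfinite(vals)):
        bad = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(len(labels))
            if i < j and not np.isfinite(vals[i, j])
        ]
        raise ValueError(f"population pairs disconnected on resistance grid: {bad[:5]}")
    vals = 0.5 * (vals + vals.T)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(labels=labels, values=vals, kind="geographic-lcd")


def circuit_distance(
    rr: ResistanceRaster, pop_table: pd.DataFrame, dense_threshold: int = 0
) -> PairwiseMatrix:
    """Effective-resistance (circuit) distances between populations.

    Edge conductance between adjacent cells is the arithmetic mean of the two
    cell conductances divided by the move-length factor (1 or sqrt(2)).
    Effective resistance R_ij = (e_i - e_j)^T L^+ (e_i - e_j) is computed via
    sparse grounded solves — one factorized solve per source population —
    never a dense pseudoinverse (grounding one node and solving
    L_g x = e_i - e_j is algebraically identical to applying L^+ to the
    difference of unit injections).
    """
    adj, node_id = _grid_graph(rr, weight="conductance")
    n = adj.shape[0]
    ncomp, comp = connected_components(adj, directed=False)
    labels, nodes = _pop_nodes(rr, pop_table, node_id)
    if ncomp > 1 and len(set(comp[nodes])) > 1:
        raise ValueError("populations fall in disconnected raster components")
    if ncomp > 1:
        # restrict to the component holding the populations
        keep = comp == comp[nodes[0]]
        remap = -np.ones(n, dtype=int)
        remap[keep] = np.arange(keep.sum())
        adj = adj[keep][:, keep]
        nodes = remap[nodes]
        n = adj.shape[0]
    lap = sparse.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    # ground one node (preferably not a population cell); entries of the
    # grounded inverse at the ground are identically zero
    used = set(nodes.tolist())
    ground = next((i for i in range(n) if i not in used), int(nodes[-1]))
    keep_idx = np.array([i for i in range(n) if i != ground])
    pos = -np.ones(n, dtype=int)
    pos[keep_idx] = np.arange(n - 1)
    lap_g = lap[keep_idx][:, keep_idx].tocsc()
    lu = splu(lap_g)
    # one grounded solve per source: x_i = L_g^{-1} e_i
    uniq = sorted(set(nodes.tolist()))
    sols: dict[int, np.ndarray | None] = {}
    for node in uniq:
        if node == ground:
            sols[node] = None
            continue
        e = np.zeros(n - 1)
        e[pos[node]] = 1.0
        sols[node] = lu.solve(e)

    def entry(x, node: int) -> float:
        return 0.0 if (x is None or node == ground) else float(x[pos[node]])

    m = len(labels)
    vals = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ni, nj = nodes[i], nodes[j]
            if ni == nj:
                r = 0.0
            else:
                xi, xj = sols[ni], sols[nj]
                r = entry(xi, ni) - entry(xi, nj) - entry(xj, ni) + entry(xj, nj)
            vals[i, j] = vals[j, i] = max(r, 0.0)
    return PairwiseMatrix(labels=labels, values=vals, kind="geographic-cd")
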