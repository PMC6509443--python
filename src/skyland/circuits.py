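"""Circuit-theory connectivity on raster resistance surfaces.

Every unmasked cell becomes a node; neighbouring cells are joined by a
resistor whose resistance is the arithmetic mean of the two cell values
(diagonal edges scaled by sqrt(2)). Effective resistance between focal
nodes is obtained from the conductance Laplacian with one grounded node per
connected component; all node pairs on one surface share a single sparse LU
factorization. Disconnection is data, not an error: pairs in different
components get infinite resistance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, splu

from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ResistanceGraph",
    "FocalNode",
    "build_graph",
    "snap_focal",
    "effective_resistance",
    "current_map",
    "pairwise_resistance",
    "base_resistance",
    "CircuitSolver",
]


@dataclass
class ResistanceGraph:
    """Node/edge view of a resistance raster.

    ``node_of_cell`` maps grid cells to node ids (-1 for masked cells);
    ``edges`` is an (m, 2) int array of node pairs with resistances in
    ``edge_resistance``.
    """

    node_of_cell: np.ndarray
    cell_of_node: np.ndarray  # (n, 2) row/col per node
    edges: np.ndarray
    edge_resistance: np.ndarray
    connectivity: int
    grid: RasterGrid

    @property
    def n_nodes(self) -> int:
        return self.cell_of_node.shape[0]

    def laplacian(self) -> sparse.csc_matrix:
        """Conductance-weighted graph Laplacian."""
        n = self.n_nodes
        g = 1.0 / self.edge_resistance
        i, j = self.edges[:, 0], self.edges[:, 1]
        a = sparse.coo_matrix(
            (np.concatenate([g, g]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(a.sum(axis=1)).ravel()
        return (sparse.diags(deg) - a).tocsc()

    def components(self) -> np.ndarray:
        n = self.n_nodes
        i, j = self.edges[:, 0], self.edges[:, 1]
        a = sparse.coo_matrix(
            (np.ones(len(i)), (i, j)), shape=(n, n)
        )
        return connected_components(a, directed=False)[1]


@dataclass
class FocalNode:
    label: str
    xy: tuple[float, float]
    node: int
    snap_distance: float = 0.0


def build_graph(surface: RasterGrid, connectivity: int = 8) -> ResistanceGraph:
    """Build the resistor network for a strictly positive resistance surface."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    ok = ~surface.nodata_mask
    vals = surface.values
    if np.any(vals[ok] <= 0):
        raise ValueError("resistance surface must be strictly positive where unmasked")
    nrows, ncols = surface.shape
    node_of_cell = np.full((nrows, ncols), -1, dtype=np.int64)
    rr, cc = np.nonzero(ok)
    node_of_cell[rr, cc] = np.arange(len(rr))
    cell_of_node = np.column_stack([rr, cc])
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    e_i, e_j, e_r = [], [], []
    for dr, dc in offsets:
        rs = slice(max(dr, 0), nrows + min(dr, 0))
        cs = slice(max(dc, 0), ncols + min(dc, 0))
        rs2 = slice(max(-dr, 0), nrows + min(-dr, 0))
        cs2 = slice(max(-dc, 0), ncols + min(-dc, 0))
        both = ok[rs2, cs2] & ok[rs, cs]
        a = node_of_cell[rs2, cs2][both]
        b = node_of_cell[rs, cs][both]
        r = 0.5 * (vals[rs2, cs2][both] + vals[rs, cs][both])
        if dr != 0 and dc != 0:
            r = r * np.sqrt(2.0)
        e_i.append(a)
        e_j.append(b)
        e_r.append(r)
    edges = np.column_stack([np.concatenate(e_i), np.concatenate(e_j)])
    return ResistanceGraph(
        node_of_cell=node_of_cell,
        cell_of_node=cell_of_node,
        edges=edges,
        edge_resistance=np.concatenate(e_r),
        connectivity=connectivity,
        grid=surface,
    )


def snap_focal(
    localities: pd.DataFrame,
    surface: RasterGrid,
    graph: ResistanceGraph | None = None,
    max_snap_cells: float = 10.0,
) -> dict[str, FocalNode]:
    """Population centroids snapped to the nearest unmasked cell center.

    The focal point of each population is the mean (x, y) of its sample
    coordinates; if the containing cell is masked, the nearest unmasked cell
    center within ``max_snap_cells`` cell widths is used.
    """
    if graph is None:
        graph = build_graph(surface)
    ok_rows, ok_cols = np.nonzero(~surface.nodata_mask)
    ok_x, ok_y = surface.cell_center(ok_rows, ok_cols)
    out: dict[str, FocalNode] = {}
    for pop, sub in localities.groupby("population"):
        cx, cy = float(sub["x"].mean()), float(sub["y"].mean())
        d2 = (ok_x - cx) ** 2 + (ok_y - cy) ** 2
        k = int(np.argmin(d2))
        dist = float(np.sqrt(d2[k]))
        if dist > max_snap_cells * surface.cell_size:
            raise ValueError(
                f"population {pop}: no unmasked cell within "
                f"{max_snap_cells} cells of centroid ({cx:.0f}, {cy:.0f})"
            )
        node = int(graph.node_of_cell[ok_rows[k], ok_cols[k]])
        if dist > 0.8 * surface.cell_size:
            logger.info("population %s centroid snapped %.1f m", pop, dist)
        out[str(pop)] = FocalNode(str(pop), (cx, cy), node, dist)
    return out


class CircuitSolver:
    """Shared Laplacian factorization for many pair solves on one graph.

    The Laplacian is singular; one node per connected component is grounded
    (its row/column removed), which makes the reduced system nonsingular.
    ``method`` is "direct" (sparse LU, reused across right-hand sides) or
    "cg" (conjugate gradient with Jacobi preconditioning, tolerance 1e-10).
    """

    def __init__(self, graph: ResistanceGraph, method: str = "direct") -> None:
        self.graph = graph
        self.method = method
        self.comp = graph.components()
        n = graph.n_nodes
        lap = graph.laplacian()
        # ground the first node of each component
        _, first = np.unique(self.comp, return_index=True)
        keep = np.ones(n, dtype=bool)
        keep[first] = False
        self.keep = keep
        self.reduced_index = np.cumsum(keep) - 1  # valid where keep
        self.lap_red = lap[keep][:, keep].tocsc()
        self._lu = None
        if method == "direct":
            self._lu = splu(self.lap_red)
        elif method == "cg":
            d = self.lap_red.diagonal()
            self._precond = sparse.diags(1.0 / d)
        else:
            raise ValueError("method must be 'direct' or 'cg'")

    def _solve(self, b_red: np.ndarray) -> np.ndarray:
        if self._lu is not None:
            return self._lu.solve(b_red)
        x, info = cg(self.lap_red, b_red, rtol=1e-10, atol=0.0, M=self._precond,
                     maxiter=20 * self.lap_red.shape[0])
        if info != 0:
            raise RuntimeError(f"conjugate gradient did not converge (info={info})")
        return x

    def potentials(self, a: int, b: int) -> np.ndarray | None:
        """Node potentials for unit current a -> b; None if disconnected."""
        if self.comp[a] != self.comp[b]:
            return None
        n = self.graph.n_nodes
        rhs = np.zeros(n)
        rhs[a] += 1.0
        rhs[b] -= 1.0
        x_red = self._solve(rhs[self.keep])
        v = np.zeros(n)
        v[self.keep] = x_red
        return v

    def resistance(self, a: int, b: int) -> float:
        """Effective resistance between nodes a and b (inf if disconnected)."""
        if a == b:
            return 0.0
        v = self.potentials(a, b)
        if v is None:
            return np.inf
        return float(v[a] - v[b])


def effective_resistance(
    graph: ResistanceGraph, a: int, b: int, method: str = "direct"
) -> float:
    """Two-point effective resistance; symmetric in (a, b); inf across components."""
    return CircuitSolver(graph, method).resistance(a, b)


def current_map(
    graph: ResistanceGraph, a: int, b: int, method: str = "direct"
) -> RasterGrid:
    """Per-cell current magnitude for unit current injected at a, extracted at b.

    Cell current is half the sum of absolute incident edge currents; the two
    focal cells are not halved, so each carries the full unit current.
    """
    solver = CircuitSolver(graph, method)
    v = solver.potentials(a, b)
    if v is None:
        raise ValueError("focal nodes are in different components")
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    edge_cur = (v[i] - v[j]) / graph.edge_resistance
    node_cur = np.zeros(graph.n_nodes)
    np.add.at(node_cur, i, np.abs(edge_cur))
    np.add.at(node_cur, j, np.abs(edge_cur))
    node_cur *= 0.5
    node_cur[a] *= 2.0
    node_cur[b] *= 2.0
    out = np.zeros(graph.grid.shape)
    out[graph.cell_of_node[:, 0], graph.cell_of_node[:, 1]] = node_cur
    return graph.grid.like(out, graph.grid.nodata_mask.copy())


def pairwise_resistance(
    surface: RasterGrid,
    localities: pd.DataFrame,
    connectivity: int = 8,
    method: str = "direct",
) -> pd.DataFrame:
    """Effective resistance between every pair of population centroids.

    Returns a symmetric DataFrame (populations x populations) with a zero
    diagonal; disconnected pairs get ``inf``.
    """
    graph = build_graph(surface, connectivity)
    focal = snap_focal(localities, surface, graph)
    solver = CircuitSolver(graph, method)
    pops = sorted(focal)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for x in range(len(pops)):
        for y in range(x + 1, len(pops)):
            r = solver.resistance(focal[pops[x]].node, focal[pops[y]].node)
            mat.iloc[x, y] = mat.iloc[y, x] = r
    return mat


def base_resistance(
    mask_geometry: RasterGrid,
    localities: pd.DataFrame,
    connectivity: int = 8,
    method: str = "direct",
) -> pd.DataFrame:
    """Pairwise resistance on an all-ones surface with the given NoData mask.

    Isolates the effect of extent/geometry from surface values; used to
    check corridor comparability before interpreting resistance differences.
    """
    ones = mask_geometry.like(
        np.ones(mask_geometry.shape), mask_geometry.nodata_mask.copy()
    )
    return pairwise_resistance(ones, localities, connectivity, method)
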