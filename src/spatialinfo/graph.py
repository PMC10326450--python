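"""Spatial neighborhood graphs and random-walk sampling.

The neighborhood distribution over cell pairs is induced by k-step uniform
random walks on a symmetric spatial graph: from each cell, every step moves
to a uniformly chosen neighbor.  Longer walks widen the neighborhood; the
stationary limit is degree-proportional, at which point spatial locality is
lost, so k is kept modest (default 10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from sklearn.neighbors import NearestNeighbors


@dataclass
class SpatialGraph:
    """Symmetric adjacency over cells in CSR-like form.

    ``indices[indptr[i]:indptr[i+1]]`` are the neighbors of cell ``i``;
    ``degrees[i]`` their count.  No self loops.  The implied transition
    matrix is uniform over neighbors (each row sums to 1).
    """

    n_cells: int
    indptr: np.ndarray
    indices: np.ndarray
    method: str = "delaunay"
    degrees: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.degrees = np.diff(self.indptr)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def edge_set(self) -> set[tuple[int, int]]:
        out = set()
        for i in range(self.n_cells):
            for j in self.neighbors(i):
                out.add((min(i, int(j)), max(i, int(j))))
        return out

    def transition_matrix(self) -> np.ndarray:
        """Dense uniform-neighbor transition matrix (small graphs only)."""
        P = np.zeros((self.n_cells, self.n_cells))
        for i in range(self.n_cells):
            nbr = self.neighbors(i)
            P[i, nbr] = 1.0 / len(nbr)
        return P


@dataclass
class WalkBatch:
    """One k-step walk per cell: endpoints and Euclidean start-end distances."""

    start_idx: np.ndarray
    end_idx: np.ndarray
    dist: np.ndarray


def _edges_to_graph(n: int, edges: set[tuple[int, int]], method: str) -> SpatialGraph:
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        if i == j:
            continue
        adj[i].append(j)
        adj[j].append(i)
    indptr = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        adj[i] = sorted(set(adj[i]))
        indptr[i + 1] = indptr[i] + len(adj[i])
    indices = np.concatenate([np.asarray(a, dtype=np.int64) for a in adj]) if n else np.empty(0, np.int64)
    return SpatialGraph(n_cells=n, indptr=indptr, indices=indices, method=method)


def _repair_isolated(coords: np.ndarray, edges: set[tuple[int, int]]) -> None:
    """Connect degree-0 cells to their nearest other cell (walks must exist)."""
    n = coords.shape[0]
    deg = np.zeros(n, dtype=int)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    isolated = np.where(deg == 0)[0]
    if len(isolated) == 0:
        return
    nn = NearestNeighbors(n_neighbors=2).fit(coords)
    _, idx = nn.kneighbors(coords[isolated])
    for i, row in zip(isolated, idx):
        j = int(row[1]) if row[1] != i else int(row[0])
        edges.add((min(int(i), j), max(int(i), j)))


def build_graph(
    coords: np.ndarray,
    method: str = "delaunay",
    epsilon: float | None = None,
    knn_m: int = 6,
    prune_quantile: float = 0.99,
) -> SpatialGraph:
    """Build a symmetric spatial neighborhood graph.

    Parameters
    ----------
    method : {"delaunay", "radius", "knn", "grid"}
        ``delaunay``: triangulation edges, with edges longer than the
        ``prune_quantile`` edge-length quantile pruned (long hull-spanning
        edges distort neighborhoods).  ``radius``: all pairs within
        ``epsilon``.  ``knn``: union-symmetrized m-nearest neighbors.
        ``grid``: lattice adjacency — all pairs within 1.05x the minimum
        positive nearest-neighbor spacing, giving 4 neighbors on a square
        lattice and 6 on a hexagonal (array-style) one.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a graph")

    if method == "delaunay":
        if n < 3:
            warnings.warn("fewer than 3 cells; falling back to knn graph")
            return build_graph(coords, "knn", knn_m=1)
        try:
            tri = Delaunay(coords)
        except QhullError:
            warnings.warn("degenerate (collinear) coordinates; falling back to knn graph")
            return build_graph(coords, "knn", knn_m=min(knn_m, n - 1))
        edges: set[tuple[int, int]] = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = int(simplex[a]), int(simplex[b])
                    edges.add((min(i, j), max(i, j)))
        if prune_quantile is not None and len(edges) > 4:
            earr = np.asarray(sorted(edges))
            lens = np.linalg.norm(coords[earr[:, 0]] - coords[earr[:, 1]], axis=1)
            cutoff = np.quantile(lens, prune_quantile)
            edges = {tuple(e) for e, L in zip(map(tuple, earr), lens) if L <= cutoff}
        _repair_isolated(coords, edges)
        return _edges_to_graph(n, edges, "delaunay")

    if method == "radius":
        if epsilon is None or epsilon <= 0:
            raise ValueError("radius graph requires epsilon > 0")
        nn = NearestNeighbors(radius=epsilon).fit(coords)
        neigh = nn.radius_neighbors(coords, return_distance=False)
        edges = set()
        for i, row in enumerate(neigh):
            for j in row:
                if int(j) != i:
                    edges.add((min(i, int(j)), max(i, int(j))))
        _repair_isolated(coords, edges)
        return _edges_to_graph(n, edges, "radius")

    if method == "knn":
        if knn_m < 1:
            raise ValueError("knn graph requires m >= 1")
        m = min(knn_m, n - 1)
        nn = NearestNeighbors(n_neighbors=m + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        edges = set()
        for i in range(n):
            for j in idx[i]:
                if int(j) != i:
                    edges.add((min(i, int(j)), max(i, int(j))))
        return _edges_to_graph(n, edges, "knn")

    if method == "grid":
        nn = NearestNeighbors(n_neighbors=2).fit(coords)
        d, _ = nn.kneighbors(coords)
        spacing = float(np.min(d[:, 1][d[:, 1] > 0])) if np.any(d[:, 1] > 0) else 1.0
        return build_graph(coords, "radius", epsilon=1.05 * spacing)

    raise ValueError(f"unknown graph method {method!r}")


def sample_walks(
    graph: SpatialGraph,
    coords: np.ndarray,
    k: int,
    rng: np.random.Generator,
    starts: np.ndarray | None = None,
) -> WalkBatch:
    """Draw one k-step uniform-neighbor random walk from every cell.

    Returns start indices (identity by default), endpoint indices reachable in
    exactly k edge steps, and the Euclidean start-to-end distance of each walk.
    k=0 is the identity walk.
    """
    if k < 0:
        raise ValueError("walk length must be >= 0")
    coords = np.asarray(coords, dtype=float)
    if starts is None:
        starts = np.arange(graph.n_cells, dtype=np.int64)
    cur = starts.copy()
    indptr, indices, deg = graph.indptr, graph.indices, graph.degrees
    for _ in range(k):
        u = rng.random(cur.shape[0])
        offs = (u * deg[cur]).astype(np.int64)
        cur = indices[indptr[cur] + offs]
    dist = np.linalg.norm(coords[starts] - coords[cur], axis=1)
    return WalkBatch(start_idx=starts, end_idx=cur, dist=dist)
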