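"""Weighted least squares on difference (adjacency) systems.

This is the shared "linear system solver" used throughout the pipeline:
tile coordinates, sub-tile brightness shifts, and per-grid-point 3D warp
vectors are all solved from systems of measured pairwise differences.
Each row of the system matrix has exactly two nonzero entries, +1 at the
destination node and -1 at the source node, so that

    A @ coords = deltas,   delta_e = pos[dst_e] - pos[src_e].

Axes are solved independently.  The gauge freedom (a global offset) is
fixed by subtracting the solution mean; for z-chain systems a per-node
linear trend may additionally be removed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve


@dataclass
class DeltaGraph:
    """Difference measurements between nodes.

    edges: (E, 2) int array of (src, dst); deltas: (E, 2) nm;
    weights: (E,) >= 0; outlier / replaced flags: (E,) bool.
    """

    n_nodes: int
    edges: np.ndarray
    deltas: np.ndarray
    weights: np.ndarray = None
    outlier: np.ndarray = None
    replaced: np.ndarray = None

    def __post_init__(self):
        self.edges = np.asarray(self.edges, int).reshape(-1, 2)
        e = len(self.edges)
        self.deltas = np.asarray(self.deltas, float).reshape(e, 2)
        if self.weights is None:
            self.weights = np.ones(e)
        self.weights = np.asarray(self.weights, float).reshape(e)
        if self.outlier is None:
            self.outlier = np.zeros(e, bool)
        if self.replaced is None:
            self.replaced = np.zeros(e, bool)
        self.outlier = np.asarray(self.outlier, bool).reshape(e)
        self.replaced = np.asarray(self.replaced, bool).reshape(e)
        if e:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge node index out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-edges not allowed")
            if (self.weights < 0).any():
                raise ValueError("negative edge weight")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class SolvedCoordinates:
    coords: np.ndarray              # (n_nodes, 2) nm
    residuals: np.ndarray           # (E, 2) nm, measured - implied deltas
    offset_removed: np.ndarray      # (2,) subtracted mean
    trend_removed: np.ndarray | None = None  # (2, 2) [slope, intercept] per axis

    @property
    def residual_norms(self) -> np.ndarray:
        return np.linalg.norm(self.residuals, axis=1)


def _components(graph: DeltaGraph):
    adj = sp.coo_matrix(
        (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    return connected_components(adj, directed=False)


def build_system(graph: DeltaGraph):
    """Return (A, b, w): sparse difference matrix, measured deltas, weights.

    Raises if the graph is disconnected, naming the smallest component.
    """
    n_comp, labels = _components(graph)
    if n_comp > 1:
        sizes = np.bincount(labels)
        smallest = int(np.argmin(sizes))
        members = np.flatnonzero(labels == smallest)
        raise ValueError(
            f"graph has {n_comp} connected components; smallest is "
            f"component {smallest} with {sizes[smallest]} node(s): "
            f"{members[:10].tolist()}"
        )
    e = graph.n_edges
    rows = np.repeat(np.arange(e), 2)
    cols = graph.edges[:, ::-1].ravel()  # dst first (+1), then src (-1)
    vals = np.tile([1.0, -1.0], e)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(e, graph.n_nodes))
    return A, graph.deltas.copy(), graph.weights.copy()


def solve(graph: DeltaGraph, l2: float = 0.0,
          remove_offset: bool = True) -> SolvedCoordinates:
    """Solve min over x of sum_e w_e ||(x_dst - x_src) - delta_e||^2 + l2 ||x||^2.

    Axes are independent; solved via the (sparse) normal equations.  With
    ``l2 == 0`` the system has a pure-offset null space which is fixed by
    mean subtraction; any further rank deficiency raises.
    """
    if l2 < 0:
        raise ValueError("l2 must be >= 0")
    if not np.isfinite(graph.weights).all():
        raise ValueError("non-finite weights")
    A, b, w = build_system(graph)
    W = sp.diags(w)
    AtW = A.T @ W
    N = (AtW @ A).tocsc()
    if l2 > 0:
        N = N + l2 * sp.eye(graph.n_nodes, format="csc")
    else:
        # pin the gauge: the offset null-space makes N singular; anchor one
        # node and restore the mean afterwards
        N = N + sp.csc_matrix(
            (np.array([1.0]), (np.array([0]), np.array([0]))),
            shape=N.shape,
        )
    rhs = AtW @ b  # (n, 2)
    coords = np.column_stack([spsolve(N, rhs[:, k]) for k in range(2)])
    if not np.isfinite(coords).all():
        raise ValueError("rank-deficient system beyond gauge freedom")
    offset = np.zeros(2)
    if remove_offset:
        offset = coords.mean(axis=0)
        coords = coords - offset
    implied = coords[graph.edges[:, 1]] - coords[graph.edges[:, 0]]
    return SolvedCoordinates(coords, b - implied, offset)


def remove_linear_trend(values: np.ndarray, z: np.ndarray):
    """Remove the least-squares line (slope and offset) from ``values(z)``.

    Returns ``(detrended, slope, offset)``.  ``values`` may be (N,) or
    (N, k); the fit is per column.  Requires >= 2 distinct z.
    """
    z = np.asarray(z, float)
    values = np.asarray(values, float)
    if z.ndim != 1 or len(z) != len(values):
        raise ValueError("z must be 1-D and match values")
    if len(np.unique(z)) < 2:
        raise ValueError("need >= 2 distinct z coordinates")
    coeffs = np.polyfit(z, values, 1)  # (2,) or (2, k)
    trend = np.outer(z, np.atleast_1d(coeffs[0])) + coeffs[1]
    trend = trend.reshape(values.shape)
    return values - trend, coeffs[0], coeffs[1]
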