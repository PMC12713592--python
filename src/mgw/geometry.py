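"""Pull-back metrics, arc-length k-NN graphs, and graph geodesics.

The pull-back metric at a point is g(s) = J(s)^T J(s): a symmetric PSD
form on the spatial tangent space measuring how fast features change per
unit spatial displacement.  Geodesic distances under g are approximated at
the resolution of the point set: a k-NN graph on the coordinates (Euclidean
neighborhoods), edge weights equal to the symmetrized local Riemannian
arc-length

    w(i, i') = 1/2 sqrt(D^T g(s_i) D) + 1/2 sqrt(D^T g(s_i') D),   D = s_i - s_i',

and all-pairs shortest paths (per-source Dijkstra) on that graph.  With
g = I this reduces exactly to Euclidean graph geodesics, which is what
makes the downstream alignment collapse to plain spatial GW when the
fields carry no feature information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MetricField",
    "ArcGraph",
    "pullback_metric",
    "build_arc_graph",
    "geodesic_distances",
    "knn_edges",
    "euclidean_arc_graph",
]


@dataclass
class MetricField:
    """Per-point k x k metric tensors, aligned with the dataset's point order."""

    g: np.ndarray  # (n, k, k)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 3 or self.g.shape[1] != self.g.shape[2]:
            raise ValueError(f"metric must be (n, k, k); got {self.g.shape}")
        if not np.isfinite(self.g).all():
            raise ValueError("metric contains non-finite entries")

    def validate(self, sym_tol: float = 1e-10, psd_tol: float = -1e-10) -> None:
        asym = np.abs(self.g - np.swapaxes(self.g, 1, 2)).max()
        if asym > sym_tol:
            raise ValueError(f"metric asymmetry {asym:.2e} exceeds {sym_tol:.0e}")
        ev = np.linalg.eigvalsh(self.g)
        if ev.min() < psd_tol:
            raise ValueError(f"metric has eigenvalue {ev.min():.2e} < {psd_tol:.0e}")


@dataclass
class ArcGraph:
    """Undirected arc-length-weighted graph over the slice's points."""

    n: int
    edges: np.ndarray     # (E, 2) with i < j, unique
    weights: np.ndarray   # (E,) nonnegative arc-lengths
    connected: bool

    def adjacency(self) -> sp.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        A = sp.coo_matrix(
            (np.concatenate([self.weights, self.weights]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        )
        return A.tocsr()


def pullback_metric(J: np.ndarray, epsilon: float = 0.0) -> MetricField:
    """g(s_i) = J(s_i)^T J(s_i) + epsilon * I.

    ``epsilon`` = 0 is the faithful default; a positive value blends the
    metric toward plain spatial geometry (an extension, useful when the
    field is nearly constant somewhere and the graph would collapse).
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 3:
        raise ValueError(f"Jacobian field must be (n, d, k); got {J.shape}")
    if not np.isfinite(J).all():
        raise ValueError("Jacobian contains non-finite entries")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    g = np.einsum("ndk,ndl->nkl", J, J)
    g = 0.5 * (g + np.swapaxes(g, 1, 2))
    if epsilon:
        g = g + epsilon * np.eye(J.shape[2])
    return MetricField(g)


def knn_edges(coords: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Union-symmetrized k-NN edge list (E, 2), i < j, by Euclidean distance."""
    n = coords.shape[0]
    if not 1 <= k_neighbors < n:
        raise ValueError(f"need 1 <= k_neighbors < n; got k={k_neighbors}, n={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    src = np.repeat(np.arange(n), k_neighbors)
    dst = idx[:, 1:].ravel()           # drop self
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    return np.unique(np.column_stack([lo, hi]), axis=0)


def _arc_weights(coords: np.ndarray, g: np.ndarray, edges: np.ndarray) -> np.ndarray:
    D = coords[edges[:, 0]] - coords[edges[:, 1]]
    # Two-step einsum so that with g = I the products are bitwise identical
    # to the plain Euclidean quadratic form (needed for the exact spatial-GW
    # reduction).
    ti = np.einsum("ejk,ek->ej", g[edges[:, 0]], D)
    tj = np.einsum("ejk,ek->ej", g[edges[:, 1]], D)
    qi = np.einsum("ej,ej->e", D, ti)
    qj = np.einsum("ej,ej->e", D, tj)
    qi = np.maximum(qi, 0.0)           # clip PSD round-off
    qj = np.maximum(qj, 0.0)
    return 0.5 * np.sqrt(qi) + 0.5 * np.sqrt(qj)


def _bridge_components(coords: np.ndarray, g: np.ndarray, edges: np.ndarray,
                       weights: np.ndarray, labels: np.ndarray):
    """Add, per component pair on an MST of components, the lowest-arc-length
    connecting edge, until the graph is connected."""
    comp_ids = np.unique(labels)
    ncomp = len(comp_ids)
    # candidate best edge per component pair
    cand = {}
    for a in range(ncomp):
        ia = np.nonzero(labels == comp_ids[a])[0]
        for b in range(a + 1, ncomp):
            ib = np.nonzero(labels == comp_ids[b])[0]
            # arc-lengths of all cross pairs (components are small in practice;
            # cap the search with Euclidean pre-selection for big blocks)
            if len(ia) * len(ib) > 250_000:
                from scipy.spatial import cKDTree

                tree = cKDTree(coords[ib])
                dd, jj = tree.query(coords[ia], k=1)
                order = np.argsort(dd)[:500]
                pairs = np.column_stack([ia[order], ib[jj[order]]])
            else:
                pairs = np.column_stack([np.repeat(ia, len(ib)),
                                         np.tile(ib, len(ia))])
            w = _arc_weights(coords, g, pairs)
            best = int(np.argmin(w))
            cand[(a, b)] = (pairs[best], w[best])
    # MST over the component graph
    cw = np.full((ncomp, ncomp), np.inf)
    for (a, b), (_, w) in cand.items():
        cw[a, b] = cw[b, a] = w
    from scipy.sparse.csgraph import minimum_spanning_tree

    mst = minimum_spanning_tree(sp.csr_matrix(np.where(np.isfinite(cw), cw, 0)))
    add_e, add_w = [], []
    for a, b in zip(*mst.nonzero()):
        key = (min(a, b), max(a, b))
        pair, w = cand[key]
        add_e.append(sorted(pair.tolist()))
        add_w.append(w)
    edges = np.vstack([edges, np.asarray(add_e, dtype=int)])
    weights = np.concatenate([weights, np.asarray(add_w)])
    return edges, weights


def build_arc_graph(coords: np.ndarray, metric: MetricField, k_neighbors: int = 10,
                    connect: bool = True) -> ArcGraph:
    """k-NN graph (Euclidean neighborhoods) weighted by Riemannian arc-length."""
    coords = np.asarray(coords, dtype=float)
    g = metric.g
    if g.shape[0] != coords.shape[0]:
        raise ValueError("metric and coords disagree on the number of points")
    if g.shape[1] != coords.shape[1]:
        raise ValueError("metric dimension does not match coordinate dimension")
    edges = knn_edges(coords, k_neighbors)
    weights = _arc_weights(coords, g, edges)

    A = sp.coo_matrix(
        (np.ones(2 * len(edges)),
         (np.concatenate([edges[:, 0], edges[:, 1]]),
          np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(coords.shape[0],) * 2,
    ).tocsr()
    ncomp, labels = connected_components(A, directed=False)
    if ncomp > 1 and connect:
        edges, weights = _bridge_components(coords, g, edges, weights, labels)
        ncomp = 1
    return ArcGraph(coords.shape[0], edges, weights, connected=(ncomp == 1))


def euclidean_arc_graph(coords: np.ndarray, k_neighbors: int = 10,
                        connect: bool = True) -> ArcGraph:
    """Euclidean-weighted k-NN graph: the spatial-GW reference geometry."""
    coords = np.asarray(coords, dtype=float)
    edges = knn_edges(coords, k_neighbors)
    D = coords[edges[:, 0]] - coords[edges[:, 1]]
    weights = np.sqrt(np.einsum("ej,ej->e", D, D))
    graph = ArcGraph(coords.shape[0], edges, weights, connected=True)
    A = graph.adjacency()
    A.data[:] = 1.0
    ncomp, labels = connected_components(A, directed=False)
    if ncomp > 1:
        if not connect:
            graph.connected = False
            return graph
        eye = np.broadcast_to(np.eye(coords.shape[1]),
                              (coords.shape[0],) + (coords.shape[1],) * 2)
        edges, weights = _bridge_components(coords, eye, edges, weights, labels)
        graph = ArcGraph(coords.shape[0], edges, weights, connected=True)
    return graph


def geodesic_distances(graph: ArcGraph) -> np.ndarray:
    """Dense all-pairs shortest-path matrix (per-source Dijkstra).

    Raises on a disconnected graph (component sizes listed) — bridging is
    the builder's job when enabled.
    """
    if not graph.connected:
        A = graph.adjacency()
        A.data[:] = 1.0
        _, labels = connected_components(A, directed=False)
        sizes = np.bincount(labels)
        raise ValueError(
            f"graph is disconnected (component sizes {sizes.tolist()}); "
            "enable connect_components or raise k"
        )
    D = dijkstra(graph.adjacency(), directed=False)
    if not np.isfinite(D).all():
        raise ValueError("infinite geodesic distances on a flagged-connected graph")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D
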