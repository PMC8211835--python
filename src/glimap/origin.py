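"""Cell-origin prediction and spatial specificity diagnostics.

The posterior over tissue positions for each cell is the mixture
responsibility at the fitted model. Specificity of an assignment is measured
on the k-nearest-neighbor graph of the tissue positions: the mean
shortest-path distance (in hops) from the best position to the next-best
ranked positions, and the cumulative posterior mass within a given graph
radius of the best position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
from sklearn.neighbors import NearestNeighbors

from .em import MappingModel, e_step
from .plsc import ParameterError

UNREACHABLE = np.inf


@dataclass
class PositionGraph:
    """Symmetrized unweighted k-NN graph over tissue positions."""

    adjacency: scipy.sparse.csr_matrix
    k: int

    @property
    def n_positions(self) -> int:
        return self.adjacency.shape[0]

    def shortest_paths(self, sources: np.ndarray | None = None) -> np.ndarray:
        """Hop-count shortest paths from ``sources`` (default: all) to all."""
        dist = scipy.sparse.csgraph.shortest_path(
            self.adjacency, method="D", unweighted=True, directed=False,
            indices=sources)
        return dist


@dataclass
class OriginAssignment:
    """Per-cell origin posterior and its spatial specificity summaries."""

    posterior: np.ndarray               # (N, K)
    best_position: np.ndarray           # (N,) int indices
    specificity_distance: np.ndarray    # (N,) mean hops to next-best ranks
    radial_mass: dict[int, np.ndarray]  # radius -> (N,) cumulative posterior


def posterior_origin(X: np.ndarray, model: MappingModel) -> np.ndarray:
    """Posterior probability that each cell originated from each position."""
    return e_step(X, model)


def build_knn_graph(coords: np.ndarray, k: int = 6) -> PositionGraph:
    """Connect each position to its ``k`` Euclidean nearest neighbors.

    Edges are symmetrized by union and the graph is unweighted, so path
    lengths count hops. A disconnected graph is allowed; unreachable pairs
    get infinite distance (with a warning at query support construction).
    """
    coords = np.asarray(coords, dtype=float)
    K = coords.shape[0]
    if not (1 <= k < K):
        raise ParameterError(f"k={k} must satisfy 1 <= k < K={K}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    adj = nn.kneighbors_graph(coords, mode="connectivity")
    adj = adj.tolil()
    adj.setdiag(0)
    adj = adj.tocsr()
    adj.eliminate_zeros()
    adj = adj.maximum(adj.T)  # union symmetrization
    n_comp, _ = scipy.sparse.csgraph.connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(f"position graph has {n_comp} connected components; "
                      "cross-component distances are infinite", stacklevel=2)
    return PositionGraph(adjacency=adj, k=k)


def assignment_specificity(posterior: np.ndarray, graph: PositionGraph,
                           top_m: int = 3) -> np.ndarray:
    """Mean path length from each cell's best position to its next ``top_m``.

    Positions are ranked by posterior; ties in the posterior are broken by
    lowest position index (stable argsort on negated values).
    """
    posterior = np.asarray(posterior, dtype=float)
    if top_m < 1:
        raise ParameterError("top_m must be >= 1")
    if posterior.shape[1] < top_m + 1:
        raise ParameterError(
            f"need at least top_m+1={top_m + 1} positions, have "
            f"{posterior.shape[1]}"
        )
    order = np.argsort(-posterior, axis=1, kind="stable")
    best = order[:, 0]
    runners = order[:, 1:top_m + 1]
    dist_from_best = graph.shortest_paths(np.unique(best))
    row_of = {p: i for i, p in enumerate(np.unique(best))}
    out = np.empty(posterior.shape[0])
    for n in range(posterior.shape[0]):
        d = dist_from_best[row_of[best[n]], runners[n]]
        out[n] = d.mean()
    return out


def radial_posterior_mass(posterior: np.ndarray, graph: PositionGraph,
                          radii: list[int]) -> dict[int, np.ndarray]:
    """Cumulative posterior within each graph radius of the best position.

    mass(r) for a cell sums its posterior over positions within ``r`` hops of
    its top-posterior position; non-decreasing in r and reaching 1 at the
    graph diameter on a connected graph.
    """
    posterior = np.asarray(posterior, dtype=float)
    radii = [int(r) for r in radii]
    if any(r < 0 for r in radii):
        raise ParameterError("radii must be nonnegative integers")
    order = np.argsort(-posterior, axis=1, kind="stable")
    best = order[:, 0]
    uniq = np.unique(best)
    dist = graph.shortest_paths(uniq)
    row_of = {p: i for i, p in enumerate(uniq)}
    out = {r: np.empty(posterior.shape[0]) for r in radii}
    for n in range(posterior.shape[0]):
        d = dist[row_of[best[n]]]
        for r in radii:
            out[r][n] = posterior[n, d <= r].sum()
    return out


def assign_origins(X: np.ndarray, model: MappingModel, coords: np.ndarray,
                   k: int = 6, top_m: int = 3,
                   radii: list[int] | None = None) -> OriginAssignment:
    """Posterior, best position, specificity, and radial masses in one call."""
    posterior = posterior_origin(X, model)
    graph = build_knn_graph(coords, k)
    if radii is None:
        radii = [0, 1, 2, 4]
    order = np.argsort(-posterior, axis=1, kind="stable")
    return OriginAssignment(
        posterior=posterior,
        best_position=order[:, 0],
        specificity_distance=assignment_specificity(posterior, graph, top_m),
        radial_mass=radial_posterior_mass(posterior, graph, radii),
    )
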