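"""Weighted small-world metrics.

Implements the weighted graph panel used to test for small-world
organisation: Onnela-style weighted clustering (geometric mean of triangle
weights, max-normalised so C lies in [0, 1]), weighted characteristic path
length with reciprocal edge lengths (length = 1/w, the usual convention for
correlation weights), degree- and weight-preserving null ensembles built by
double-edge swaps, the normalised ratios gamma = C_w / C_w^rand and
lambda = L_w / L_w^rand, the small-worldness index sigma = gamma / lambda,
and the mean-weight connectivity cost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .preprocessing import ConnectivityMatrix

logger = logging.getLogger(__name__)


def max_edges(n_rois: int) -> int:
    """Edge capacity of an undirected simple graph: n(n-1)/2."""
    if n_rois < 0:
        raise ValueError("n_rois must be nonnegative")
    return n_rois * (n_rois - 1) // 2


@dataclass
class SmallWorldResult:
    """Raw and null-normalised small-world panel for one subject."""

    c_w: float  # average weighted clustering
    l_w: float  # weighted characteristic path length
    c_w_rand: float  # null-ensemble mean clustering
    l_w_rand: float  # null-ensemble mean path length
    gamma: float  # c_w / c_w_rand
    lam: float  # l_w / l_w_rand
    sigma: float  # gamma / lam
    conn: float  # mean off-diagonal weight
    n_null: int
    per_node_clustering: np.ndarray


def weighted_clustering(conn: ConnectivityMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node weighted clustering C_i and its mean C_w.

    Weights are first scaled by the network maximum; the triangle intensity
    around node i is t_i = 1/2 * sum_{j,k} (w_ij w_jk w_ki)^(1/3) and
    C_i = 2 t_i / (k_i (k_i - 1)), with C_i = 0 where the degree k_i < 2.
    """
    weights = _as_weights(conn)
    n = weights.shape[0]
    w_max = weights.max()
    if w_max == 0:
        return np.zeros(n), 0.0
    cube = np.cbrt(weights / w_max)
    triangles = np.diag(cube @ cube @ cube) / 2.0
    degree = (weights > 0).sum(axis=1)
    c_i = np.zeros(n)
    mask = degree >= 2
    c_i[mask] = 2.0 * triangles[mask] / (degree[mask] * (degree[mask] - 1))
    return c_i, float(c_i.mean())


def shortest_paths(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest weighted distances with edge length 1/w.

    Unreachable pairs come back infinite; callers decide whether that is an
    error (default) or triggers the harmonic-mean fallback.
    """
    weights = _as_weights(conn)
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def is_connected(conn: ConnectivityMatrix | np.ndarray) -> bool:
    return bool(np.isfinite(shortest_paths(conn)).all())


def characteristic_path_length(
    distances: np.ndarray, harmonic_fallback: bool = False
) -> float:
    """Mean shortest distance over ordered node pairs.

    With ``harmonic_fallback`` the harmonic mean is used instead, which
    tolerates infinite distances from disconnected graphs.
    """
    n = distances.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = distances[off]
    if harmonic_fallback:
        with np.errstate(divide="ignore"):
            return float(1.0 / np.mean(1.0 / vals))
    if not np.isfinite(vals).all():
        raise ValueError(
            "graph is disconnected; enable harmonic_fallback or check inputs"
        )
    return float(vals.mean())


def connectivity_cost(conn: ConnectivityMatrix | np.ndarray) -> float:
    """Mean off-diagonal weight (absent edges count as 0)."""
    weights = _as_weights(conn)
    n = weights.shape[0]
    if n < 2:
        raise ValueError("connectivity cost needs at least 2 nodes")
    return float(weights.sum() / (n * (n - 1)))


def null_ensemble(
    conn: ConnectivityMatrix | np.ndarray,
    n_null: int = 100,
    iterations_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Degree- and weight-preserving random rewirings of the graph.

    Each null is produced by Maslov–Sneppen double-edge swaps with weights
    travelling on their edges, so the degree sequence and the multiset of
    edge weights are both preserved.  If no swap is ever possible (e.g. a
    complete graph) the nulls equal the input and a warning is emitted.
    """
    weights = _as_weights(conn)
    rng = np.random.default_rng(seed)
    i_idx, j_idx = np.nonzero(np.triu(weights, 1))
    edges = list(zip(i_idx.tolist(), j_idx.tolist()))
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; null ensemble equals the input")
        return [weights.copy() for _ in range(n_null)]
    nulls = []
    any_swapped = False
    for _ in range(n_null):
        null, swapped = _rewire(weights, edges, iterations_per_edge, rng)
        any_swapped |= swapped
        nulls.append(null)
    if not any_swapped:
        warnings.warn(
            "no rewirable edge pairs found; null ensemble equals the input"
        )
    return nulls


def _rewire(
    weights: np.ndarray,
    edges: list[tuple[int, int]],
    iterations_per_edge: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, bool]:
    null = weights.copy()
    edge_list = list(edges)
    m = len(edge_list)
    attempts = iterations_per_edge * m
    swapped = False
    for _ in range(attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b = edge_list[e1]
        c, d = edge_list[e2]
        # swap to (a, d), (c, b); weights travel with their edge
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if null[a, d] > 0 or null[c, b] > 0:
            continue
        w1, w2 = null[a, b], null[c, d]
        null[a, b] = null[b, a] = 0.0
        null[c, d] = null[d, c] = 0.0
        null[a, d] = null[d, a] = w1
        null[c, b] = null[b, c] = w2
        edge_list[e1] = (a, d)
        edge_list[e2] = (c, b)
        swapped = True
    return null, swapped


def small_worldness(
    conn: ConnectivityMatrix | np.ndarray,
    ensemble: list[np.ndarray] | None = None,
    n_null: int = 100,
    iterations_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
    harmonic_fallback: bool = False,
) -> SmallWorldResult:
    """Score a graph against an edge/weight-preserving null ensemble.

    gamma = C_w / mean C_w over nulls, lambda = L_w / mean L_w over nulls,
    sigma = gamma / lambda; sigma > 1 indicates small-world organisation
    (segregation above a random graph at comparable integration).
    """
    weights = _as_weights(conn)
    if ensemble is None:
        ensemble = null_ensemble(weights, n_null, iterations_per_edge, seed)
    if not ensemble:
        raise ValueError("null ensemble is empty")
    c_i, c_w = weighted_clustering(weights)
    l_w = characteristic_path_length(shortest_paths(weights), harmonic_fallback)
    c_rand = float(np.mean([weighted_clustering(m)[1] for m in ensemble]))
    l_rand = float(
        np.mean(
            [
                characteristic_path_length(shortest_paths(m), harmonic_fallback)
                for m in ensemble
            ]
        )
    )
    if c_rand == 0 or l_rand == 0:
        raise ValueError("null ensemble mean is zero; cannot normalise")
    gamma = c_w / c_rand
    lam = l_w / l_rand
    return SmallWorldResult(
        c_w=c_w,
        l_w=l_w,
        c_w_rand=c_rand,
        l_w_rand=l_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        conn=connectivity_cost(weights),
        n_null=len(ensemble),
        per_node_clustering=c_i,
    )


def _as_weights(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(conn, ConnectivityMatrix):
        return conn.weights
    return np.asarray(conn, dtype=float)
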