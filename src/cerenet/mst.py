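"""Maximum-weight spanning trees and their descriptors.

The spanning tree retaining the strongest connections is built with
Kruskal's algorithm run on descending edge weight (equivalently, ascending
reciprocal length), with union–find cycle rejection and a deterministic
lexicographic tie-break.  Three local descriptors (degree, betweenness
centrality, eccentricity) and six global descriptors (diameter, radius,
leaf fraction, tree hierarchy, degree divergence kappa, degree correlation)
follow.

Conventions:

* Betweenness on the tree is the fraction of the (n-1)(n-2)/2 unordered
  node pairs whose unique path passes through the node (endpoints
  excluded), so BC lies in [0, 1] and a star centre attains exactly 1.
* Eccentricity, diameter and radius are hop counts divided by n-1, the
  edge count of the tree.
* Degree and BC are additionally divided by their within-tree maximum;
  tree hierarchy uses the maximum fraction-scale BC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import networkx as nx

from .preprocessing import ConnectivityMatrix

logger = logging.getLogger(__name__)


@dataclass
class SpanningTree:
    """Acyclic connected subgraph with exactly n-1 positive-weight edges."""

    n_nodes: int
    edges: list[tuple[int, int, float]]
    roi_labels: list[str]

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )
        if any(w <= 0 for _, _, w in self.edges):
            raise ValueError("tree edge weights must be positive")
        graph = self.to_networkx()
        if graph.number_of_nodes() != self.n_nodes or not nx.is_connected(graph):
            raise ValueError("edges do not form a connected spanning tree")

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(range(self.n_nodes))
        graph.add_weighted_edges_from(self.edges)
        return graph

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass
class MstLocalMetrics:
    """Per-node tree descriptors, raw and normalised."""

    degree_raw: np.ndarray  # edge count per node
    degree: np.ndarray  # max-normalised
    betweenness_raw: np.ndarray  # fraction of pairs routed through the node
    betweenness: np.ndarray  # max-normalised
    eccentricity_raw: np.ndarray  # hop counts
    eccentricity: np.ndarray  # hops / (n-1)
    roi_labels: list[str]


@dataclass
class MstGlobalMetrics:
    """Whole-tree descriptors on the scales used for group comparison."""

    diameter: float  # max eccentricity, hops/(n-1)
    radius: float  # min eccentricity, hops/(n-1)
    leaf_fraction: float  # N_leaf / (n-1)
    tree_hierarchy: float  # N_leaf / (2 (n-1) BC_max)
    kappa: float  # <k^2> / <k> over raw degrees
    degree_correlation: float  # assortativity over both edge orientations


class DisconnectedGraphError(ValueError):
    """Positive-weight subgraph is not connected; no spanning tree exists."""


def maximum_spanning_tree(conn: ConnectivityMatrix | np.ndarray,
                          roi_labels: list[str] | None = None) -> SpanningTree:
    """Kruskal maximum-weight spanning tree with deterministic tie-breaks.

    Edges are taken in (-weight, i, j) lexicographic order and rejected when
    they would close a cycle (union–find).  Ties between equal weights are
    logged, since tree uniqueness then fails.
    """
    if isinstance(conn, ConnectivityMatrix):
        weights, labels = conn.weights, list(conn.roi_labels)
    else:
        weights = np.asarray(conn, dtype=float)
        labels = roi_labels or [f"ROI{i:02d}" for i in range(weights.shape[0])]
    n = weights.shape[0]
    i_idx, j_idx = np.nonzero(np.triu(weights, 1))
    edge_weights = weights[i_idx, j_idx]
    order = np.lexsort((j_idx, i_idx, -edge_weights))

    if len(np.unique(edge_weights)) < len(edge_weights):
        logger.warning("equal-weight edges present; spanning tree may be non-unique")

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges: list[tuple[int, int, float]] = []
    for k in order:
        a, b = int(i_idx[k]), int(j_idx[k])
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        tree_edges.append((a, b, float(edge_weights[k])))
        if len(tree_edges) == n - 1:
            break
    if len(tree_edges) != n - 1:
        roots = {}
        for node in range(n):
            roots.setdefault(find(node), []).append(labels[node])
        raise DisconnectedGraphError(
            "positive-weight graph is disconnected; components: "
            + "; ".join(", ".join(v) for v in roots.values())
        )
    return SpanningTree(n, tree_edges, labels)


def local_metrics(tree: SpanningTree) -> MstLocalMetrics:
    """Degree, betweenness and eccentricity of every node of the tree."""
    graph = tree.to_networkx()
    n = tree.n_nodes
    degree_raw = tree.degrees()
    # on a tree every pair has a unique shortest path, so the pair-fraction
    # betweenness is exact
    bc = nx.betweenness_centrality(graph, normalized=True, weight=None)
    betweenness_raw = np.array([bc[i] for i in range(n)])
    ecc = nx.eccentricity(graph)
    eccentricity_raw = np.array([ecc[i] for i in range(n)], dtype=float)
    return MstLocalMetrics(
        degree_raw=degree_raw,
        degree=degree_raw / degree_raw.max(),
        betweenness_raw=betweenness_raw,
        betweenness=_max_normalise(betweenness_raw),
        eccentricity_raw=eccentricity_raw,
        eccentricity=eccentricity_raw / (n - 1),
        roi_labels=list(tree.roi_labels),
    )


def global_metrics(tree: SpanningTree, local: MstLocalMetrics | None = None) -> MstGlobalMetrics:
    """The six whole-tree descriptors.

    ``degree_correlation`` is reported as NaN for n < 3 (no interior node to
    correlate against).
    """
    if local is None:
        local = local_metrics(tree)
    n = tree.n_nodes
    degree_raw = local.degree_raw
    n_leaf = int((degree_raw == 1).sum())
    bc_max = float(local.betweenness_raw.max())
    if bc_max == 0:  # only possible for n = 2
        tree_hierarchy = float("nan")
    else:
        tree_hierarchy = n_leaf / (2 * (n - 1) * bc_max)
    kappa = float((degree_raw**2).mean() / degree_raw.mean())
    return MstGlobalMetrics(
        diameter=float(local.eccentricity.max()),
        radius=float(local.eccentricity.min()),
        leaf_fraction=n_leaf / (n - 1),
        tree_hierarchy=tree_hierarchy,
        kappa=kappa,
        degree_correlation=degree_assortativity(tree),
    )


def degree_assortativity(tree: SpanningTree) -> float:
    """Pearson correlation of endpoint degrees over both edge orientations.

    Matches the standard assortativity convention; a star evaluates to -1.
    NaN when fewer than 3 nodes or when either marginal is constant.
    """
    if tree.n_nodes < 3:
        return float("nan")
    deg = tree.degrees()
    x, y = [], []
    for i, j, _ in tree.edges:
        x.extend((deg[i], deg[j]))
        y.extend((deg[j], deg[i]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _max_normalise(values: np.ndarray) -> np.ndarray:
    peak = values.max()
    if peak == 0:
        return np.zeros_like(values)
    return values / peak
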