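import numpy as np
import pytest

from cerenet import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_weighted_graph(rng, n, density=0.8, ensure_connected=True):
    """Random symmetric weight matrix with weights in (0, 1)."""
    while True:
        weights = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    weights[i, j] = weights[j, i] = rng.uniform(0.05, 0.99)
        if not ensure_connected:
            return weights
        # connectivity check by reachability
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(weights[u] > 0):
                if v not in seen:
                    seen.add(int(v))
                    stack.append(int(v))
        if len(seen) == n:
            return weights


def random_tree_edges(rng, n):
    """Uniform random labelled tree via a random attachment process."""
    nodes = list(rng.permutation(n))
    edges = []
    for idx in range(1, n):
        parent = nodes[rng.integers(0, idx)]
        edges.append((int(min(parent, nodes[idx])), int(max(parent, nodes[idx])),
                      float(rng.uniform(0.1, 0.9))))
    return edges


def as_connectivity(weights, labels=None):
    n = weights.shape[0]
    labels = labels or [f"ROI{i:02d}" for i in range(n)]
    return ConnectivityMatrix(weights, labels)
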