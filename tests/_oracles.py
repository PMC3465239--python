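"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (O(n^3) triple scans, explicit
Pearson correlations over edge-end lists) and shares no code with the
package.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def triangles_brute(g: nx.Graph) -> int:
    """O(n^3) triple scan."""
    nodes = list(g.nodes)
    count = 0
    for a, b, c in itertools.combinations(nodes, 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            count += 1
    return count


def node_clustering_brute(g: nx.Graph, v) -> float:
    """2N / (k(k-1)) with N counted by enumerating neighbour pairs."""
    nbrs = list(g[v])
    k = len(nbrs)
    assert k >= 2
    n_links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
    return 2.0 * n_links / (k * (k - 1))


def assortativity_brute(g: nx.Graph) -> float:
    """Pearson correlation over the explicit edge-endpoint degree list."""
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges:
        xs.extend([deg[u], deg[v]])
        ys.extend([deg[v], deg[u]])
    return float(np.corrcoef(xs, ys)[0, 1])


def joint_degree_tally_brute(g: nx.Graph) -> dict[tuple[int, int], int]:
    """Unordered degree-pair -> edge count."""
    deg = dict(g.degree())
    tally: dict[tuple[int, int], int] = {}
    for u, v in g.edges:
        key = tuple(sorted((deg[u], deg[v])))
        tally[key] = tally.get(key, 0) + 1
    return tally


def random_test_graphs(n_cases: int, max_nodes: int = 60, seed: int = 0):
    """Assorted small random graphs: G(n,p), trees, stars, unions of cliques."""
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_cases):
        kind = i % 4
        n = int(rng.integers(5, max_nodes + 1))
        if kind == 0:
            g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.5)), seed=int(rng.integers(2**31)))
        elif kind == 1:
            g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        elif kind == 2:
            g = nx.star_graph(n - 1)
        else:
            g = nx.disjoint_union(
                nx.complete_graph(int(rng.integers(3, 8))),
                nx.gnp_random_graph(n // 2, 0.3, seed=int(rng.integers(2**31))),
            )
        graphs.append(nx.relabel_nodes(g, {v: f"n{v}" for v in g.nodes}))
    return graphs
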