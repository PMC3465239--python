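"""Generative network models.

Four constructions:

* the deterministic hierarchical model -- a recursive 5-clique design
  whose C(k) falls off as 1/k and which is often taken as the archetype
  of hierarchical modularity;
* scale-free configuration-model graphs realizing a discrete power-law
  degree sequence P(k) ~ k^-gamma by stub matching;
* preferential-attachment injection of "super-hubs", nodes whose degree
  far exceeds the power-law structural cutoff;
* a heuristic spoke model in which hubs connect only to low-degree
  leaves and are joined indirectly through shared bridge nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PowerLawSpec",
    "configuration_graph",
    "hierarchical_model",
    "inject_superhubs",
    "sample_powerlaw_degrees",
    "spoke_graph",
    "structural_cutoff",
]

_MAX_LEVELS = 7  # 5^7 = 78,125 nodes; guard against accidental blow-up


# ---------------------------------------------------------------------------
# Deterministic hierarchical model
# ---------------------------------------------------------------------------

def hierarchical_model(levels: int) -> nx.Graph:
    """Recursive 5-clique hierarchical network with 5**levels nodes.

    Level 1 is a 5-clique: one central node and four peripheral ones.
    At each later level four replicas of the current module are created
    and every replica's bottom-level peripheral nodes (4**(level-1) per
    replica) are wired to the central node of the original module.

    Node ids are stringified integers; the root center is ``"0"``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels > _MAX_LEVELS:
        raise ValueError(f"levels > {_MAX_LEVELS} rejected (5^{levels} nodes)")
    g = nx.complete_graph(5)
    center = 0
    periph = [1, 2, 3, 4]
    for _ in range(2, levels + 1):
        n = g.number_of_nodes()
        new_g = nx.Graph()
        new_g.add_edges_from(g.edges)
        new_periph = []
        for copy in range(1, 5):
            off = copy * n
            new_g.add_edges_from((u + off, v + off) for u, v in g.edges)
            for p in periph:
                new_g.add_edge(p + off, center)
                new_periph.append(p + off)
        g, periph = new_g, new_periph
    return nx.relabel_nodes(g, {v: str(v) for v in g.nodes})


# ---------------------------------------------------------------------------
# Power-law degree sequences and configuration graphs
# ---------------------------------------------------------------------------

def structural_cutoff(n: int, kmin: int = 1) -> int:
    """Structural degree cutoff sqrt(n * kmin).

    Keeping all degrees below this bound makes a configuration-model
    graph essentially uncorrelated (no entropic disassortativity from
    the simple-graph constraint).  Injected super-hubs deliberately
    violate it.
    """
    return int(math.isqrt(n * kmin))


@dataclass(frozen=True)
class PowerLawSpec:
    """Parameters of a discrete power-law degree distribution P(k) ~ k^-gamma.

    ``kmax`` defaults to the structural cutoff sqrt(n * kmin) so the
    baseline configuration graph is uncorrelated.
    """

    n: int
    gamma: float
    kmin: int = 1
    kmax: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.gamma <= 1:
            raise ValueError("gamma must exceed 1")
        kmax = self.resolved_kmax
        if not (1 <= self.kmin <= kmax <= self.n - 1):
            raise ValueError(
                f"need 1 <= kmin ({self.kmin}) <= kmax ({kmax}) <= n-1 ({self.n - 1})"
            )

    @property
    def resolved_kmax(self) -> int:
        return self.kmax if self.kmax is not None else structural_cutoff(self.n, self.kmin)


def sample_powerlaw_degrees(spec: PowerLawSpec) -> np.ndarray:
    """Draw n degrees from normalized P(k) ~ k^-gamma on [kmin, kmax].

    One entry is resampled until the total degree is even (a stub-
    matching requirement).
    """
    rng = np.random.default_rng(spec.seed)
    ks = np.arange(spec.kmin, spec.resolved_kmax + 1)
    p = ks.astype(float) ** (-spec.gamma)
    p /= p.sum()
    degrees = rng.choice(ks, size=spec.n, p=p)
    while degrees.sum() % 2:
        degrees[rng.integers(spec.n)] = rng.choice(ks, p=p)
    return degrees


def configuration_graph(degrees, seed: int) -> nx.Graph:
    """Simple configuration-model graph from a degree sequence.

    Stub matching with rejection: stubs are shuffled and paired; pairs
    that would create a self-loop or a duplicate edge are set aside and
    re-shuffled in further rounds.  Stubs still unmatched after the
    retry budget are dropped with a warning, so the realized degree of
    all but a vanishing fraction of nodes equals the request.

    Node ids are ``"v0" ... "v{n-1}"`` with ``degrees[i]`` the request
    for ``"v{i}"``.
    """
    degrees = np.asarray(degrees, dtype=int)
    if degrees.sum() % 2:
        raise ValueError("degree sum must be even")
    if (degrees < 0).any():
        raise ValueError("degrees must be non-negative")
    n = len(degrees)
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"v{i}" for i in range(n))
    stubs = np.repeat(np.arange(n), degrees)
    max_rounds = 200
    for _ in range(max_rounds):
        if len(stubs) < 2:
            break
        rng.shuffle(stubs)
        leftover = []
        it = iter(stubs.tolist())
        for u, v in zip(it, it):
            if u == v or g.has_edge(f"v{u}", f"v{v}"):
                leftover.extend((u, v))
            else:
                g.add_edge(f"v{u}", f"v{v}")
        if len(stubs) % 2:
            leftover.append(int(stubs[-1]))
        stubs = np.array(leftover, dtype=int)
    if len(stubs):
        logger.warning("configuration_graph: dropped %d unmatchable stub(s)", len(stubs))
    return g


# ---------------------------------------------------------------------------
# Super-hub injection
# ---------------------------------------------------------------------------

def inject_superhubs(
    g: nx.Graph, hub_degrees, seed: int
) -> tuple[nx.Graph, list[str]]:
    """Add one new node per requested degree by preferential attachment.

    Each new node ``"hub{i}"`` is wired to ``hub_degrees[i]`` distinct
    existing nodes sampled *without replacement* with probability
    proportional to their degree in the input graph.  Attachment
    weights are frozen at the pre-injection degrees; nodes injected
    earlier are visible as candidates for later ones but carry zero
    weight, so hubs never attach to each other.

    Returns the new graph and the list of injected node ids.
    """
    rng = np.random.default_rng(seed)
    h = g.copy()
    nodes = list(g.nodes)
    weights = np.array([g.degree(v) for v in nodes], dtype=float)
    injected: list[str] = []
    for i, d in enumerate(hub_degrees):
        if d > len(nodes):
            raise ValueError(f"hub degree {d} exceeds candidate count {len(nodes)}")
        if d <= 0:
            raise ValueError("hub degrees must be positive")
        # weighted sampling without replacement via exponential races:
        # the d smallest Exp(w) arrival times select nodes with the same
        # law as sequential draws proportional to w.
        keys = rng.exponential(1.0, len(nodes)) / np.maximum(weights, 1e-300)
        chosen = np.argpartition(keys, d - 1)[:d]
        hub = f"hub{i}"
        h.add_edges_from((hub, nodes[j]) for j in chosen)
        injected.append(hub)
        nodes.append(hub)
        weights = np.append(weights, 0.0)
    return h, injected


# ---------------------------------------------------------------------------
# Spoke model
# ---------------------------------------------------------------------------

def spoke_graph(
    n_hubs: int, leaves_per_hub: int, n_bridges: int, seed: int
) -> nx.Graph:
    """Heuristic spoke-model graph: hubs wired only to leaves and bridges.

    Every hub ``"s{i}"`` gets its own set of degree-1 leaves; bridge
    nodes each connect two distinct random hubs, joining the spokes
    indirectly.  No edge ever joins two hubs, so the graph is
    disassortative by construction.
    """
    if n_hubs <= 0 or leaves_per_hub <= 0 or n_bridges < 0:
        raise ValueError("n_hubs and leaves_per_hub must be positive, n_bridges >= 0")
    if n_bridges > 0 and n_hubs < 2:
        raise ValueError("bridges need at least 2 hubs")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    hubs = [f"s{i}" for i in range(n_hubs)]
    g.add_nodes_from(hubs)
    for i, hub in enumerate(hubs):
        for j in range(leaves_per_hub):
            g.add_edge(hub, f"leaf{i}_{j}")
    for b in range(n_bridges):
        h1, h2 = rng.choice(n_hubs, size=2, replace=False)
        g.add_edge(f"bridge{b}", hubs[h1])
        g.add_edge(f"bridge{b}", hubs[h2])
    return g
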