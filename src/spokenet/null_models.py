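"""Randomized null models at three levels of constraint.

* :func:`rewire_degree_preserving` fixes every node's degree
  (double-edge swaps);
* :func:`joint_degree_seed` additionally fixes the full joint degree
  matrix -- the number of edges between every pair of degree classes --
  and therefore the assortativity coefficient exactly;
* :func:`anneal_to_triangle_count` further drives the triangle count of
  a joint-degree-preserving random graph to that of a reference graph
  by Metropolis simulated annealing, producing a null that matches
  degree sequence, degree-degree correlations *and* the global level of
  modularity (triangle density);
* :func:`overlapping_null` is the stringent variant that freezes a
  fraction of the original edges in place and randomizes the rest.

All operations are seeded and return new graphs; inputs are never
mutated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from spokenet.graph_core import count_triangles

logger = logging.getLogger(__name__)

__all__ = [
    "AnnealSchedule",
    "AnnealState",
    "anneal_to_triangle_count",
    "joint_degree_dict",
    "joint_degree_seed",
    "metropolis_accept",
    "overlapping_null",
    "rewire_degree_preserving",
]


# ---------------------------------------------------------------------------
# Degree-preserving rewiring
# ---------------------------------------------------------------------------

def rewire_degree_preserving(g: nx.Graph, n_swaps: int, seed: int) -> nx.Graph:
    """Randomize a graph by double-edge swaps, preserving all degrees.

    Performs ``n_swaps`` successful swaps ((a,b),(c,d) -> (a,d),(c,b));
    proposals creating self-loops or duplicate edges are rejected and
    retried.  If no valid swap can be found within the retry budget
    (e.g. a lone triangle) the input is returned unchanged with a
    warning.
    """
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    h = g.copy()
    if n_swaps <= 0:
        return h
    try:
        nx.double_edge_swap(h, nswap=n_swaps, max_tries=100 * n_swaps + 100, seed=seed)
    except nx.NetworkXError as exc:  # too few nodes/edges or budget exhausted
        logger.warning("rewire_degree_preserving: %s; returning input unchanged", exc)
        return g.copy()
    return h


# ---------------------------------------------------------------------------
# Joint-degree-preserving seed networks
# ---------------------------------------------------------------------------

def joint_degree_dict(g: nx.Graph) -> dict[int, dict[int, int]]:
    """Joint degree matrix as nested dict of directed edge-end counts.

    ``jd[k][l]`` counts ordered endpoint pairs, so each k-l edge
    contributes to both ``jd[k][l]`` and ``jd[l][k]`` and the diagonal
    is twice the number of k-k edges.
    """
    return {
        k: {l: int(v) for l, v in row.items()}
        for k, row in nx.degree_mixing_dict(g).items()
    }


def joint_degree_seed(g: nx.Graph, seed: int) -> nx.Graph:
    """Random simple graph with exactly the joint degree matrix of ``g``.

    Because assortativity is a function of the joint degree matrix
    alone, the seed network reproduces r exactly while being otherwise
    random.  Isolated nodes of the input are carried over so node and
    edge counts match.

    Node ids are ``"v0" ...``; there is no correspondence with the
    input's node ids beyond degree class.
    """
    jd = joint_degree_dict(g)
    if not nx.is_valid_joint_degree(jd):
        raise ValueError("joint degree matrix of input is not realizable (not simple?)")
    h = nx.joint_degree_graph(jd, seed=seed)
    n_isolated = sum(1 for v in g.nodes if g.degree(v) == 0)
    h = nx.relabel_nodes(h, {v: f"v{v}" for v in h.nodes})
    for i in range(n_isolated):
        h.add_node(f"iso{i}")
    if h.number_of_nodes() != g.number_of_nodes() or h.number_of_edges() != g.number_of_edges():
        raise RuntimeError("joint degree seed failed to preserve graph size")
    return h


# ---------------------------------------------------------------------------
# Simulated annealing to a target triangle count
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealSchedule:
    """Annealing schedule and stopping rules.

    Parameters
    ----------
    temperature
        Initial effective temperature T of the Metropolis rule.
    cooling
        Geometric cooling factor applied every ``cool_every`` steps
        (1.0 keeps T fixed).
    cool_every
        Steps between cooling events.
    max_steps
        Hard cap on Monte-Carlo steps.
    tolerance
        Stop once the energy E = |N_random - N_real| / N_real falls to
        or below this value.
    window
        Stationarity window W: the run also stops when the mean energy
        over the last W steps changes by less than ``stationarity_rtol``
        relative to the previous window.
    """

    temperature: float = 0.05
    cooling: float = 0.995
    cool_every: int = 1000
    max_steps: int = 2_000_000
    tolerance: float = 0.05
    window: int = 10_000
    stationarity_rtol: float = 1e-3

    def __post_init__(self):
        if self.temperature <= 0 or not (0 < self.cooling <= 1):
            raise ValueError("temperature must be > 0 and cooling in (0, 1]")
        if min(self.max_steps, self.cool_every, self.window) <= 0:
            raise ValueError("step counts must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class AnnealState:
    """Result of an annealing run."""

    graph: nx.Graph
    energy: float
    n_triangles: int
    n_target: int
    steps: int
    accepted: int
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    stopped_by: str = "max_steps"

    def trajectory_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tenergy\n")
            for step, e in self.trajectory:
                fh.write(f"{step}\t{e:.6g}\n")


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Metropolis rule: accept with probability min(exp(-dE/T), 1)."""
    if delta_e <= 0:
        return True
    return bool(rng.random() < math.exp(-delta_e / temperature))


def anneal_to_triangle_count(
    g_real: nx.Graph,
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    check_every: int = 1000,
) -> AnnealState:
    """Joint-degree-preserving null annealed to the triangle count of ``g_real``.

    Starts from :func:`joint_degree_seed`.  Each Monte-Carlo step
    proposes a swap of two edges that share an endpoint degree class
    ((a,b),(c,d) with deg(a)=deg(c) -> (a,d),(c,b)) -- the minimal move
    that preserves the joint degree matrix -- and accepts it with
    probability min(exp(-dE/T), 1), where

        E = |N_random - N_real| / N_real

    and N is a triangle count.  Proposals are drawn symmetrically:
    a uniform random edge with random orientation fixes (a, b), a
    uniform node of the same degree class as ``a`` fixes ``c``, and a
    uniform neighbour of ``c`` fixes ``d``.

    The joint degree matrix is re-verified against the seed every
    ``check_every`` steps.

    Raises
    ------
    ValueError
        If the reference graph has no triangles (energy undefined).
    """
    if schedule is None:
        schedule = AnnealSchedule()
    n_real = count_triangles(g_real)
    if n_real == 0:
        raise ValueError("reference graph has no triangles; energy undefined")
    if g_real.number_of_edges() < 2:
        raise ValueError("need at least 2 edges")
    rng = np.random.default_rng(seed)
    h = joint_degree_seed(g_real, seed=int(rng.integers(2**31)))

    adj: dict = {v: set(h[v]) for v in h.nodes}
    deg = {v: len(adj[v]) for v in adj}
    classes: dict[int, list] = {}
    for v in adj:
        classes.setdefault(deg[v], []).append(v)
    edges = [tuple(e) for e in h.edges]
    eindex = {frozenset(e): i for i, e in enumerate(edges)}
    jd_ref = joint_degree_dict(h)

    n_cur = count_triangles(h)
    energy = abs(n_cur - n_real) / n_real
    temp = schedule.temperature
    trajectory: list[tuple[int, float]] = [(0, energy)]
    accepted = 0
    stopped_by = "max_steps"
    win_sum = 0.0
    prev_win_mean: float | None = None
    n_edges = len(edges)

    step = 0
    for step in range(1, schedule.max_steps + 1):
        if energy <= schedule.tolerance:
            stopped_by = "tolerance"
            break
        a, b = edges[int(rng.integers(n_edges))]
        if rng.random() < 0.5:
            a, b = b, a
        cls = classes[deg[a]]
        c = cls[int(rng.integers(len(cls)))]
        proposal_ok = False
        if c != a and c != b:
            nbrs = adj[c]
            d = _nth_member(nbrs, int(rng.integers(len(nbrs))))
            if d != a and d != b and d not in adj[a] and b not in adj[c]:
                proposal_ok = True
        if proposal_ok:
            # sequential local triangle delta
            d_tri = -len(adj[a] & adj[b])
            adj[a].discard(b); adj[b].discard(a)
            d_tri -= len(adj[c] & adj[d])
            adj[c].discard(d); adj[d].discard(c)
            d_tri += len(adj[a] & adj[d])
            adj[a].add(d); adj[d].add(a)
            d_tri += len(adj[c] & adj[b])
            adj[c].add(b); adj[b].add(c)
            new_energy = abs(n_cur + d_tri - n_real) / n_real
            if metropolis_accept(new_energy - energy, temp, rng):
                n_cur += d_tri
                energy = new_energy
                accepted += 1
                i = eindex.pop(frozenset((a, b)))
                j = eindex.pop(frozenset((c, d)))
                edges[i] = (a, d)
                edges[j] = (c, b)
                eindex[frozenset((a, d))] = i
                eindex[frozenset((c, b))] = j
            else:  # revert
                adj[a].discard(d); adj[d].discard(a)
                adj[c].discard(b); adj[b].discard(c)
                adj[a].add(b); adj[b].add(a)
                adj[c].add(d); adj[d].add(c)
        win_sum += energy
        if step % schedule.cool_every == 0:
            temp *= schedule.cooling
        if step % check_every == 0:
            trajectory.append((step, energy))
            if _jd_from_adj(adj, deg) != jd_ref:
                raise RuntimeError(f"joint degree matrix violated at step {step}")
        if step % schedule.window == 0:
            win_mean = win_sum / schedule.window
            win_sum = 0.0
            # While T is still being lowered the energy often plateaus at the
            # hot-ensemble equilibrium; treat the chain as stationary only
            # once a one-triangle uphill move is accepted < 1% of the time
            # (or when T is held fixed, where the plateau IS the answer).
            frozen = schedule.cooling == 1.0 or temp <= 1.0 / (math.log(100.0) * n_real)
            if (
                frozen
                and prev_win_mean is not None
                and prev_win_mean > 0
                and abs(win_mean - prev_win_mean) / prev_win_mean < schedule.stationarity_rtol
            ):
                stopped_by = "stationary"
                break
            prev_win_mean = win_mean

    out = nx.Graph()
    out.add_nodes_from(adj)
    out.add_edges_from(edges)
    if joint_degree_dict(out) != jd_ref:
        raise RuntimeError("annealing violated the joint degree matrix")
    if count_triangles(out) != n_cur:
        raise RuntimeError("incremental triangle count drifted")
    trajectory.append((step, energy))
    logger.info(
        "anneal: N=%d target=%d E=%.4g after %d steps (%d accepted, %s)",
        n_cur, n_real, energy, step, accepted, stopped_by,
    )
    return AnnealState(
        graph=out,
        energy=energy,
        n_triangles=n_cur,
        n_target=n_real,
        steps=step,
        accepted=accepted,
        trajectory=trajectory,
        stopped_by=stopped_by,
    )


def _jd_from_adj(adj: dict, deg: dict) -> dict[int, dict[int, int]]:
    jd: dict[int, dict[int, int]] = {}
    for u, nbrs in adj.items():
        ku = deg[u]
        row = jd.setdefault(ku, {})
        for v in nbrs:
            kv = deg[v]
            row[kv] = row.get(kv, 0) + 1
    return jd


def _nth_member(s: set, n: int):
    for i, x in enumerate(s):
        if i == n:
            return x
    raise IndexError(n)


# ---------------------------------------------------------------------------
# Stringent overlapping null
# ---------------------------------------------------------------------------

def overlapping_null(
    g: nx.Graph, overlap_fraction: float, n_swaps: int, seed: int
) -> tuple[nx.Graph, float]:
    """Degree-preserving null sharing at least a fixed fraction of edges.

    A uniform random subset of ``ceil(overlap_fraction * M)`` edges is
    frozen; double-edge swaps are applied to the remaining edges only.
    Returns the null and the realized shared-edge fraction (>= the
    request, since non-frozen swaps can also recreate original edges).
    """
    if not (0 < overlap_fraction <= 1):
        raise ValueError("overlap_fraction must be in (0, 1]")
    m = g.number_of_edges()
    if overlap_fraction == 1.0:
        return g.copy(), 1.0
    rng = np.random.default_rng(seed)
    edges = sorted(tuple(sorted(e)) for e in g.edges)
    n_frozen = math.ceil(overlap_fraction * m)
    frozen_idx = set(rng.choice(m, size=n_frozen, replace=False).tolist())
    free = [e for i, e in enumerate(edges) if i not in frozen_idx]

    h = g.copy()
    swaps = tries = 0
    max_tries = 100 * n_swaps + 100
    n_free = len(free)
    while swaps < n_swaps and tries < max_tries and n_free >= 2:
        tries += 1
        i, j = rng.integers(n_free), rng.integers(n_free)
        if i == j:
            continue
        a, b = free[i]
        c, d = free[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        free[i] = (a, d)
        free[j] = (c, b)
        swaps += 1
    if swaps < n_swaps:
        logger.warning("overlapping_null: only %d/%d swaps achieved", swaps, n_swaps)
    shared = sum(1 for e in edges if h.has_edge(*e))
    return h, shared / m
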