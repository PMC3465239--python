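"""Synthetic fixtures emulating the statistical structure of real data.

Four generators, all deterministic given their seed:

* :func:`synth_metabolic_like` -- a power-law configuration graph plus
  a few preferentially attached super-hubs, mimicking metabolic
  networks where currency metabolites (ATP, H2O, ...) sit far above
  the power-law cutoff;
* :func:`synth_disassortative` -- a configuration graph pushed toward a
  target assortativity by greedy degree-preserving swaps, mimicking the
  hub repulsion of protein-interaction and synthetic-lethal networks
  (positive targets give hub-affine, co-expression-like graphs);
* :func:`synth_modular` -- a planted-partition graph whose triangle
  count far exceeds any degree-matched null, mimicking the high
  modularity of biological networks;
* :func:`synth_expression` -- a block-correlated expression matrix with
  missing entries, mimicking module-structured microarray data.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np

from spokenet.generators import (
    PowerLawSpec,
    configuration_graph,
    inject_superhubs,
    sample_powerlaw_degrees,
)

logger = logging.getLogger(__name__)

__all__ = [
    "synth_disassortative",
    "synth_expression",
    "synth_metabolic_like",
    "synth_modular",
]


def synth_metabolic_like(
    n: int = 10_000,
    gamma: float = 2.6,
    superhub_degrees=(2000, 2000),
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Power-law graph with injected super-hubs; returns (graph, hub ids)."""
    rng = np.random.default_rng(seed)
    spec = PowerLawSpec(n=n, gamma=gamma, seed=int(rng.integers(2**31)))
    degrees = sample_powerlaw_degrees(spec)
    g = configuration_graph(degrees, seed=int(rng.integers(2**31)))
    if not superhub_degrees:
        return g, []
    return inject_superhubs(g, list(superhub_degrees), seed=int(rng.integers(2**31)))


def synth_disassortative(
    n: int,
    gamma: float,
    target_r: float,
    seed: int,
    tol: float = 0.02,
    max_swaps: int = 2_000_000,
) -> nx.Graph:
    """Configuration graph steered to a target assortativity r.

    Starts from an uncorrelated power-law configuration graph and
    applies greedy double-edge swaps, accepting a swap only when it
    moves r toward ``target_r``; stops within ``tol`` of the target or
    at the swap-proposal budget.  The degree sequence is untouched.

    r depends on the edge set only through sum(k_u k_v) over edges, so
    the greedy score is updated in O(1) per proposal.
    """
    rng = np.random.default_rng(seed)
    spec = PowerLawSpec(n=n, gamma=gamma, seed=int(rng.integers(2**31)))
    degrees = sample_powerlaw_degrees(spec)
    g = configuration_graph(degrees, seed=int(rng.integers(2**31)))

    deg = dict(g.degree())
    stubs = np.array([k for k in deg.values() for _ in range(k)], dtype=float)
    mu = stubs.mean()
    var = stubs.var()
    if var == 0:
        raise ValueError("regular degree sequence: r undefined")
    m = g.number_of_edges()
    edges = [tuple(e) for e in g.edges]
    cross = sum(deg[u] * deg[v] for u, v in edges)

    def r_of(cross_sum: float) -> float:
        return (cross_sum / m - mu**2) / var

    for _ in range(max_swaps):
        if abs(r_of(cross) - target_r) <= tol:
            break
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4 or g.has_edge(a, d) or g.has_edge(c, b):
            continue
        delta = (deg[a] * deg[d] + deg[c] * deg[b]) - (deg[a] * deg[b] + deg[c] * deg[d])
        if abs(r_of(cross + delta) - target_r) >= abs(r_of(cross) - target_r):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        cross += delta
    else:
        logger.warning(
            "synth_disassortative: swap budget exhausted at r=%.4f (target %.4f)",
            r_of(cross), target_r,
        )
    return g


def synth_modular(
    n_modules: int = 5,
    module_size: int = 100,
    p_in: float = 0.12,
    p_out: float = 0.01,
    seed: int = 0,
) -> nx.Graph:
    """Planted-partition graph: dense blocks, sparse between-block edges.

    With the defaults the graph has far more triangles than any
    degree-preserving randomization, emulating the excess modularity of
    biological networks that the annealing null is designed to match.
    """
    g = nx.planted_partition_graph(n_modules, module_size, p_in, p_out, seed=seed)
    return nx.relabel_nodes(g, {v: f"m{v}" for v in g.nodes})


def synth_expression(
    n_genes: int = 300,
    n_arrays: int = 30,
    n_modules: int = 3,
    rho_in: float = 0.9,
    missing_rate: float = 0.05,
    seed: int = 0,
):
    """Block-correlated expression matrix with missing entries.

    Genes are split into ``n_modules`` contiguous equal blocks; each
    gene's profile is sqrt(rho) * module factor + sqrt(1-rho) * noise,
    giving within-module pairwise correlation ``rho_in`` and zero
    between modules.  Entries are masked missing independently at
    ``missing_rate``.  Returns an :class:`ExpressionMatrix` whose gene
    ids encode the module (``g<module>_<i>``).
    """
    from spokenet.coexpression import ExpressionMatrix
    import pandas as pd

    if not (0 <= rho_in < 1):
        raise ValueError("rho_in must lie in [0, 1)")
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_modules, n_arrays))
    per_module = n_genes // n_modules
    rows, ids = [], []
    for gi in range(n_genes):
        mod = min(gi // max(per_module, 1), n_modules - 1)
        noise = rng.standard_normal(n_arrays)
        rows.append(np.sqrt(rho_in) * factors[mod] + np.sqrt(1.0 - rho_in) * noise)
        ids.append(f"g{mod}_{gi}")
    values = np.array(rows)
    mask = rng.random(values.shape) < missing_rate
    values[mask] = np.nan
    df = pd.DataFrame(values, index=ids, columns=[f"a{j}" for j in range(n_arrays)])
    return ExpressionMatrix(df)
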