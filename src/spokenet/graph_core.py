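"""Graph I/O and the basic per-node / per-degree statistics.

Graphs are plain :class:`networkx.Graph` objects with string node ids,
no self-loops and no parallel edges.  Every function in the package
assumes (and the readers here enforce) that convention.

The central quantity is the degree-resolved clustering coefficient

    C(k) = mean over nodes of degree k of  2 N_v / (k (k - 1)),

where ``N_v`` is the number of edges among the neighbours of ``v``
(equivalently the number of triangles through ``v``).  Nodes of degree
0 or 1 have no defined clustering coefficient and are excluded from all
clustering statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CkSpectrum",
    "DegreeHistogram",
    "assortativity",
    "ck_spectrum",
    "count_triangles",
    "degree_histogram",
    "mean_clustering",
    "node_clustering",
    "read_edgelist",
    "write_edgelist",
]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edgelist(path: str | Path, format: str = "tsv") -> nx.Graph:
    """Read an undirected simple graph from an edge-list TSV or GraphML file.

    TSV lines hold at least two whitespace-separated columns (extra
    columns ignored); lines starting with ``#`` and blank lines are
    skipped.  Self-loops are dropped and duplicate edges collapsed, each
    with a logged warning.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` (default) or ``"graphml"``.

    Raises
    ------
    ValueError
        If the file yields an empty graph or a line has fewer than two
        columns.
    """
    path = Path(path)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.Graph()
        g.add_nodes_from(str(v) for v in raw.nodes)
        pairs: Iterable[tuple[str, str]] = ((str(u), str(v)) for u, v in raw.edges())
    elif format == "tsv":
        g = nx.Graph()
        pairs = _iter_tsv_pairs(path)
    else:
        raise ValueError(f"unknown edge-list format: {format!r}")

    n_loops = n_dups = 0
    for u, v in pairs:
        if u == v:
            n_loops += 1
            logger.warning("dropping self-loop %s-%s in %s", u, v, path)
            continue
        if g.has_edge(u, v):
            n_dups += 1
            logger.warning("collapsing duplicate edge %s-%s in %s", u, v, path)
            continue
        g.add_edge(u, v)
    if n_loops or n_dups:
        logger.warning(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            path, n_loops, n_dups,
        )
    if g.number_of_nodes() == 0:
        raise ValueError(f"empty graph read from {path}")
    return g


def _iter_tsv_pairs(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(cols)}")
            yield cols[0], cols[1]


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Write a graph as a two-column TSV, edges sorted lexicographically."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# spokenet edge list\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\n")
        # isolated nodes are not representable in a pure edge list; note them
        isolated = sorted(v for v in g.nodes if g.degree(v) == 0)
        for v in isolated:
            fh.write(f"# isolated\t{v}\n")


# ---------------------------------------------------------------------------
# Basic statistics
# ---------------------------------------------------------------------------

def node_clustering(g: nx.Graph, v) -> float:
    """Clustering coefficient 2N/(k(k-1)) of one node of degree >= 2.

    ``N`` is the number of edges among the neighbours of ``v``.

    Raises
    ------
    ValueError
        If ``degree(v) < 2`` (the quantity is undefined; callers must
        exclude such nodes).
    """
    k = g.degree(v)
    if k < 2:
        raise ValueError(f"clustering undefined for node {v!r} of degree {k}")
    n_tri = nx.triangles(g, v)
    return 2.0 * n_tri / (k * (k - 1))


def count_triangles(g: nx.Graph) -> int:
    """Total number of distinct triangles in the graph."""
    return sum(nx.triangles(g).values()) // 3


def mean_clustering(g: nx.Graph) -> float:
    """Mean clustering coefficient over nodes of degree >= 2."""
    vals = [node_clustering(g, v) for v in g.nodes if g.degree(v) >= 2]
    if not vals:
        raise ValueError("no node of degree >= 2")
    return float(np.mean(vals))


def assortativity(g: nx.Graph) -> float:
    """Degree-mixing Pearson coefficient r over edges (both orientations).

    ``r`` is the Pearson correlation of the degrees found at the two
    ends of an edge, with each edge contributing both orientations; it
    lies in [-1, 1], and is negative when hubs avoid each other
    (disassortative mixing).

    Raises
    ------
    ValueError
        On fewer than 2 edges or when the endpoint-degree variance is
        zero (e.g. a regular graph), where r is undefined.
    """
    if g.number_of_edges() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    degs = dict(g.degree())
    ends = np.array([(degs[u], degs[v]) for u, v in g.edges], dtype=float)
    x = np.concatenate([ends[:, 0], ends[:, 1]])
    if np.ptp(x) == 0:
        raise ValueError("assortativity undefined: all endpoint degrees equal")
    r = nx.degree_pearson_correlation_coefficient(g)
    return float(r)


# ---------------------------------------------------------------------------
# Spectra / histograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CkSpectrum:
    """Per-degree mean clustering coefficient with node counts.

    ``entries`` maps degree ``k >= 2`` to ``(mean C, number of nodes of
    that degree)``.
    """

    entries: Mapping[int, tuple[float, int]]

    def __post_init__(self):
        for k, (c, n) in self.entries.items():
            if k < 2:
                raise ValueError(f"degree {k} < 2 in CkSpectrum")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"mean clustering {c} outside [0, 1] at k={k}")
            if n <= 0:
                raise ValueError(f"non-positive node count at k={k}")

    @property
    def degrees(self) -> list[int]:
        return sorted(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, c, n) for k, (c, n) in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["k", "mean_clustering", "n_nodes"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def log_binned(self, base: float = 2.0) -> pd.DataFrame:
        """Presentation-layer log binning: node-weighted means per bin.

        Returns a frame with geometric-mean degree, weighted mean C and
        node count per non-empty bin.  The unbinned spectrum remains the
        canonical result.
        """
        rows = []
        lo = 2
        kmax = max(self.entries, default=2)
        while lo <= kmax:
            hi = max(int(lo * base), lo + 1)
            ks = [k for k in self.entries if lo <= k < hi]
            if ks:
                ns = np.array([self.entries[k][1] for k in ks], dtype=float)
                cs = np.array([self.entries[k][0] for k in ks])
                logk = np.array([math.log(k) for k in ks])
                rows.append((
                    math.exp(float(np.average(logk, weights=ns))),
                    float(np.average(cs, weights=ns)),
                    int(ns.sum()),
                ))
            lo = hi
        return pd.DataFrame(rows, columns=["k", "mean_clustering", "n_nodes"])


def ck_spectrum(g: nx.Graph) -> CkSpectrum:
    """C(k) spectrum: mean node clustering per exact degree k >= 2."""
    by_k: dict[int, list[float]] = {}
    for v in g.nodes:
        k = g.degree(v)
        if k >= 2:
            by_k.setdefault(k, []).append(node_clustering(g, v))
    if not by_k:
        raise ValueError("no node of degree >= 2")
    return CkSpectrum({k: (float(np.mean(vals)), len(vals)) for k, vals in by_k.items()})


@dataclass(frozen=True)
class DegreeHistogram:
    """Degree -> node-count map with derived size statistics."""

    counts: Mapping[int, int]

    def __post_init__(self):
        for k, n in self.counts.items():
            if k < 0 or n <= 0:
                raise ValueError(f"invalid histogram entry k={k}, count={n}")

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())

    @property
    def n_edges(self) -> int:
        tot = sum(k * n for k, n in self.counts.items())
        return tot // 2

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["k", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def degree_histogram(g: nx.Graph) -> DegreeHistogram:
    """Degree histogram P(k) of a graph (unnormalized counts)."""
    counts: dict[int, int] = {}
    for _, k in g.degree():
        counts[k] = counts.get(k, 0) + 1
    return DegreeHistogram(counts)
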