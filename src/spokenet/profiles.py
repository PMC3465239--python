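"""Degree-correlation profiles, C(k) envelopes and super-hub detection.

The correlation profile compares the joint probability P(k_i, k_j) of
finding an edge between nodes of degrees k_i and k_j with the same
probability in an ensemble of degree-preserving randomizations, as a
ratio matrix P / <P_r> and a z-score matrix (P - <P_r>) / sigma_r.
A suppressed upper-right corner (hub-hub bins with ratio < 1) is the
signature of hub repulsion; enrichment there signals hub affinity.

Raw degree pairs are far too sparse in graphs of 10^3-10^4 nodes, so
profiles are computed on logarithmic degree bins (base 2 by default);
the bin edges are part of the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

from spokenet.graph_core import DegreeHistogram, ck_spectrum
from spokenet.null_models import rewire_degree_preserving

__all__ = [
    "CorrelationProfile",
    "JointDegreeMatrix",
    "ck_envelope",
    "correlation_profile",
    "detect_superhubs",
    "joint_degree_matrix",
    "log2_bin_edges",
]


# ---------------------------------------------------------------------------
# Joint degree matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointDegreeMatrix:
    """Symmetric edge-count matrix over degree (or degree-bin) pairs.

    ``counts[i, j]`` holds the number of edges whose endpoint degrees
    fall in classes i and j; off-diagonal cells are mirrored, so the
    total edge count is the sum over the upper triangle including the
    diagonal (:meth:`total`).

    ``labels`` are the exact degrees when unbinned; with binning,
    ``bin_edges`` gives the half-open bin boundaries and ``labels`` the
    bin lower edges.
    """

    counts: np.ndarray
    labels: tuple[int, ...]
    bin_edges: tuple[int, ...] | None = None

    def __post_init__(self):
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if not np.allclose(c, c.T):
            raise ValueError("counts must be symmetric")

    def total(self) -> int:
        """Total number of edges represented (sum over unordered pairs)."""
        return int(np.triu(self.counts).sum())

    def normalized(self) -> np.ndarray:
        """Probability twin P(k_i, k_j): each cell holds its unordered-pair
        probability (mirrored off the diagonal), so the upper triangle
        including the diagonal sums to 1."""
        return self.counts / self.total()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def log2_bin_edges(kmax: int) -> tuple[int, ...]:
    """Half-open log-2 degree bin edges 1, 2, 4, ... covering up to kmax."""
    edges = [1]
    while edges[-1] <= kmax:
        edges.append(edges[-1] * 2)
    return tuple(edges)


def joint_degree_matrix(g: nx.Graph, bins: str | None = None) -> JointDegreeMatrix:
    """Edge-count matrix over endpoint-degree pairs.

    Each edge contributes once to its unordered degree pair (mirrored
    into both symmetric cells off the diagonal).

    Parameters
    ----------
    bins
        ``None`` for exact degrees, ``"log2"`` for logarithmic base-2
        degree bins.
    """
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    degs = dict(g.degree())
    if bins is None:
        labels = tuple(sorted({degs[v] for v in g.nodes if degs[v] > 0}))
        index = {k: i for i, k in enumerate(labels)}
        edges_def = None
    elif bins == "log2":
        kmax = max(degs.values())
        edges_def = log2_bin_edges(kmax)
        labels = edges_def[:-1]
        index = {}
    else:
        raise ValueError(f"unknown binning: {bins!r}")

    def class_of(k: int) -> int:
        if bins is None:
            return index[k]
        return int(math.floor(math.log2(k)))

    n = len(labels)
    counts = np.zeros((n, n), dtype=float)
    for u, v in g.edges:
        i, j = class_of(degs[u]), class_of(degs[v])
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
    return JointDegreeMatrix(counts=counts, labels=tuple(labels), bin_edges=edges_def)


# ---------------------------------------------------------------------------
# Correlation profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationProfile:
    """Ratio and z-score matrices of a graph against a rewired ensemble.

    Cells whose ensemble mean is zero are masked (NaN in ``ratio``,
    ``zscores``; False in ``mask``).
    """

    ratio: np.ndarray
    zscores: np.ndarray
    mask: np.ndarray
    null_mean: np.ndarray
    labels: tuple[int, ...]
    bin_edges: tuple[int, ...] | None
    ensemble_size: int

    def __post_init__(self):
        if self.ratio.shape != self.zscores.shape or self.ratio.shape != self.mask.shape:
            raise ValueError("matrices must share a shape")
        if self.ensemble_size < 2:
            raise ValueError("ensemble size must be >= 2")

    def hub_hub_ratio(self) -> float:
        """Ratio in the top diagonal (largest-degree-bin vs itself) cell.

        Falls back to the largest unmasked diagonal cell.
        """
        for i in range(len(self.labels) - 1, -1, -1):
            if self.mask[i, i]:
                return float(self.ratio[i, i])
        raise ValueError("no unmasked diagonal cell")

    def well_sampled(self, min_mean: float = 5.0) -> np.ndarray:
        """Cells whose ensemble mean edge count reaches ``min_mean``.

        Ratio and z statistics are only interpretable where the null
        expects a non-trivial number of edges; sparse bins fluctuate
        wildly for purely combinatorial reasons.
        """
        return self.mask & (self.null_mean >= min_mean)


def correlation_profile(
    g: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    bins: str | None = "log2",
    n_swaps: int | None = None,
) -> CorrelationProfile:
    """Correlation profile of ``g`` against degree-preserving rewirings.

    ``n_random`` rewired counterparts (default 100) are generated with
    ``n_swaps`` double-edge swaps each (default 10 M); the ratio matrix
    is P / <P_r> and the z matrix (P - <P_r>) / sigma_r over the chosen
    degree bins.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    real = joint_degree_matrix(g, bins=bins)
    rng = np.random.default_rng(seed)
    ens = np.empty((n_random,) + real.counts.shape)
    for i in range(n_random):
        null = rewire_degree_preserving(g, n_swaps, seed=int(rng.integers(2**31)))
        jm = joint_degree_matrix(null, bins=bins)
        if jm.counts.shape != real.counts.shape:  # degree set is preserved, shape must match
            raise RuntimeError("null joint degree matrix shape mismatch")
        ens[i] = jm.counts
    mean = ens.mean(axis=0)
    std = ens.std(axis=0, ddof=1)
    mask = mean > 0
    ratio = np.full(mean.shape, np.nan)
    z = np.full(mean.shape, np.nan)
    ratio[mask] = real.counts[mask] / mean[mask]
    pos = mask & (std > 0)
    z[pos] = (real.counts[pos] - mean[pos]) / std[pos]
    z[mask & (std == 0)] = 0.0
    return CorrelationProfile(
        ratio=ratio,
        zscores=z,
        mask=mask,
        null_mean=mean,
        labels=real.labels,
        bin_edges=real.bin_edges,
        ensemble_size=n_random,
    )


# ---------------------------------------------------------------------------
# Super-hub detection
# ---------------------------------------------------------------------------

def detect_superhubs(
    hist: DegreeHistogram,
    gamma_fit_range: tuple[int, int] | None = None,
    alpha: float = 0.05,
) -> list[int]:
    """Degrees in the histogram tail unexpected under the fitted power law.

    A discrete power law P(k) ~ k^-gamma is fitted by maximum
    likelihood to the bulk of the distribution (degrees within
    ``gamma_fit_range``, by default from max(kmin, 2) up to the
    structural cutoff sqrt(n * kmin); degree-1 counts are skipped by
    default because they are the most easily distorted part of any
    empirical degree distribution).  A degree ``k`` above the fit range
    is flagged when the expected number of nodes of degree >= k under
    the fitted law, ``n_{K >= lo} * P(K >= k | K >= lo)``, falls below
    ``alpha``.

    Returns the sorted list of flagged degrees.
    """
    counts = {k: c for k, c in hist.counts.items() if k > 0}
    if len(counts) < 10:
        raise ValueError("need at least 10 distinct degrees to fit a power law")
    kmin_obs = min(counts)
    if gamma_fit_range is None:
        cutoff = int(math.isqrt(hist.n_nodes * kmin_obs))
        lo = max(kmin_obs, 2)
        gamma_fit_range = (lo, max(cutoff, lo + 9))
    lo, hi = gamma_fit_range
    bulk = {k: c for k, c in counts.items() if lo <= k <= hi}
    if len(bulk) < 3:
        raise ValueError("fewer than 3 distinct degrees in the fit range")
    gamma_hat = _fit_truncated_zipf(bulk, lo, hi)

    # survival under the *untruncated* fitted law, conditioned on k >= lo
    n_support = sum(c for k, c in counts.items() if k >= lo)
    z_lo = special.zeta(gamma_hat, lo)
    flagged = []
    for k in sorted(counts):
        if k <= hi:
            continue
        expected = n_support * special.zeta(gamma_hat, k) / z_lo
        if expected < alpha:
            flagged.append(k)
    return flagged


def _fit_truncated_zipf(bulk: dict[int, int], lo: int, hi: int) -> float:
    """MLE of gamma for P(k) ~ k^-gamma truncated to [lo, hi]."""
    ks = np.arange(lo, hi + 1, dtype=float)
    obs_k = np.array(sorted(bulk))
    obs_c = np.array([bulk[k] for k in sorted(bulk)], dtype=float)
    sum_log = float((obs_c * np.log(obs_k)).sum())
    n_obs = obs_c.sum()

    def nll(gamma: float) -> float:
        log_z = special.logsumexp(-gamma * np.log(ks))
        return gamma * sum_log + n_obs * log_z

    res = optimize.minimize_scalar(nll, bounds=(1.05, 6.0), method="bounded")
    if not res.success:
        raise ValueError("power-law fit failed")
    return float(res.x)


# ---------------------------------------------------------------------------
# C(k) ensemble envelope
# ---------------------------------------------------------------------------

def ck_envelope(
    g: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    band: tuple[float, float] = (5.0, 95.0),
    n_swaps: int | None = None,
) -> pd.DataFrame:
    """C(k) of a graph with a degree-preserving null ensemble envelope.

    Returns a frame indexed by degree with the real per-degree mean
    clustering, the null ensemble mean, the ``band`` percentiles of the
    null per-degree means, and a flag for degrees where the real value
    exits the band.  Rewiring preserves degrees, so every degree in the
    real spectrum is present in each null.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    if n_swaps is None:
        n_swaps = 10 * g.number_of_edges()
    real = ck_spectrum(g)
    degrees = real.degrees
    rng = np.random.default_rng(seed)
    null_vals = np.empty((n_random, len(degrees)))
    for i in range(n_random):
        null = rewire_degree_preserving(g, n_swaps, seed=int(rng.integers(2**31)))
        spec = ck_spectrum(null)
        null_vals[i] = [spec.entries[k][0] for k in degrees]
    lo, hi = np.percentile(null_vals, band, axis=0)
    mean = null_vals.mean(axis=0)
    c_real = np.array([real.entries[k][0] for k in degrees])
    return pd.DataFrame(
        {
            "c_real": c_real,
            "null_mean": mean,
            "null_lo": lo,
            "null_hi": hi,
            "n_nodes": [real.entries[k][1] for k in degrees],
            "outside": (c_real < lo) | (c_real > hi),
        },
        index=pd.Index(degrees, name="k"),
    )
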