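"""Minimal plot helpers: C(k) curves, degree histograms, profile heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from spokenet.graph_core import CkSpectrum, DegreeHistogram
from spokenet.profiles import CorrelationProfile

__all__ = ["plot_ck", "plot_degree_histogram", "plot_profile"]


def plot_ck(spectra: dict[str, CkSpectrum], path=None, ax=None):
    """Log-log C(k) curves for one or more labelled spectra."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, spec in spectra.items():
        frame = spec.to_frame()
        ax.loglog(frame["k"], frame["mean_clustering"].where(frame["mean_clustering"] > 0),
                  "o", ms=4, alpha=0.7, label=label)
    ax.set_xlabel("degree k")
    ax.set_ylabel("C(k)")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_degree_histogram(hist: DegreeHistogram, path=None, ax=None):
    """Log-log degree distribution; super-hubs stand out as isolated tail points."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    frame = hist.to_frame()
    ax.loglog(frame["k"], frame["count"], "o", ms=4)
    ax.set_xlabel("degree k")
    ax.set_ylabel("node count")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_profile(profile: CorrelationProfile, path=None, ax=None, kind: str = "ratio"):
    """Heat map of the ratio (log2 color scale) or z-score matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.2))
    mat = profile.ratio if kind == "ratio" else profile.zscores
    if kind == "ratio":
        with np.errstate(divide="ignore"):
            shown = np.log2(mat)
        vmax = np.nanmax(np.abs(shown[np.isfinite(shown)])) if np.isfinite(shown).any() else 1
        im = ax.imshow(shown, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        label = "log2 P / <P_r>"
    else:
        vmax = np.nanmax(np.abs(mat)) if np.isfinite(mat).any() else 1
        im = ax.imshow(mat, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        label = "z score"
    ticks = range(len(profile.labels))
    ax.set_xticks(ticks, [str(l) for l in profile.labels], fontsize=7)
    ax.set_yticks(ticks, [str(l) for l in profile.labels], fontsize=7)
    ax.set_xlabel("degree bin (lower edge)")
    ax.set_ylabel("degree bin (lower edge)")
    ax.figure.colorbar(im, ax=ax, label=label)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
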