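"""Gene co-expression network construction.

An expression matrix (genes x arrays, missing entries allowed) is
cleaned in two deterministic passes -- arrays with too much missing
data first, then genes missing in too many arrays -- and a network is
built by connecting gene pairs whose pairwise-complete Pearson
correlation exceeds a threshold in absolute value (default |r| > 0.65,
strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FilterReport",
    "coexpression_network",
    "filter_expression",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x arrays matrix of real values with NaN marking missing entries."""

    values: pd.DataFrame  # index: gene ids, columns: array ids

    def __post_init__(self):
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and array ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column, arrays as header, NA missing."""
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df.astype(float))

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")


@dataclass(frozen=True)
class FilterReport:
    arrays_removed: tuple[str, ...]
    genes_removed: tuple[str, ...]

    @property
    def n_arrays_removed(self) -> int:
        return len(self.arrays_removed)

    @property
    def n_genes_removed(self) -> int:
        return len(self.genes_removed)


def filter_expression(
    m: ExpressionMatrix,
    max_array_missing_frac: float = 0.10,
    max_gene_missing_arrays: int = 7,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove low-quality arrays, then low-coverage genes.

    Arrays missing strictly more than ``max_array_missing_frac`` of
    their genes are dropped first; genes then missing in strictly more
    than ``max_gene_missing_arrays`` of the remaining arrays are
    dropped.  The order matters and the operation is idempotent on its
    own output.
    """
    df = m.values
    arr_frac = df.isna().mean(axis=0)
    bad_arrays = tuple(arr_frac.index[arr_frac > max_array_missing_frac])
    df = df.drop(columns=list(bad_arrays))
    gene_missing = df.isna().sum(axis=1)
    bad_genes = tuple(gene_missing.index[gene_missing > max_gene_missing_arrays])
    df = df.drop(index=list(bad_genes))
    if df.shape[0] == 0 or df.shape[1] < 3:
        raise ValueError("filtering removed too much: fewer than 1 gene or 3 arrays remain")
    return ExpressionMatrix(df), FilterReport(bad_arrays, bad_genes)


def coexpression_network(
    m: ExpressionMatrix,
    threshold: float = 0.65,
    min_shared_arrays: int = 3,
) -> nx.Graph:
    """Network with an edge for every gene pair with |Pearson r| > threshold.

    Correlations use pairwise-complete observations; pairs sharing
    fewer than ``min_shared_arrays`` non-missing arrays get no edge.
    The inequality is strict, and all genes appear as nodes whether or
    not they gain edges.
    """
    if m.n_genes < 2:
        raise ValueError("need at least 2 genes")
    corr = m.values.T.corr(method="pearson", min_periods=min_shared_arrays)
    genes = list(m.values.index)
    g = nx.Graph()
    g.add_nodes_from(genes)
    mat = corr.to_numpy()
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    vals = mat[iu, ju]
    hit = np.abs(vals) > threshold
    for i, j in zip(iu[hit], ju[hit]):
        g.add_edge(genes[i], genes[j])
    return g
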