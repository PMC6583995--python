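"""Count-matrix container, CPM/FPKM transforms, expression filtering and
sample clustering.

The pipeline starts from a gene x sample matrix of raw read counts (TSV,
genes in rows). Expression units:

* CPM  = count / library_size * 1e6 (library size = column sum)
* FPKM = count * 1e9 / (library_size * gene_length_bp); the heatmap scale is
  log10(FPKM + 1). When gene lengths are unavailable, log10(CPM + 1) is the
  documented fallback.

The expression filter retains genes with >= ``min_cpm`` CPM in at least
``min_samples`` samples (both comparisons inclusive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionFilterConfig",
    "cpm",
    "filter_expressed",
    "log_fpkm",
    "log_cpm10",
    "cluster_samples",
    "SampleClustering",
]


@dataclass(frozen=True)
class ExpressionFilterConfig:
    min_cpm: float = 1.0
    min_samples: int = 4

    def __post_init__(self) -> None:
        if self.min_cpm < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be non-negative")


class CountMatrix:
    """Gene x sample raw counts with optional gene lengths (bp).

    Thin wrapper around a pandas DataFrame (rows = genes, columns = samples)
    enforcing unique identifiers and non-negative integer counts.
    """

    def __init__(self, counts: pd.DataFrame, gene_lengths: Optional[pd.Series] = None):
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in count matrix")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers in count matrix")
        values = counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64) if values.size else counts
        if gene_lengths is not None:
            missing = counts.index.difference(gene_lengths.index)
            if len(missing):
                raise ValueError(
                    f"gene lengths missing for {len(missing)} genes, e.g. {list(missing[:3])}"
                )
            gene_lengths = gene_lengths.loc[counts.index].astype(float)
            if len(gene_lengths) and (gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")
        self.gene_lengths = gene_lengths

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        lengths = self.gene_lengths.loc[genes] if self.gene_lengths is not None else None
        return CountMatrix(self.counts.loc[genes], lengths)

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path, lengths_path=None) -> "CountMatrix":
        """Read counts from TSV (first column = gene id, header = samples)
        and, optionally, a two-column gene-length TSV (gene, length_bp)."""
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = None
        if lengths_path is not None:
            ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
            lengths = ldf.iloc[:, 0]
        return cls(counts, lengths)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene")


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million; every column of the result sums to 1e6."""
    lib = matrix.library_sizes
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return matrix.counts / lib * 1e6


def filter_expressed(
    cpm_matrix: pd.DataFrame, config: ExpressionFilterConfig = ExpressionFilterConfig()
) -> list[str]:
    """Genes with CPM >= min_cpm in >= min_samples samples, input order kept."""
    keep = (cpm_matrix >= config.min_cpm).sum(axis=1) >= config.min_samples
    return list(cpm_matrix.index[keep])


def log_fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """log10(FPKM + 1), the heatmap normalisation.

    Requires gene lengths; raises otherwise (use :func:`log_cpm10` as the
    length-free fallback).
    """
    if matrix.gene_lengths is None:
        raise ValueError(
            "gene lengths are required for FPKM; supply a gene-length TSV "
            "or use log_cpm10(cpm(matrix)) as fallback"
        )
    lib = matrix.library_sizes
    if (lib == 0).any():
        raise ValueError("zero library size")
    fpkm = matrix.counts * 1e9
    fpkm = fpkm.div(lib, axis=1).div(matrix.gene_lengths, axis=0)
    return np.log10(fpkm + 1.0)


def log_cpm10(cpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """log10(CPM + 1): fallback heatmap scale when lengths are unknown."""
    return np.log10(cpm_matrix + 1.0)


@dataclass
class SampleClustering:
    """Agglomerative clustering of samples (average linkage, Euclidean)."""

    sample_ids: list
    linkage: np.ndarray

    @property
    def leaf_order(self) -> list:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int = 2) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({_fmt(tree.left, tree.dist)},{_fmt(tree.right, tree.dist)});"


def cluster_samples(expr: pd.DataFrame, method: str = "average", metric: str = "euclidean") -> SampleClustering:
    """Hierarchically cluster the samples (columns) of an expression matrix.

    Used for the two-group heatmap view: on the planted differentially
    expressed genes, cutting the tree into 2 clusters should recover the
    risk dichotomy.
    """
    if expr.shape[1] < 2:
        raise ValueError("sample clustering needs at least 2 samples")
    data = expr.to_numpy().T  # samples as observations
    link = hierarchy.linkage(pdist(data, metric=metric), method=method)
    return SampleClustering(sample_ids=list(expr.columns), linkage=link)
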