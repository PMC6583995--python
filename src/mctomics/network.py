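"""Weighted gene co-expression network: soft-threshold adjacency, topological
overlap, module detection by dendrogram branch cutting, module eigengenes and
eigengene-trait correlation.

Construction (unsigned network):

* adjacency          a_ij = |cor(x_i, x_j)|^beta, a_ii = 0
* connectivity       k_i  = sum_{j != i} a_ij (soft; a raw sum-of-|cor| mode
  is available via ``connectivity_mode='raw'``)
* topological overlap
      TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
      l_ij = sum_{u != i,j} a_iu * a_uj
* modules: average-linkage clustering of 1 - TOM, branches cut at a fixed
  fraction of the maximum merge height; clusters below ``min_module_size``
  fall into the ``'unassigned'`` pool.
* module eigengene: first singular direction of the gene-standardised module
  expression in sample space, sign-oriented so the mean correlation with
  member genes is non-negative.
* module-trait association: Pearson correlation of each eigengene with the
  malignancy score, p from the t-test with n-2 degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "connectivity",
    "select_top_connected",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "correlation_pvalue",
    "CoexpressionNetwork",
    "NetworkResults",
    "ModulePartition",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"

# cosmetic colour aliases for size-ranked module labels (M1 -> first name, ...)
MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


@dataclass(frozen=True)
class NetworkConfig:
    beta: float = 11.0
    n_top_genes: int = 6000
    min_module_size: int = 30
    trait_p_threshold: float = 0.1
    cut_height_fraction: float = 0.99
    connectivity_mode: str = "soft"  # 'soft' (sum |cor|^beta) or 'raw' (sum |cor|)

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 < self.trait_p_threshold < 1:
            raise ValueError("trait_p_threshold must lie in (0, 1)")
        if self.connectivity_mode not in ("soft", "raw"):
            raise ValueError("connectivity_mode must be 'soft' or 'raw'")


def _screen_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    var = expr.var(axis=1, ddof=1)
    constant = var[var == 0].index
    if len(constant):
        logger.warning(
            "removing %d zero-variance gene(s) before correlation: %s%s",
            len(constant), list(constant[:5]), "..." if len(constant) > 5 else "",
        )
        expr = expr.drop(index=constant)
    return expr


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Pearson correlation between genes (rows) across samples."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for gene-gene correlation")
    if (expr.var(axis=1, ddof=1) == 0).any():
        raise ValueError("constant gene(s) present; screen them out first")
    return np.corrcoef(expr.to_numpy())


def connectivity(expr: pd.DataFrame, beta: float = 11.0, mode: str = "soft") -> pd.Series:
    """Per-gene network connectivity.

    ``mode='soft'``: k_i = sum_{j != i} |cor_ij|^beta (consistent with the
    beta-power network); ``mode='raw'``: k_i = sum_{j != i} |cor_ij|.
    """
    expr = _screen_constant_genes(expr)
    cor = correlation_matrix(expr)
    acor = np.abs(np.clip(cor, -1.0, 1.0))
    np.fill_diagonal(acor, 0.0)
    if mode == "soft":
        k = (acor ** beta).sum(axis=1)
    elif mode == "raw":
        k = acor.sum(axis=1)
    else:
        raise ValueError("mode must be 'soft' or 'raw'")
    return pd.Series(k, index=expr.index, name="connectivity")


def select_top_connected(k: pd.Series, n_top: int) -> list[str]:
    """The ``n_top`` genes of highest connectivity, ties broken by input order."""
    if n_top >= len(k):
        if n_top > len(k):
            warnings.warn(
                f"n_top={n_top} exceeds the {len(k)} available genes; taking all"
            )
        return list(k.index)
    order = np.argsort(-k.to_numpy(), kind="stable")
    return list(k.index[np.sort(order[:n_top])])


def adjacency(cor: np.ndarray, beta: float = 11.0) -> np.ndarray:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    cor = np.asarray(cor, dtype=float)
    if cor.ndim != 2 or cor.shape[0] != cor.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(cor, cor.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if np.nanmax(np.abs(cor)) > 1 + 1e-8:
        raise ValueError("correlation entries must lie in [-1, 1]")
    a = np.abs(np.clip(cor, -1.0, 1.0)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_u a_iu; the diagonal is set
    to 1. Values lie in [0, 1] for adjacency in [0, 1].
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(a < -1e-12) or np.any(a > 1 + 1e-12):
        raise ValueError("adjacency entries must lie in [0, 1]")
    if np.any(np.abs(np.diag(a)) > 1e-12):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    # l_ij over u != i, j: full product minus the u = i and u = j terms;
    # the diagonal of a is zero so those terms vanish automatically.
    l = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return t


@dataclass
class ModulePartition:
    """Gene-to-module assignment with deterministic, size-ranked labels."""

    labels: pd.Series  # gene id -> module label ('M1', ..., or 'unassigned')
    linkage: np.ndarray
    colour_aliases: dict = field(default_factory=dict)

    @property
    def module_names(self) -> list[str]:
        return [m for m in pd.unique(self.labels) if m != UNASSIGNED]

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def genes(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def detect_modules(
    dissimilarity: np.ndarray,
    gene_ids: Sequence[str],
    config: NetworkConfig = NetworkConfig(),
) -> ModulePartition:
    """Cut the average-linkage dendrogram of a TOM dissimilarity into modules.

    Branches are formed by cutting at ``cut_height_fraction`` of the maximum
    merge height; clusters of at least ``min_module_size`` genes become
    modules M1, M2, ... ranked by decreasing size (ties by first occurrence);
    everything else is pooled under ``'unassigned'``.
    """
    d = np.asarray(dissimilarity, dtype=float)
    gene_ids = list(gene_ids)
    if d.shape[0] != len(gene_ids):
        raise ValueError("dissimilarity size does not match gene ids")
    if len(gene_ids) < config.min_module_size:
        warnings.warn(
            f"only {len(gene_ids)} genes (< min_module_size={config.min_module_size}); "
            "no modules detected"
        )
        return ModulePartition(
            labels=pd.Series(UNASSIGNED, index=gene_ids, name="module"),
            linkage=np.empty((0, 4)),
        )
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    cut_h = config.cut_height_fraction * link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut_h, criterion="distance")

    # size-ranked deterministic labels
    counts = pd.Series(raw).value_counts()
    order = sorted(
        counts.index,
        key=lambda c: (-counts[c], int(np.argmax(raw == c))),
    )
    labels = np.full(len(gene_ids), UNASSIGNED, dtype=object)
    rank = 0
    aliases = {}
    for c in order:
        if counts[c] >= config.min_module_size:
            name = f"M{rank + 1}"
            labels[raw == c] = name
            if rank < len(MODULE_COLOURS):
                aliases[name] = MODULE_COLOURS[rank]
            rank += 1
    return ModulePartition(
        labels=pd.Series(labels, index=gene_ids, name="module"),
        linkage=link,
        colour_aliases=aliases,
    )


def module_eigengene(expr: pd.DataFrame, genes: Sequence[str]) -> tuple[pd.Series, float]:
    """Eigengene (unit-norm sample-space profile) and variance explained.

    The module's expression is standardised per gene; the eigengene is the
    first right-singular vector (samples as coordinates), oriented so that
    its mean correlation with the member genes is non-negative.
    """
    sub = expr.loc[list(genes)]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).all():
        raise ValueError("module contains only zero-variance genes")
    sub = sub.loc[sd > 0]
    z = (sub.sub(mu[sd > 0], axis=0)).div(sd[sd > 0], axis=0).to_numpy()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    if u[:, 0].mean() < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return pd.Series(eig, index=expr.columns, name="eigengene"), var_explained


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    p_threshold: float = 0.1,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a per-sample trait.

    Returns a table (module, r, p, significant) where significance means
    p < ``p_threshold`` (strict, matching the screening rule p < 0.1).
    """
    if len(trait) < 4:
        raise ValueError("need at least 4 samples for module-trait correlation")
    if float(np.std(trait)) == 0:
        raise ValueError("trait is constant; correlation undefined")
    trait = trait.loc[eigengenes.columns]
    rows = []
    for module, eig in eigengenes.iterrows():
        r, p = stats.pearsonr(eig.to_numpy(), trait.to_numpy(dtype=float))
        rows.append(
            {"module": module, "r": float(r), "p": float(p), "significant": bool(p < p_threshold)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Weighted co-expression network model over an expression matrix.

    Parameters
    ----------
    expr : DataFrame
        Expression values (e.g. log CPM), genes x samples, already filtered
        for expression.
    config : NetworkConfig
        beta, top-gene count, minimum module size, trait p threshold.
    """

    def __init__(self, expr: pd.DataFrame, config: NetworkConfig = NetworkConfig()):
        if expr.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        self.expr = _screen_constant_genes(expr)
        self.config = config

    def fit(self) -> "NetworkResults":
        cfg = self.config
        k = connectivity(self.expr, beta=cfg.beta, mode=cfg.connectivity_mode)
        top = select_top_connected(k, cfg.n_top_genes)
        sub = self.expr.loc[top]
        cor = correlation_matrix(sub)
        a = adjacency(cor, beta=cfg.beta)
        t = tom(a)
        partition = detect_modules(1.0 - t, top, cfg)

        eig_rows, var_expl = {}, {}
        for module in partition.module_names:
            eig, ve = module_eigengene(sub, partition.genes(module))
            eig_rows[module] = eig
            var_expl[module] = ve
        eigengenes = (
            pd.DataFrame(eig_rows).T
            if eig_rows
            else pd.DataFrame(columns=sub.columns)
        )
        eigengenes.index.name = "module"
        return NetworkResults(
            model=self,
            connectivity_=k,
            top_genes=top,
            partition=partition,
            eigengenes=eigengenes,
            variance_explained=pd.Series(var_expl, dtype=float),
        )


@dataclass
class NetworkResults:
    """Fitted network: module partition, eigengenes and trait associations."""

    model: CoexpressionNetwork
    connectivity_: pd.Series
    top_genes: list
    partition: ModulePartition
    eigengenes: pd.DataFrame
    variance_explained: pd.Series

    def trait_correlation(self, trait: pd.Series) -> pd.DataFrame:
        """Module-trait table against a per-sample trait (malignancy score)."""
        return module_trait_correlation(
            self.eigengenes, trait, p_threshold=self.model.config.trait_p_threshold
        )

    @property
    def n_modules(self) -> int:
        return len(self.partition.module_names)

    def summary(self, trait: Optional[pd.Series] = None) -> str:
        cfg = self.model.config
        lines = [
            "Weighted co-expression network "
            f"(beta={cfg.beta:g}, unsigned, min module size {cfg.min_module_size})",
            f"genes in network:   {len(self.top_genes)}",
            f"modules detected:   {self.n_modules}",
            f"unassigned genes:   {int((self.partition.labels == UNASSIGNED).sum())}",
        ]
        if trait is not None:
            mt = self.trait_correlation(trait)
            sig = mt[mt["significant"]]
            lines.append(
                f"trait-associated:   {len(sig)} module(s) at p < {cfg.trait_p_threshold}"
            )
            for _, row in sig.iterrows():
                lines.append(f"  {row['module']}: r = {row['r']:+.2f}, p = {row['p']:.3g}")
        return "\n".join(lines)
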