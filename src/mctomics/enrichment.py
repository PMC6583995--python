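"""Hypergeometric over-representation of annotation terms in a target gene
set against the expressed-gene background, with Benjamini-Hochberg FDR.

For a background universe of N genes of which K carry a term, and a target
list of n genes of which k carry it, the enrichment p-value is the
hypergeometric upper tail P(X >= k). Terms with adjusted p <= alpha (default
0.05) are significant. Gene identifiers may first be translated through a
user-supplied orthologue mapping table (e.g. dog -> human); unmapped genes
are dropped from both target and background and reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = [
    "map_orthologues",
    "hypergeom_upper_tail",
    "enrich",
    "read_annotation_tsv",
    "read_annotation_gaf",
    "read_mapping_tsv",
]


def map_orthologues(
    gene_ids: Sequence[str], mapping: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    """Translate gene ids through a one-to-one orthologue table.

    Returns ``(mapped, unmapped)`` where ``mapped`` preserves input order.
    The mapping must have unique source keys (enforced by the readers).
    """
    mapped, unmapped = [], []
    for g in gene_ids:
        if g in mapping:
            mapped.append(mapping[g])
        else:
            unmapped.append(g)
    return mapped, unmapped


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    target: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, set],
    alpha: float = 0.05,
    namespaces: Optional[Mapping[str, str]] = None,
    min_term_size: int = 1,
    max_term_size: Optional[int] = None,
) -> pd.DataFrame:
    """Over-representation of each annotation term in ``target``.

    ``annotation`` maps term id -> set of gene ids. Only genes in the
    background universe count; terms with fewer than ``min_term_size``
    background genes are not tested. BH adjustment is applied within each
    namespace when ``namespaces`` (term -> namespace) is given, else over all
    tested terms. The result is sorted by raw p (ties by term id).
    """
    target = set(target)
    background = set(background)
    stray = target - background
    if stray:
        raise ValueError(
            f"{len(stray)} target gene(s) absent from background, "
            f"e.g. {sorted(stray)[:5]}"
        )
    N, n = len(background), len(target)
    rows = []
    for term, genes in annotation.items():
        in_bg = genes & background
        K = len(in_bg)
        if K < min_term_size or K == 0:
            continue
        if max_term_size is not None and K > max_term_size:
            continue
        k = len(in_bg & target)
        rows.append(
            {
                "term": term,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_upper_tail(N, K, n, k),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    if table.empty:
        table["p_adj"] = []
        table["significant"] = []
        return table
    if namespaces:
        table["namespace"] = [namespaces.get(t, "all") for t in table["term"]]
        table["p_adj"] = np.nan
        for _, idx in table.groupby("namespace").groups.items():
            table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    else:
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] <= alpha
    return table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


# ---- readers --------------------------------------------------------------

def read_annotation_tsv(path) -> dict[str, set]:
    """Two-column TSV (gene, term) -> mapping term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    out: dict[str, set] = {}
    for gene, term in zip(df["gene"].astype(str), df["term"].astype(str)):
        out.setdefault(term, set()).add(gene)
    return out


def read_annotation_gaf(path) -> dict[str, set]:
    """GAF 2.x annotation: gene symbol from column 2, GO id from column 5."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            out.setdefault(cols[4], set()).add(cols[1])
    return out


def read_mapping_tsv(path) -> dict[str, str]:
    """Two-column TSV (source_id, target_id) with unique source keys."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], comment="#")
    dup = df["source"][df["source"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate source keys in mapping: {sorted(set(dup))[:5]}")
    return dict(zip(df["source"].astype(str), df["target"].astype(str)))
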