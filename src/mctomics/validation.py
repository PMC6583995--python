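"""Immunostaining quantification and rank-based group comparison.

Ki67 proliferation index: the mean over high-power fields of the per-field
percentage of positively stained mast cells (five 400x "hot spot" fields,
at least 200 cells per section in the standard protocol; sections below 200
cells are flagged, not dropped).

CAF score: total count of alpha-SMA-positive stromal fibroblasts summed over
five hot-spot fields.

Group comparison: two-sided Mann-Whitney U. For small samples
(n1 + n2 <= 12) the p-value is exact, by full enumeration of all C(N, n1)
group assignments of the pooled observations (midranks make this valid under
ties); larger samples use the normal approximation with tie-corrected
variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ki67_index",
    "caf_score",
    "mann_whitney",
    "MannWhitneyResult",
    "read_field_counts_csv",
    "sample_indices",
    "MIN_CELLS_KI67",
]

MIN_CELLS_KI67 = 200
EXACT_MAX_N = 12


def ki67_index(positive: Sequence[float], negative: Sequence[float]) -> float:
    """Mean per-field percentage of Ki67-positive cells.

    Each field contributes 100 * positive / (positive + negative); fields are
    weighted equally regardless of cell count.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if positive.size == 0 or positive.shape != negative.shape:
        raise ValueError("positive and negative field counts must be non-empty and aligned")
    totals = positive + negative
    if (totals <= 0).any():
        raise ValueError("every field must contain at least one counted cell")
    return float(np.mean(100.0 * positive / totals))


def caf_score(field_counts: Sequence[float], n_fields: int = 5) -> int:
    """Sum of alpha-SMA-positive fibroblast counts over the hot-spot fields."""
    counts = np.asarray(field_counts, dtype=float)
    if counts.size != n_fields:
        raise ValueError(f"expected {n_fields} field counts, got {counts.size}")
    if (counts < 0).any():
        raise ValueError("field counts must be non-negative")
    return int(counts.sum())


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    n1: int
    n2: int
    median1: float
    median2: float
    method: str  # 'exact' or 'normal'


def _u_statistic(ranks: np.ndarray, idx1: np.ndarray, n1: int) -> float:
    r1 = ranks[idx1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is reported for the first group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, np.arange(n1), n1)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_MAX_N:
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = _u_statistic(ranks, np.array(idx), n1)
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        method = "exact"
    else:
        N = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
        sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
            p = float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
        method = "normal"
    return MannWhitneyResult(
        U=float(u_obs),
        p=float(min(1.0, p)),
        n1=n1,
        n2=n2,
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        method=method,
    )


# ---- field-count I/O ------------------------------------------------------

def read_field_counts_csv(path) -> pd.DataFrame:
    """Field-count CSV: columns sample, field_index, positive and, per mode,
    negative (Ki67) or caf_count (alpha-SMA)."""
    df = pd.read_csv(path)
    if "sample" not in df.columns or "field_index" not in df.columns:
        raise ValueError(f"field-count CSV {path} needs 'sample' and 'field_index' columns")
    return df


def sample_indices(field_counts: pd.DataFrame, mode: str = "ki67") -> pd.DataFrame:
    """Per-sample Ki67 index (with a <200-cell flag) or CAF score.

    ``mode='ki67'`` expects columns positive/negative; ``mode='caf'`` expects
    caf_count.
    """
    rows = []
    for sample, grp in field_counts.groupby("sample", sort=False):
        if mode == "ki67":
            idx = ki67_index(grp["positive"].to_numpy(), grp["negative"].to_numpy())
            total = float((grp["positive"] + grp["negative"]).sum())
            rows.append(
                {
                    "sample": sample,
                    "ki67_index": idx,
                    "total_cells": total,
                    "low_cell_count": total < MIN_CELLS_KI67,
                }
            )
        elif mode == "caf":
            rows.append(
                {
                    "sample": sample,
                    "caf_score": caf_score(
                        grp["caf_count"].to_numpy(), n_fields=len(grp)
                    ),
                }
            )
        else:
            raise ValueError("mode must be 'ki67' or 'caf'")
    return pd.DataFrame(rows)
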