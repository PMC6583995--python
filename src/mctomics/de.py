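"""Negative-binomial exact-test differential expression between risk groups.

The model: counts y_gs ~ NB(mean = N_s * p_g(group), variance = mu + phi*mu^2)
with a single common dispersion phi shared across genes. The test is the
classic conditional exact test: after scaling every sample to a common
(geometric-mean) effective library size, the group-A sum is compared with its
conditional distribution given the two-group total — a negative
hypergeometric under NB sampling, binomial in the Poisson limit phi -> 0.
Two-sided p-values sum the probabilities of all outcomes no more probable
than the observed one.

Library composition is normalised by trimmed-mean-of-M-values (TMM) factors;
the common dispersion is estimated by maximising the conditional
(group-sum-conditioned) log-likelihood summed over genes (qCML).

Calling thresholds: a gene is called up (down) in the comparison group when
the BH-adjusted p-value is <= ``alpha_adj`` and the log2 fold change is
>= ``min_abs_logfc`` (<= -``min_abs_logfc``); both comparisons inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEConfig",
    "norm_factors",
    "effective_library_sizes",
    "equalize_libraries",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_de",
    "ExactTestDE",
    "DEResults",
]


@dataclass(frozen=True)
class DEConfig:
    alpha_adj: float = 0.05
    min_abs_logfc: float = 2.0  # log2 units
    prior_count: float = 0.125

    def __post_init__(self) -> None:
        if not 0 < self.alpha_adj < 1:
            raise ValueError("alpha_adj must lie in (0, 1)")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")
        if self.prior_count <= 0:
            raise ValueError("prior_count must be positive")


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def norm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the column whose upper-quartile CPM is closest to
    the mean upper quartile. For each sample, per-gene log2 expression ratios
    (M) against the reference are trimmed by ``logratio_trim`` on M and
    ``abundance_trim`` on average abundance (A), then averaged with
    inverse-asymptotic-variance weights.
    """
    lib = counts.sum(axis=0).astype(float)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    y = counts.to_numpy(dtype=float)
    n = y / lib.to_numpy()  # proportions

    uq = np.quantile(n, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    r = n[:, ref_idx]
    Nr = lib.iloc[ref_idx]
    for j in range(y.shape[1]):
        factors[j] = _tmm_pair(n[:, j], r, lib.iloc[j], Nr, logratio_trim, abundance_trim, weighted)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(p_obs, p_ref, N_obs, N_ref, logratio_trim, abundance_trim, weighted) -> float:
    keep = (p_obs > 0) & (p_ref > 0)
    if not keep.any():
        return 1.0
    po, pr = p_obs[keep], p_ref[keep]
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic binomial variance of M
    w = (1 - po) / (po * N_obs) + (1 - pr) / (pr * N_ref)
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[finite], A[finite], w[finite]
    if M.size == 0 or float(np.max(np.abs(M))) < 1e-6:
        return 1.0
    n = M.size
    loM = np.floor(n * logratio_trim) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * abundance_trim) + 1
    hiA = n + 1 - loA
    rM = pd.Series(M).rank().to_numpy()
    rA = pd.Series(A).rank().to_numpy()
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        return 1.0
    if weighted:
        f = np.nansum(M[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
    else:
        f = np.nanmean(M[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def effective_library_sizes(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.Series:
    if factors is None:
        factors = norm_factors(counts)
    return counts.sum(axis=0) * factors


def equalize_libraries(counts: pd.DataFrame, eff_lib: pd.Series) -> pd.DataFrame:
    """Deterministically rescale counts to the geometric-mean effective
    library size (quantile-preserving scaling of expected counts)."""
    target = float(np.exp(np.mean(np.log(eff_lib.astype(float)))))
    return counts * (target / eff_lib)


# ---------------------------------------------------------------------------
# Common dispersion (conditional maximum likelihood)
# ---------------------------------------------------------------------------

def _group_cond_loglik(y: np.ndarray, r: float) -> float:
    """Conditional NB log-likelihood of one gene's counts in one group, given
    the group sum, assuming equal means and size parameter r = 1/phi."""
    z = y.sum()
    n = y.size
    return float(
        np.sum(gammaln(y + r)) - n * gammaln(r) - np.sum(gammaln(y + 1))
        - (gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1))
    )


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Sequence[str],
    factors: Optional[pd.Series] = None,
    bounds: tuple[float, float] = (1e-4, 4.0),
) -> float:
    """Single dispersion phi maximising the summed conditional log-likelihood.

    Counts are first scaled to equal effective library sizes and rounded;
    each group needs >= 2 samples. Returns phi >= 0 (the lower bound is
    treated as zero dispersion / Poisson).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(labels)}")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    eff = effective_library_sizes(counts, factors)
    pseudo = np.rint(equalize_libraries(counts, eff).to_numpy()).astype(np.int64)
    masks = [groups == g for g in labels]
    # drop genes with zero total: they carry no dispersion information
    keep = pseudo.sum(axis=1) > 0
    pseudo = pseudo[keep]

    ya = pseudo[:, masks[0]].astype(float)
    yb = pseudo[:, masks[1]].astype(float)

    def neg_loglik(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        ll = 0.0
        for y in (ya, yb):
            n = y.shape[1]
            z = y.sum(axis=1)
            ll += float(
                np.sum(gammaln(y + r)) - y.size * gammaln(r) - np.sum(gammaln(y + 1))
                - np.sum(gammaln(z + n * r) - gammaln(n * r) - gammaln(z + 1))
            )
        return -ll

    res = minimize_scalar(
        neg_loglik,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(np.exp(res.x))
    if phi <= bounds[0] * 1.05:
        # boundary solution: effectively Poisson
        return bounds[0]
    return phi


# ---------------------------------------------------------------------------
# Conditional exact test
# ---------------------------------------------------------------------------

def _exact_pvalue(sa: int, s: int, na: int, nb: int, phi: float) -> float:
    """Two-sided exact p for group-A sum ``sa`` given total ``s``.

    Conditional distribution of the group-A sum given the total under iid NB
    sampling with common mean and dispersion; outcomes are ranked by
    probability and all outcomes no more probable than the observed one are
    summed.
    """
    if s == 0:
        return 1.0
    a = np.arange(s + 1)
    if phi <= 0:
        # Poisson limit: Binomial(s, na / (na + nb))
        p = na / (na + nb)
        logp = (
            gammaln(s + 1) - gammaln(a + 1) - gammaln(s - a + 1)
            + a * np.log(p) + (s - a) * np.log1p(-p)
        )
    else:
        ra, rb = na / phi, nb / phi
        logp = (
            gammaln(a + ra) - gammaln(a + 1)
            + gammaln(s - a + rb) - gammaln(s - a + 1)
        )
        logp -= logsumexp(logp)
    logp -= logsumexp(logp)  # normalise (no-op for the NB branch, safe for both)
    obs = logp[sa]
    mask = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def nb_exact_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    phi: float,
    factors: Optional[pd.Series] = None,
) -> pd.Series:
    """Raw two-sided exact-test p-value per gene.

    ``counts`` are raw counts; they are library-equalised internally (TMM
    factors computed if not supplied) and rounded before conditioning.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(labels)}")
    eff = effective_library_sizes(counts, factors)
    pseudo = np.rint(equalize_libraries(counts, eff).to_numpy()).astype(np.int64)
    mask_a = groups == labels[0]
    na, nb = int(mask_a.sum()), int((~mask_a).sum())
    sa = pseudo[:, mask_a].sum(axis=1)
    sb = pseudo[:, ~mask_a].sum(axis=1)
    phi_eff = 0.0 if phi <= 1e-4 else phi
    pvals = np.array([
        _exact_pvalue(int(a), int(a + b), na, nb, phi_eff) for a, b in zip(sa, sb)
    ])
    return pd.Series(pvals, index=counts.index, name="PValue")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, config: DEConfig = DEConfig()) -> pd.DataFrame:
    """Add the up/down/none call column given logFC and FDR columns."""
    call = np.where(
        (table["FDR"] <= config.alpha_adj) & (table["logFC"] >= config.min_abs_logfc),
        "up",
        np.where(
            (table["FDR"] <= config.alpha_adj) & (table["logFC"] <= -config.min_abs_logfc),
            "down",
            "none",
        ),
    )
    out = table.copy()
    out["call"] = call
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ExactTestDE:
    """Exact-test differential expression model.

    Parameters
    ----------
    counts : CountMatrix or DataFrame
        Raw counts, genes x samples (pre-filtered for expression).
    groups : sequence of labels
        One label per sample; exactly two distinct values.
    baseline : label, optional
        The reference group; positive logFC means higher expression in the
        *other* (comparison) group. Defaults to ``'low'`` when the labels are
        {'low', 'high'}, else the lexicographically smaller label.
    """

    def __init__(self, counts, groups: Sequence[str], baseline: Optional[str] = None,
                 config: DEConfig = DEConfig()):
        from .expression import CountMatrix

        self.counts = counts.counts if isinstance(counts, CountMatrix) else counts
        self.groups = np.asarray(groups)
        if len(self.groups) != self.counts.shape[1]:
            raise ValueError("one group label per sample is required")
        labels = sorted(pd.unique(self.groups))
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, got {labels}")
        if baseline is None:
            baseline = "low" if set(labels) == {"low", "high"} else labels[0]
        if baseline not in labels:
            raise ValueError(f"baseline {baseline!r} not among group labels {labels}")
        self.baseline = baseline
        self.comparison = [g for g in labels if g != baseline][0]
        self.config = config

    def fit(self, dispersion: Optional[float] = None) -> "DEResults":
        factors = norm_factors(self.counts)
        phi = (
            estimate_common_dispersion(self.counts, self.groups, factors)
            if dispersion is None
            else float(dispersion)
        )
        pvals = nb_exact_test(self.counts, self.groups, phi, factors)

        eff = effective_library_sizes(self.counts, factors)
        pseudo = equalize_libraries(self.counts, eff)
        mean_lib = float(np.exp(np.mean(np.log(eff.astype(float)))))
        prior = self.config.prior_count
        m_cmp = pseudo.loc[:, self.groups == self.comparison].mean(axis=1)
        m_base = pseudo.loc[:, self.groups == self.baseline].mean(axis=1)
        logfc = np.log2((m_cmp + prior) / (m_base + prior))
        logcpm = np.log2((pseudo.mean(axis=1) + prior) / mean_lib * 1e6)

        table = pd.DataFrame(
            {
                "logFC": logfc,
                "logCPM": logcpm,
                "PValue": pvals,
                "FDR": bh_adjust(pvals.to_numpy()),
            },
            index=self.counts.index,
        )
        table = call_de(table, self.config)
        return DEResults(model=self, table=table, dispersion=phi, norm_factors=factors)


@dataclass
class DEResults:
    """Per-gene exact-test results with calling at the configured thresholds."""

    model: ExactTestDE
    table: pd.DataFrame
    dispersion: float
    norm_factors: pd.Series

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["call"] != "none"])

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Negative-binomial exact test: "
            f"{self.model.comparison} vs {self.model.baseline}",
            f"genes tested:        {len(self.table)}",
            f"common dispersion:   {self.dispersion:.4f}",
            f"thresholds:          FDR <= {cfg.alpha_adj}, |log2FC| >= {cfg.min_abs_logfc}",
            f"up in {self.model.comparison:<14}{self.n_up}",
            f"down in {self.model.comparison:<12}{self.n_down}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")
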