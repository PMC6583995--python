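"""Synthetic cohorts, count matrices, annotations and immunostaining counts
with known ground truth.

The generator emulates the study conditions of the real dataset it stands in
for: 15 tumours split 4 high-risk / 11 low-risk, ~14k expressed genes,
negative-binomial counts (variance mu + phi*mu^2, default phi = 0.1),
per-sample library-size factors log-uniform in [0.5, 2], a planted set of
differentially expressed genes (mostly up-regulated in the high-risk group)
and planted co-expression modules driven by one latent per-sample factor
each, some of which are coupled to the malignancy score.

A trait-linked module's latent factor is constructed to have the requested
*empirical* correlation with the cohort's malignancy scores (standardised
scores mixed with orthogonalised noise), so the planted coupling is exact in
every simulated dataset rather than only in expectation.

All randomness flows from explicit integer seeds through named
``numpy.random.Generator`` instances; identical seeds and parameters yield
bit-identical artefacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, Status, classify_risk, malignancy_score
from .expression import CountMatrix

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_counts",
    "generate_annotation",
    "generate_field_counts",
    "generate_caf_field_counts",
    "default_truth",
    "simulate_dataset",
    "SyntheticDataset",
]

_LOCATIONS = ["Limbs and tail", "Trunk", "Abdomen", "Inguinal"]
_BREEDS = ["Labrador", "Golden Retriever", "Pitbull", "Poodle", "Mixed breed"]


@dataclass(frozen=True)
class CohortSpec:
    """Target shape of a synthetic clinical cohort."""

    n_samples: int = 15
    n_high_risk: int = 4
    follow_up_range: tuple[int, int] = (101, 1095)  # days
    ki67_range: tuple[float, float] = (0.3, 23.4)  # percent
    grade2_fraction: float = 2 / 15  # proportion of two-tier high-grade lesions

    def __post_init__(self) -> None:
        if self.n_high_risk > self.n_samples:
            raise ValueError(
                f"n_high_risk={self.n_high_risk} exceeds n_samples={self.n_samples}"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside a simulated count matrix."""

    de_log2fc: dict = field(default_factory=dict)  # gene id -> signed log2 effect
    module_membership: dict = field(default_factory=dict)  # gene id -> module label
    trait_linked_modules: set = field(default_factory=set)
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        modules = set(self.module_membership.values())
        missing = self.trait_linked_modules - modules
        if missing:
            raise ValueError(f"trait-linked module(s) not planted: {sorted(missing)}")

    @property
    def de_gene_ids(self) -> set:
        return set(self.de_log2fc)

    def module_genes(self, module: str) -> list[str]:
        return [g for g, m in self.module_membership.items() if m == module]

    def to_json(self, path) -> None:
        payload = {
            "de_log2fc": self.de_log2fc,
            "module_membership": self.module_membership,
            "trait_linked_modules": sorted(self.trait_linked_modules),
            "dispersion": self.dispersion,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

_SUBSCORE_COMBOS = [
    (g, s, d, k)
    for g in (1, 2)
    for s in (1, 2, 3)
    for d in (0, 3)
    for k in (1, 2, 3)
]


def _sample_fields(rng, combo, spec: CohortSpec):
    g, s, d, k = combo
    fu_lo, fu_hi = spec.follow_up_range
    if s == 1:
        follow_up = int(rng.integers(366, max(fu_hi, 367) + 1))
    elif s == 2:
        follow_up = int(rng.integers(180, 366))
    else:
        follow_up = int(rng.integers(max(min(fu_lo, 179), 1), 180))
    if d == 3:
        status = Status.DEAD_MCT
    else:
        status = Status.CENSORED if rng.random() < 0.1 else Status.ALIVE
    k_lo, k_hi = spec.ki67_range
    if k == 1:
        ki67 = float(rng.uniform(max(k_lo, 0.05), 2.94))
    elif k == 2:
        ki67 = float(rng.uniform(3.0, 7.0))
    else:
        ki67 = float(rng.uniform(7.1, max(k_hi, 7.2)))
    return g, follow_up, status, round(ki67, 2)


def generate_cohort(
    spec: CohortSpec = CohortSpec(), seed: int = 0
) -> tuple[list[ClinicalRecord], list[str]]:
    """Simulate a clinical cohort whose records score into intended classes.

    Returns ``(records, intended_risk_labels)``; rescoring the records with
    the composite malignancy rules reproduces the intended labels exactly.
    """
    rng = np.random.default_rng(seed)
    intended = np.array(
        ["high"] * spec.n_high_risk + ["low"] * (spec.n_samples - spec.n_high_risk)
    )
    rng.shuffle(intended)
    records = []
    for i, label in enumerate(intended):
        grade = 2 if rng.random() < spec.grade2_fraction else 1
        if label == "high":
            combos = [c for c in _SUBSCORE_COMBOS if c[0] == grade and sum(c) >= 6]
        else:
            combos = [c for c in _SUBSCORE_COMBOS if c[0] == grade and sum(c) <= 5]
        if not combos:  # grade 2 cannot score <= 5 with status 3; always has <=5 combos though
            combos = [c for c in _SUBSCORE_COMBOS if sum(c) >= 6] if label == "high" else [
                c for c in _SUBSCORE_COMBOS if sum(c) <= 5
            ]
        combo = combos[int(rng.integers(len(combos)))]
        g, follow_up, status, ki67 = _sample_fields(rng, combo, spec)
        records.append(
            ClinicalRecord(
                sample_id=f"S{i + 1:02d}",
                follow_up_days=follow_up,
                status=status,
                two_tier_grade=g,
                ki67_index=ki67,
                age_years=float(rng.integers(3, 16)),
                sex="male" if rng.random() < 0.4 else "female",
                location=_LOCATIONS[int(rng.integers(len(_LOCATIONS)))],
                breed=_BREEDS[int(rng.integers(len(_BREEDS)))],
            )
        )
    return records, list(intended)


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def _trait_factor(rng, scores: np.ndarray, coupling: float) -> np.ndarray:
    """Latent factor with exact empirical correlation ``coupling`` with the
    scores: standardised scores mixed with orthogonalised standard noise."""
    if scores.std() == 0:
        raise ValueError("malignancy scores are constant; cannot plant a trait-linked module")
    z = (scores - scores.mean()) / scores.std()
    e = rng.standard_normal(scores.size)
    e = e - e.mean()
    e = e - (e @ z) / (z @ z) * z  # orthogonalise against the score
    if np.allclose(e, 0):
        e = np.zeros_like(z)
    else:
        e = e / e.std()
    return coupling * z + np.sqrt(max(0.0, 1.0 - coupling ** 2)) * e


def generate_counts(
    n_genes: int,
    sample_ids: Sequence[str],
    high_risk: Sequence[bool],
    truth: SyntheticTruth,
    scores: Optional[Sequence[float]] = None,
    base_log2_mean: tuple[float, float] = (2.0, 9.0),
    module_loading: float = 0.8,
    trait_coupling: float = 0.7,
    lib_factor_range: tuple[float, float] = (0.5, 2.0),
    with_lengths: bool = True,
) -> CountMatrix:
    """Simulate a gene x sample NB count matrix with planted structure.

    * planted DE genes: the high-risk group's NB mean is 2**log2fc times the
      low-risk mean (signed effects; negative = down in high-risk);
    * planted module genes: one standard-normal latent factor per module is
      added on the log2-mean scale with weight ``module_loading``;
    * trait-linked modules: the factor has empirical correlation
      ``trait_coupling`` with the samples' malignancy scores (``scores``
      required; falls back to the 0/1 risk indicator if omitted);
    * every sample's expected counts are scaled by a library-size factor
      drawn log-uniformly from ``lib_factor_range``.
    """
    if truth.dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    sample_ids = list(sample_ids)
    high = np.asarray(high_risk, dtype=bool)
    if len(sample_ids) != high.size:
        raise ValueError("sample_ids and high_risk must align")
    planted = truth.de_gene_ids | set(truth.module_membership)
    if n_genes < len(planted):
        raise ValueError(
            f"n_genes={n_genes} below the {len(planted)} planted DE/module genes"
        )
    n_samples = len(sample_ids)
    if n_genes == 0:
        return CountMatrix(pd.DataFrame(index=pd.Index([], name="gene"), columns=sample_ids))

    rng = np.random.default_rng(truth.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    stray = planted - set(gene_ids)
    if stray:
        raise ValueError(
            f"planted gene id(s) outside the generated universe G00001..G{n_genes:05d}: "
            f"{sorted(stray)[:5]}"
        )

    log2_mean = rng.uniform(*base_log2_mean, size=n_genes)
    log2mu = np.tile(log2_mean[:, None], (1, n_samples))

    # planted differential expression (signed, relative to high-risk)
    for g, lfc in truth.de_log2fc.items():
        log2mu[idx_of[g], high] += lfc

    # planted module factors
    if scores is None:
        score_vec = high.astype(float)
    else:
        score_vec = np.asarray(scores, dtype=float)
    modules = sorted(set(truth.module_membership.values()))
    for m in modules:
        if m in truth.trait_linked_modules:
            f = _trait_factor(rng, score_vec, trait_coupling)
        else:
            f = rng.standard_normal(n_samples)
            f = (f - f.mean()) / f.std()
        for g in truth.module_genes(m):
            log2mu[idx_of[g], :] += module_loading * f

    lib = np.exp(rng.uniform(np.log(lib_factor_range[0]), np.log(lib_factor_range[1]),
                             size=n_samples))
    mu = (2.0 ** log2mu) * lib[None, :]

    if truth.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / truth.dispersion
        lam = rng.gamma(shape, truth.dispersion * mu)
        counts = rng.poisson(lam)

    lengths = (
        pd.Series(rng.integers(300, 10000, size=n_genes), index=gene_ids, name="length_bp")
        if with_lengths
        else None
    )
    return CountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sample_ids),
        gene_lengths=lengths,
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(
    gene_ids: Sequence[str],
    n_terms: int,
    seed: int = 0,
    enriched_term: Optional[str] = None,
    enriched_target: Optional[Sequence[str]] = None,
    target_rate: float = 0.8,
    background_rate: float = 0.05,
    base_rate_range: tuple[float, float] = (0.02, 0.2),
) -> pd.DataFrame:
    """Random per-gene term memberships with one optionally enriched term.

    Each of the ``n_terms`` terms includes every gene independently at a
    term-specific rate drawn from ``base_rate_range``. The designated
    ``enriched_term`` instead includes genes of ``enriched_target`` at
    ``target_rate`` and all other genes at ``background_rate``; setting
    ``target_rate == background_rate`` makes that term null (memberships
    uniform with respect to the target). Returns a long (gene, term) table.
    """
    if not 0.0 <= target_rate <= 1.0 or not 0.0 <= background_rate <= 1.0:
        raise ValueError("membership rates must lie in [0, 1]")
    gene_ids = list(gene_ids)
    universe = set(gene_ids)
    if enriched_target is not None:
        offenders = sorted(set(enriched_target) - universe)
        if offenders:
            raise ValueError(f"unknown gene id(s) in enriched target: {offenders[:5]}")
    rng = np.random.default_rng(seed)
    genes_arr = np.array(gene_ids)
    is_target = (
        np.isin(genes_arr, list(enriched_target)) if enriched_target is not None else None
    )
    rows = []
    for j in range(n_terms):
        term = f"T{j + 1:04d}"
        if enriched_term is not None and term == enriched_term and is_target is not None:
            rates = np.where(is_target, target_rate, background_rate)
        else:
            rates = np.full(len(gene_ids), rng.uniform(*base_rate_range))
        member = rng.random(len(gene_ids)) < rates
        rows.extend((g, term) for g in genes_arr[member])
    return pd.DataFrame(rows, columns=["gene", "term"])


# ---------------------------------------------------------------------------
# immunostaining field counts
# ---------------------------------------------------------------------------

def generate_field_counts(
    records: Sequence[ClinicalRecord],
    fields_per_sample: int = 5,
    cells_per_field: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial Ki67 field counts whose underlying positive rate equals each
    record's Ki67 index; defaults give 5 x 40 = 200 cells per section."""
    if fields_per_sample < 1:
        raise ValueError("fields_per_sample must be >= 1")
    if cells_per_field < 1:
        raise ValueError("cells_per_field must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in records:
        p = rec.ki67_index / 100.0
        for f in range(fields_per_sample):
            pos = int(rng.binomial(cells_per_field, p))
            rows.append(
                {
                    "sample": rec.sample_id,
                    "field_index": f + 1,
                    "positive": pos,
                    "negative": cells_per_field - pos,
                }
            )
    return pd.DataFrame(rows)


def generate_caf_field_counts(
    records: Sequence[ClinicalRecord],
    risk_labels: Sequence[str],
    fields_per_sample: int = 5,
    mean_low: float = 10.0,
    mean_high: float = 25.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson alpha-SMA-positive fibroblast counts per hot-spot field, with a
    higher mean in high-risk tumours."""
    rng = np.random.default_rng(seed)
    rows = []
    for rec, risk in zip(records, risk_labels):
        lam = mean_high if risk == "high" else mean_low
        for f in range(fields_per_sample):
            rows.append(
                {
                    "sample": rec.sample_id,
                    "field_index": f + 1,
                    "caf_count": int(rng.poisson(lam)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A complete simulated study: cohort, counts, truth, annotation, fields."""

    records: list
    risk_labels: list
    scores: pd.Series
    counts: CountMatrix
    truth: SyntheticTruth
    annotation: pd.DataFrame
    ki67_fields: pd.DataFrame
    caf_fields: pd.DataFrame

    def write(self, outdir) -> dict:
        """Write the fixture bundle (TSV/CSV/JSON) and return the paths."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clinical": outdir / "clinical.csv",
            "counts": outdir / "counts.tsv",
            "lengths": outdir / "gene_lengths.tsv",
            "annotation": outdir / "annotation.tsv",
            "truth": outdir / "truth.json",
            "ki67_fields": outdir / "ki67_field_counts.csv",
            "caf_fields": outdir / "caf_field_counts.csv",
        }
        rows = []
        for rec in self.records:
            rows.append(
                {
                    "id": rec.sample_id,
                    "breed": rec.breed,
                    "age_years": rec.age_years,
                    "sex": rec.sex,
                    "location": rec.location,
                    "follow_up_days": rec.follow_up_days,
                    "status": Status.TO_CSV[rec.status],
                    "grade_two_tier": rec.two_tier_grade,
                    "ki67_index": rec.ki67_index,
                }
            )
        pd.DataFrame(rows).to_csv(paths["clinical"], index=False)
        self.counts.to_tsv(paths["counts"])
        if self.counts.gene_lengths is not None:
            self.counts.gene_lengths.to_csv(paths["lengths"], sep="\t", index_label="gene")
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False, header=False)
        self.truth.to_json(paths["truth"])
        self.ki67_fields.to_csv(paths["ki67_fields"], index=False)
        self.caf_fields.to_csv(paths["caf_fields"], index=False)
        return {k: str(v) for k, v in paths.items()}


def default_truth(
    n_genes: int,
    seed: int,
    n_de: int = 70,
    n_de_down: int = 3,
    de_log2fc: float = 3.0,
    module_sizes: Sequence[int] = (85, 53, 54, 43),
    n_trait_linked: int = 2,
    dispersion: float = 0.1,
) -> SyntheticTruth:
    """Plant DE genes (mostly up in high-risk) and co-expression modules.

    Module and DE gene sets are disjoint; the first ``n_trait_linked``
    modules are coupled to the malignancy score.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    need = n_de + sum(module_sizes)
    if need > n_genes:
        raise ValueError(f"{need} planted genes exceed n_genes={n_genes}")
    chosen = rng.choice(n_genes, size=need, replace=False)
    de_idx = chosen[:n_de]
    de_log2fc_map = {}
    for j, i in enumerate(de_idx):
        sign = -1.0 if j < n_de_down else 1.0
        de_log2fc_map[gene_ids[i]] = sign * de_log2fc
    membership = {}
    offset = n_de
    module_labels = [f"PM{j + 1}" for j in range(len(module_sizes))]
    for label, size in zip(module_labels, module_sizes):
        for i in chosen[offset : offset + size]:
            membership[gene_ids[i]] = label
        offset += size
    return SyntheticTruth(
        de_log2fc=de_log2fc_map,
        module_membership=membership,
        trait_linked_modules=set(module_labels[:n_trait_linked]),
        dispersion=dispersion,
        seed=seed,
    )


def simulate_dataset(
    seed: int = 0,
    n_genes: int = 14000,
    cohort_spec: CohortSpec = CohortSpec(),
    truth: Optional[SyntheticTruth] = None,
    n_annotation_terms: int = 50,
    **counts_kwargs,
) -> SyntheticDataset:
    """Simulate a full study at the default (paper-scale) conditions.

    Sub-seeds for the cohort, counts, annotation and field counts are derived
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    records, risk_labels = generate_cohort(cohort_spec, seed=sub[0])
    scores = pd.Series(
        {r.sample_id: malignancy_score(r).total for r in records}, name="malignancy_score"
    ).astype(float)
    if truth is None:
        truth = default_truth(n_genes, seed=sub[1])
    counts = generate_counts(
        n_genes,
        [r.sample_id for r in records],
        [l == "high" for l in risk_labels],
        truth,
        scores=scores.to_numpy(),
        **counts_kwargs,
    )
    gene_ids = list(counts.gene_ids)
    enriched_target = sorted(truth.de_gene_ids) or None
    annotation = generate_annotation(
        gene_ids,
        n_annotation_terms,
        seed=sub[2],
        enriched_term="T0001" if enriched_target else None,
        enriched_target=enriched_target,
    )
    ki67_fields = generate_field_counts(records, seed=sub[3])
    caf_fields = generate_caf_field_counts(records, risk_labels, seed=sub[4])
    return SyntheticDataset(
        records=records,
        risk_labels=risk_labels,
        scores=scores,
        counts=counts,
        truth=truth,
        annotation=annotation,
        ki67_fields=ki67_fields,
        caf_fields=caf_fields,
    )
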