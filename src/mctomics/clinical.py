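"""Composite clinical malignancy scoring for canine cutaneous mast cell tumours.

A tumour is scored on four axes — two-tier histological grade, post-surgical
survival time, death attributable to the tumour, and the Ki67 proliferation
index — and the sum (range 3–11) dichotomises the cohort into low-risk
(total <= 5) and high-risk (total >= 6) lesions.

Sub-score bands:

==================  =========================================  =====
axis                band                                       score
==================  =========================================  =====
two-tier grade      low-grade                                  1
                    high-grade                                 2
survival time       > 365 days                                 1
                    180–365 days (closed interval)             2
                    < 180 days                                 3
death status        alive or censored (non-MCT death)          0
                    death related to the tumour                3
Ki67 index          < 3 %                                      1
                    3–7 % (closed interval)                    2
                    > 7 %                                      3
==================  =========================================  =====
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Status",
    "ClinicalRecord",
    "MalignancyScore",
    "CohortSummary",
    "survival_score",
    "ki67_score",
    "status_score",
    "grade_score",
    "malignancy_score",
    "classify_risk",
    "score_cohort",
    "read_clinical_csv",
    "write_score_table",
    "load_example_cohort",
    "HIGH_RISK_THRESHOLD",
]

HIGH_RISK_THRESHOLD = 6

#: vital-status vocabulary; CSV files use the two-letter codes.
class Status:
    ALIVE = "alive"
    CENSORED = "censored_non_mct_death"
    DEAD_MCT = "dead_mct"

    ALL = (ALIVE, CENSORED, DEAD_MCT)

    CSV_CODES = {"LA": ALIVE, "CS": CENSORED, "DT": DEAD_MCT}
    TO_CSV = {v: k for k, v in CSV_CODES.items()}


@dataclass(frozen=True)
class ClinicalRecord:
    """One tumour's clinical fields.

    Only ``two_tier_grade``, ``follow_up_days``, ``status`` and ``ki67_index``
    enter the malignancy score; the rest is carried metadata (the three-tier
    Patnaik grade is never scored).
    """

    sample_id: str
    follow_up_days: int
    status: str
    two_tier_grade: int
    ki67_index: float
    age_years: Optional[float] = None
    sex: Optional[str] = None
    location: Optional[str] = None
    breed: Optional[str] = None
    patnaik_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.two_tier_grade not in (1, 2):
            raise ValueError(
                f"{self.sample_id}: two-tier grade must be 1 or 2, got {self.two_tier_grade}"
            )
        if self.follow_up_days < 0:
            raise ValueError(f"{self.sample_id}: negative follow-up time")
        if not 0.0 <= self.ki67_index <= 100.0:
            raise ValueError(
                f"{self.sample_id}: Ki67 index {self.ki67_index} outside [0, 100]"
            )
        if self.status not in Status.ALL:
            raise ValueError(
                f"{self.sample_id}: unknown status {self.status!r}; "
                f"expected one of {Status.ALL}"
            )


@dataclass(frozen=True)
class MalignancyScore:
    """Four sub-scores, their total, and the resulting risk class."""

    sample_id: str
    grade_score: int
    survival_score: int
    status_score: int
    ki67_score: int

    @property
    def total(self) -> int:
        return self.grade_score + self.survival_score + self.status_score + self.ki67_score

    @property
    def risk(self) -> str:
        return classify_risk(self.total)


def survival_score(follow_up_days: int) -> int:
    """Score the post-surgical survival time in days (1, 2 or 3)."""
    if follow_up_days < 0:
        raise ValueError(f"negative follow-up time: {follow_up_days}")
    if follow_up_days > 365:
        return 1
    if follow_up_days >= 180:
        return 2
    return 3


def ki67_score(ki67_index: float) -> int:
    """Score the Ki67 proliferation index, in percent (1, 2 or 3)."""
    if not 0.0 <= ki67_index <= 100.0:
        raise ValueError(f"Ki67 index {ki67_index} outside [0, 100]")
    if ki67_index < 3.0:
        return 1
    if ki67_index <= 7.0:
        return 2
    return 3


def status_score(status: str) -> int:
    """Score the vital status: 3 for tumour-related death, else 0."""
    if status not in Status.ALL:
        raise ValueError(f"unknown status {status!r}; expected one of {Status.ALL}")
    return 3 if status == Status.DEAD_MCT else 0


def grade_score(two_tier_grade: int) -> int:
    """The two-tier grade is used as its own sub-score (1 or 2)."""
    if two_tier_grade not in (1, 2):
        raise ValueError(f"two-tier grade must be 1 or 2, got {two_tier_grade}")
    return two_tier_grade


def classify_risk(total: int) -> str:
    """Dichotomise a total malignancy score: 'low' (<=5) or 'high' (>=6)."""
    if not 3 <= total <= 11:
        raise ValueError(f"total malignancy score {total} outside [3, 11]")
    return "high" if total >= HIGH_RISK_THRESHOLD else "low"


def malignancy_score(record: ClinicalRecord) -> MalignancyScore:
    """Compute all four sub-scores and the composite score for one tumour."""
    return MalignancyScore(
        sample_id=record.sample_id,
        grade_score=grade_score(record.two_tier_grade),
        survival_score=survival_score(record.follow_up_days),
        status_score=status_score(record.status),
        ki67_score=ki67_score(record.ki67_index),
    )


@dataclass
class CohortSummary:
    """Descriptive statistics over a scored cohort (non-missing fields only)."""

    n_samples: int
    n_high_risk: int
    n_low_risk: int
    n_grade_two_tier: Mapping[int, int]
    n_patnaik_grade: Mapping[int, int]
    location_frequencies: Mapping[str, float]
    age_median: Optional[float]
    age_mean: Optional[float]
    ki67_mean: float
    ki67_sd: float
    sex_frequencies: Mapping[str, float] = field(default_factory=dict)


def score_cohort(
    records: Sequence[ClinicalRecord],
) -> tuple[pd.DataFrame, CohortSummary]:
    """Score every record and summarise the cohort.

    Returns a table with one row per sample (sub-scores, total, risk) and a
    :class:`CohortSummary`. The Ki67 standard deviation uses the n-1
    denominator; location and sex frequencies are proportions of samples with
    the field present.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot score an empty cohort")
    scores = [malignancy_score(r) for r in records]
    table = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "grade_score": [s.grade_score for s in scores],
            "survival_score": [s.survival_score for s in scores],
            "status_score": [s.status_score for s in scores],
            "ki67_score": [s.ki67_score for s in scores],
            "total": [s.total for s in scores],
            "risk": [s.risk for s in scores],
        }
    )

    ages = [r.age_years for r in records if r.age_years is not None]
    ki67 = np.array([r.ki67_index for r in records], dtype=float)
    locations = [r.location for r in records if r.location]
    sexes = [r.sex for r in records if r.sex]

    def _freq(values: list) -> dict:
        n = len(values)
        counts = pd.Series(values).value_counts()
        return {k: c / n for k, c in counts.items()}

    grade_counts = pd.Series([r.two_tier_grade for r in records]).value_counts()
    patnaik = [r.patnaik_grade for r in records if r.patnaik_grade is not None]
    patnaik_counts = pd.Series(patnaik).value_counts() if patnaik else pd.Series(dtype=int)

    summary = CohortSummary(
        n_samples=len(records),
        n_high_risk=int((table["risk"] == "high").sum()),
        n_low_risk=int((table["risk"] == "low").sum()),
        n_grade_two_tier={int(k): int(v) for k, v in grade_counts.items()},
        n_patnaik_grade={int(k): int(v) for k, v in patnaik_counts.items()},
        location_frequencies=_freq(locations) if locations else {},
        age_median=float(np.median(ages)) if ages else None,
        age_mean=float(np.mean(ages)) if ages else None,
        ki67_mean=float(ki67.mean()),
        ki67_sd=float(ki67.std(ddof=1)) if len(ki67) > 1 else 0.0,
        sex_frequencies=_freq(sexes) if sexes else {},
    )
    return table, summary


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Read a clinical cohort CSV.

    Required columns: ``id``, ``grade_two_tier``, ``follow_up_days``,
    ``status`` (LA = alive, CS = censored non-MCT death, DT = MCT-related
    death; long-form labels are also accepted) and ``ki67_index`` (percent).
    Optional: ``age_years``, ``sex``, ``location``, ``breed``,
    ``patnaik_grade``.
    """
    df = pd.read_csv(path)
    required = {"id", "grade_two_tier", "follow_up_days", "status", "ki67_index"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV {path} missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        raw_status = str(row["status"]).strip()
        status = Status.CSV_CODES.get(raw_status.upper(), raw_status)
        try:
            rec = ClinicalRecord(
                sample_id=str(row["id"]),
                follow_up_days=int(row["follow_up_days"]),
                status=status,
                two_tier_grade=int(row["grade_two_tier"]),
                ki67_index=float(str(row["ki67_index"]).rstrip("%")),
                age_years=float(row["age_years"]) if "age_years" in df and pd.notna(row.get("age_years")) else None,
                sex=str(row["sex"]) if "sex" in df and pd.notna(row.get("sex")) else None,
                location=str(row["location"]) if "location" in df and pd.notna(row.get("location")) else None,
                breed=str(row["breed"]) if "breed" in df and pd.notna(row.get("breed")) else None,
                patnaik_grade=int(row["patnaik_grade"]) if "patnaik_grade" in df and pd.notna(row.get("patnaik_grade")) else None,
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"clinical CSV {path}, row {i + 2}: {exc}") from exc
        records.append(rec)
    return records


def write_score_table(table: pd.DataFrame, path) -> None:
    """Write the per-sample score table (sub-scores, total, risk) as TSV."""
    table.to_csv(path, sep="\t", index=False)


def load_example_cohort() -> list[ClinicalRecord]:
    """The bundled 15-dog example cohort shipped with the package."""
    from importlib.resources import files

    return read_clinical_csv(files("mctomics.data").joinpath("clinical_table1.csv"))
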