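"""Annual glaucoma consultation counts and surgery incidence.

Consultations are counted per exam category — (1) general eye examination
(ophthalmoscopy and tonometry), (2) perimetry, (3) optical coherence
tomography — over the 12 months after the index date and bucketed
(none / 1-3 / 4-6 / 7-9 / 10-12 / >12 times). Surgery incidence is the
first glaucoma surgery (laser included) within 12 months post-index,
expressed as a percent of patients and as events per 100 person-years of
observation, with person-time censored at first surgery or day 365.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import EXAM_CATEGORIES, ProcedureCategory

DAYS_PER_YEAR = 365.25


class CountBucket(str, enum.Enum):
    NONE = "NONE"
    FROM1TO3 = "1TO3"
    FROM4TO6 = "4TO6"
    FROM7TO9 = "7TO9"
    FROM10TO12 = "10TO12"
    GT12 = "GT12"


def bucket_count(count: int) -> CountBucket:
    if count < 0:
        raise ValueError("count must be nonnegative")
    if count == 0:
        return CountBucket.NONE
    if count <= 3:
        return CountBucket.FROM1TO3
    if count <= 6:
        return CountBucket.FROM4TO6
    if count <= 9:
        return CountBucket.FROM7TO9
    if count <= 12:
        return CountBucket.FROM10TO12
    return CountBucket.GT12


@dataclass(frozen=True)
class ExamCounts:
    patient_id: str
    ophthalmoscopy_tonometry: int
    perimetry: int
    oct: int

    def count(self, category: ProcedureCategory) -> int:
        return {
            ProcedureCategory.OPHTHALMOSCOPY_TONOMETRY: self.ophthalmoscopy_tonometry,
            ProcedureCategory.PERIMETRY: self.perimetry,
            ProcedureCategory.OCT: self.oct,
        }[category]

    def bucket(self, category: ProcedureCategory) -> CountBucket:
        return bucket_count(self.count(category))


@dataclass(frozen=True)
class SurgeryOutcome:
    patient_id: str
    surgery_date: date | None
    person_years: float


def count_exams(
    procedures: Iterable[tuple[date, ProcedureCategory]],
    patient_id: str,
    index_date: date,
    window_days: int = 365,
) -> ExamCounts:
    """Per-category exam counts in ``[index, index + window_days - 1]``."""
    counts = {cat: 0 for cat in EXAM_CATEGORIES}
    for day, cat in procedures:
        if not isinstance(cat, ProcedureCategory):
            raise ValueError(f"{patient_id}: unknown procedure category {cat!r}")
        rel = (day - index_date).days
        if cat in counts and 0 <= rel < window_days:
            counts[cat] += 1
    return ExamCounts(
        patient_id=patient_id,
        ophthalmoscopy_tonometry=counts[ProcedureCategory.OPHTHALMOSCOPY_TONOMETRY],
        perimetry=counts[ProcedureCategory.PERIMETRY],
        oct=counts[ProcedureCategory.OCT],
    )


def surgery_outcome(
    procedures: Iterable[tuple[date, ProcedureCategory]],
    patient_id: str,
    index_date: date,
    window_days: int = 365,
) -> SurgeryOutcome:
    """First post-index surgery within the window and the patient's person-time.

    Person-time runs from index to first surgery, capped at ``window_days``
    (1.0 years at the default) for surgery-free patients.
    """
    first: date | None = None
    for day, cat in procedures:
        rel = (day - index_date).days
        if cat is ProcedureCategory.SURGERY and 0 <= rel < window_days:
            if first is None or day < first:
                first = day
    if first is None:
        return SurgeryOutcome(patient_id, None, window_days / DAYS_PER_YEAR)
    return SurgeryOutcome(patient_id, first, (first - index_date).days / DAYS_PER_YEAR)


def surgery_incidence(
    outcomes: Sequence[SurgeryOutcome],
) -> tuple[int, float, float]:
    """(n_events, percent of patients, events per 100 person-years)."""
    if not outcomes:
        raise ValueError("surgery_incidence requires a non-empty cohort")
    n_events = sum(1 for o in outcomes if o.surgery_date is not None)
    total_py = sum(o.person_years for o in outcomes)
    percent = 100.0 * n_events / len(outcomes)
    rate = 100.0 * n_events / total_py if total_py > 0 else 0.0
    return n_events, percent, rate


def summarize_exams(
    exam_counts_by_cohort: Mapping[str, Sequence[ExamCounts]],
) -> pd.DataFrame:
    """Consultation-rate summary: mean, SD and bucket counts per category."""
    rows = []
    for cohort, counts in exam_counts_by_cohort.items():
        if not counts:
            raise ValueError(f"cohort {cohort!r} is empty")
        for cat in EXAM_CATEGORIES:
            values = np.array([c.count(cat) for c in counts])
            row: dict[str, object] = {
                "cohort": cohort,
                "category": cat.value,
                "n": len(values),
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            }
            for bucket in CountBucket:
                row[f"n_{bucket.value}"] = int(
                    sum(c.bucket(cat) is bucket for c in counts)
                )
            rows.append(row)
    return pd.DataFrame(rows)
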