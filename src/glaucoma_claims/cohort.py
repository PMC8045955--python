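"""New-user cohort construction with guideline-compliance classification.

The index date is a patient's first dispensing of any topical IOP-lowering
medication. New users must be observable and glaucoma-treatment-free for a
washout period (~12 months) before index, carry a glaucoma diagnosis (ICD-10
H401/H409), have no glaucoma surgery — laser included — on or before index,
and remain observable for 12 months after index.

Eligible patients are assigned by their first-line regimen:

* GL_NONCOMPLIANT — a fixed combination at index (guidelines recommend
  starting with a single agent);
* GL_COMPLIANT — a monotherapy at index whose first regimen change within
  the compliance window is to a fixed combination (mono-to-mono switches
  keep the patient a compliant candidate);
* OTHER — everything else: unfixed starters, mono starters who switch to
  unfixed combinations, and mono starters who never step up.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

import pandas as pd

from .adherence import PharmacyClaim
from .codes import GLAUCOMA_ICD10, ProcedureCategory
from .formulary import Formulary, Regimen, classify_regimen


class Eligibility(str, enum.Enum):
    ELIGIBLE = "ELIGIBLE"
    EXCLUDED = "EXCLUDED"


class ExclusionReason(str, enum.Enum):
    NO_RX = "NO_RX"
    NO_GLAUCOMA_DX = "NO_GLAUCOMA_DX"
    SHORT_WASHOUT = "SHORT_WASHOUT"
    PRIOR_SURGERY = "PRIOR_SURGERY"
    SHORT_FOLLOWUP = "SHORT_FOLLOWUP"


class Cohort(str, enum.Enum):
    GL_COMPLIANT = "GL_COMPLIANT"
    GL_NONCOMPLIANT = "GL_NONCOMPLIANT"
    OTHER = "OTHER"


@dataclass(frozen=True)
class CohortConfig:
    washout_days: int = 365
    followup_days: int = 365
    compliance_window_days: int = 365

    def __post_init__(self) -> None:
        if min(self.washout_days, self.followup_days, self.compliance_window_days) <= 0:
            raise ValueError("all cohort window lengths must be positive")


@dataclass
class PatientTimeline:
    """Everything known about one patient, date-sorted."""

    patient_id: str
    claims: list[PharmacyClaim] = field(default_factory=list)
    diagnoses: list[tuple[date, str]] = field(default_factory=list)
    procedures: list[tuple[date, ProcedureCategory]] = field(default_factory=list)
    obs_start: date | None = None
    obs_end: date | None = None


@dataclass
class CohortAssignment:
    patient_id: str
    index_date: date | None
    eligibility: Eligibility
    exclusion_reason: ExclusionReason | None = None
    cohort: Cohort | None = None
    first_line_regimen: Regimen | None = None
    first_line_products: tuple[str, ...] = ()
    second_line_start: date | None = None


def find_index_date(
    claims: Iterable[PharmacyClaim], formulary: Formulary
) -> date | None:
    """Earliest dispense date of any formulary product, or None.

    Every product code must resolve in the formulary; an unknown code
    raises, naming the code.
    """
    index: date | None = None
    for claim in claims:
        formulary[claim.product_code]  # raises FormularyError on unknown code
        if index is None or claim.dispense_date < index:
            index = claim.dispense_date
    return index


def screen_eligibility(
    timeline: PatientTimeline,
    index_date: date,
    config: CohortConfig = CohortConfig(),
) -> tuple[Eligibility, ExclusionReason | None]:
    """Apply the attrition rules in flowchart order; report the first failure.

    Order: glaucoma diagnosis anywhere in the record, then washout
    (observable pre-index span and no pre-index glaucoma fill), then prior
    surgery on or before index, then the 12-month follow-up requirement.
    """
    if not any(code in GLAUCOMA_ICD10 for _, code in timeline.diagnoses):
        return Eligibility.EXCLUDED, ExclusionReason.NO_GLAUCOMA_DX
    if timeline.obs_start is None or timeline.obs_end is None:
        raise ValueError(f"{timeline.patient_id}: missing observability window")
    if (index_date - timeline.obs_start).days < config.washout_days:
        return Eligibility.EXCLUDED, ExclusionReason.SHORT_WASHOUT
    if any(c.dispense_date < index_date for c in timeline.claims):
        return Eligibility.EXCLUDED, ExclusionReason.SHORT_WASHOUT
    if any(
        cat is ProcedureCategory.SURGERY and day <= index_date
        for day, cat in timeline.procedures
    ):
        return Eligibility.EXCLUDED, ExclusionReason.PRIOR_SURGERY
    if (timeline.obs_end - index_date).days < config.followup_days:
        return Eligibility.EXCLUDED, ExclusionReason.SHORT_FOLLOWUP
    return Eligibility.ELIGIBLE, None


def _fills_by_day(
    claims: Sequence[PharmacyClaim], formulary: Formulary
) -> list[tuple[date, list]]:
    by_day: dict[date, dict[str, object]] = {}
    for c in claims:
        by_day.setdefault(c.dispense_date, {})[c.product_code] = formulary[c.product_code]
    return [(day, list(by_day[day].values())) for day in sorted(by_day)]


def assign_cohort(
    timeline: PatientTimeline,
    index_date: date,
    formulary: Formulary,
    config: CohortConfig = CohortConfig(),
) -> CohortAssignment:
    """Classify an eligible patient's first-line path.

    A fixed-combination start is guideline-noncompliant. A monotherapy
    start is scanned forward: mono-to-mono switches continue the scan; the
    first change to a fixed combination within the compliance window makes
    the patient guideline-compliant (recording the second-line start); a
    change to an unfixed combination, or no step-up at all, routes the
    patient to OTHER.
    """
    days = _fills_by_day(timeline.claims, formulary)
    index_products = [p for day, prods in days if day == index_date for p in prods]
    if not index_products:
        raise ValueError(f"{timeline.patient_id}: no dispensing on index date")
    first = classify_regimen(index_products)
    assignment = CohortAssignment(
        patient_id=timeline.patient_id,
        index_date=index_date,
        eligibility=Eligibility.ELIGIBLE,
        first_line_regimen=first,
        first_line_products=tuple(sorted(p.product_code for p in index_products)),
    )
    if first is Regimen.FIXED:
        assignment.cohort = Cohort.GL_NONCOMPLIANT
        return assignment
    if first is Regimen.UNFIXED:
        assignment.cohort = Cohort.OTHER
        return assignment
    window_end = index_date + timedelta(days=config.compliance_window_days)
    for day, prods in days:
        if day <= index_date or day > window_end:
            continue
        regimen = classify_regimen(prods)
        if regimen is Regimen.MONO:
            continue  # mono-to-mono: still adherent to first-line monotherapy
        if regimen is Regimen.FIXED:
            assignment.cohort = Cohort.GL_COMPLIANT
            assignment.second_line_start = day
        else:
            assignment.cohort = Cohort.OTHER
        return assignment
    assignment.cohort = Cohort.OTHER  # compliant candidate, never stepped up
    return assignment


def build_assignment(
    timeline: PatientTimeline,
    formulary: Formulary,
    config: CohortConfig = CohortConfig(),
) -> CohortAssignment:
    """Index date, eligibility screen and cohort label for one patient."""
    index_date = find_index_date(timeline.claims, formulary)
    if index_date is None:
        return CohortAssignment(
            patient_id=timeline.patient_id,
            index_date=None,
            eligibility=Eligibility.EXCLUDED,
            exclusion_reason=ExclusionReason.NO_RX,
        )
    eligibility, reason = screen_eligibility(timeline, index_date, config)
    if eligibility is Eligibility.EXCLUDED:
        return CohortAssignment(
            patient_id=timeline.patient_id,
            index_date=index_date,
            eligibility=eligibility,
            exclusion_reason=reason,
        )
    return assign_cohort(timeline, index_date, formulary, config)


def timelines_from_tables(
    pharmacy: pd.DataFrame,
    diagnosis: pd.DataFrame,
    procedure: pd.DataFrame,
    coverage: pd.DataFrame,
) -> dict[str, PatientTimeline]:
    """Assemble per-patient timelines from the input tables.

    Patients are the union of ids across tables; the coverage table gives
    each patient's observability window (claims absence outside it is
    uninformative).
    """
    timelines: dict[str, PatientTimeline] = {}

    def get(pid: str) -> PatientTimeline:
        if pid not in timelines:
            timelines[pid] = PatientTimeline(patient_id=pid)
        return timelines[pid]

    for row in pharmacy.itertuples(index=False):
        get(str(row.patient_id)).claims.append(
            PharmacyClaim(
                patient_id=str(row.patient_id),
                dispense_date=pd.Timestamp(row.dispense_date).date(),
                product_code=str(row.product_code),
                quantity_ml=float(row.quantity_ml),
                period_field=str(row.period_field),
            )
        )
    for row in diagnosis.itertuples(index=False):
        get(str(row.patient_id)).diagnoses.append(
            (pd.Timestamp(row.diagnosis_date).date(), str(row.icd10_code))
        )
    for row in procedure.itertuples(index=False):
        get(str(row.patient_id)).procedures.append(
            (pd.Timestamp(row.procedure_date).date(), ProcedureCategory(str(row.category)))
        )
    for row in coverage.itertuples(index=False):
        tl = get(str(row.patient_id))
        tl.obs_start = pd.Timestamp(row.obs_start).date()
        tl.obs_end = pd.Timestamp(row.obs_end).date()
    for tl in timelines.values():
        tl.claims.sort(key=lambda c: (c.dispense_date, c.product_code))
        tl.diagnoses.sort()
        tl.procedures.sort()
    return timelines


def attrition_report(assignments: Sequence[CohortAssignment]) -> pd.DataFrame:
    """Ordered attrition counts mirroring the extraction flowchart.

    Percentages of the cohort rows are relative to the analyzed (eligible)
    population.
    """
    n_total = len(assignments)
    reasons = {r: 0 for r in ExclusionReason}
    cohorts = {c: 0 for c in Cohort}
    for a in assignments:
        if a.eligibility is Eligibility.EXCLUDED:
            reasons[a.exclusion_reason] += 1
        else:
            cohorts[a.cohort] += 1
    n_eligible = sum(cohorts.values())
    n_mono_starters = sum(
        1
        for a in assignments
        if a.eligibility is Eligibility.ELIGIBLE and a.first_line_regimen is Regimen.MONO
    )
    rows = [
        {"stage": "extracted", "n": n_total, "pct_of_analyzed": None},
        *(
            {"stage": f"excluded_{r.value.lower()}", "n": reasons[r], "pct_of_analyzed": None}
            for r in ExclusionReason
        ),
        {
            "stage": "analyzed",
            "n": n_eligible,
            "pct_of_analyzed": 100.0 if n_eligible else 0.0,
        },
        {
            "stage": "first_line_monotherapy",
            "n": n_mono_starters,
            "pct_of_analyzed": 100.0 * n_mono_starters / n_eligible if n_eligible else 0.0,
        },
        *(
            {
                "stage": c.value.lower(),
                "n": cohorts[c],
                "pct_of_analyzed": 100.0 * cohorts[c] / n_eligible if n_eligible else 0.0,
            }
            for c in Cohort
        ),
    ]
    return pd.DataFrame(rows)
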