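"""End-to-end study pipeline: simulate -> cohorts -> PDC -> persistence ->
utilization -> factor screen, collected into a single report.

The report mirrors the structure of a first-line glaucoma therapy claims
study: an attrition flowchart, per-cohort adherence (PDC) summaries with a
t test on means and a chi-square on the 80% adherence split, a
representative-pattern subset comparison (latanoprost stepping up to
latanoprost/timolol versus first-line latanoprost/timolol), Kaplan–Meier
persistence with 6- and 12-month Wald CIs and a log-rank comparison,
consultation and surgery utilization, and the stepwise logistic screen for
factors associated with guideline noncompliance. Every p-value carries its
Bonferroni verdict at the study's m = 6 threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from .adherence import (
    PDCResult,
    PharmacyClaim,
    build_supply_intervals,
    compute_pdc,
    summarize_pdc,
)
from .cohort import (
    Cohort,
    CohortAssignment,
    CohortConfig,
    Eligibility,
    attrition_report,
    build_assignment,
    timelines_from_tables,
)
from .persistence import (
    KMEstimate,
    PersistenceRecord,
    hall_wellner_band,
    km_fit,
    logrank,
    persistence_at,
    time_to_discontinuation,
)
from .screening import (
    StatsConfig,
    bonferroni_significant,
    chi_square_2x2,
    screen_to_frame,
    stepwise_logistic,
    two_sample_t,
    univariate_screen,
)
from .synthetic import SimulatedData, SimulationConfig, generate
from .utilization import (
    count_exams,
    summarize_exams,
    surgery_incidence,
    surgery_outcome,
)

logger = logging.getLogger("glaucoma_claims")

SIX_MONTHS_DAYS = 183
TWELVE_MONTHS_DAYS = 365


class StudyConfig(BaseModel):
    """One document driving the whole pipeline.

    The constants of the method are all here by name: the 365-day washout,
    follow-up and PDC window, the 30-day grace period, the 7-bottle
    bilateral threshold (in the adherence module), the 80% adherence
    cutoff, the 0.1 univariate screen and the m = 6 Bonferroni rule.
    """

    simulation: SimulationConfig
    washout_days: int = 365
    followup_days: int = 365
    compliance_window_days: int = 365
    grace_days: int = 30
    pdc_window_days: int = 365
    subset_mono_generic: str = "latanoprost"
    subset_fixed_generic: str = "latanoprost/timolol"
    m_tests: int = 6
    alpha: float = 0.05

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            washout_days=self.washout_days,
            followup_days=self.followup_days,
            compliance_window_days=self.compliance_window_days,
        )

    def stats_config(self) -> StatsConfig:
        return StatsConfig(m_tests=self.m_tests, alpha=self.alpha)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    bonferroni_significant: bool


@dataclass
class CohortPersistence:
    estimate: KMEstimate
    persistence_6m: tuple[float, float, float]
    persistence_12m: tuple[float, float, float]
    records: list[PersistenceRecord] = field(repr=False, default_factory=list)


@dataclass
class StudyReport:
    attrition: pd.DataFrame
    pdc_summary: pd.DataFrame
    pdc_t_test: ComparisonResult
    pdc_chi2: ComparisonResult
    subset_summary: pd.DataFrame
    subset_t_test: Optional[ComparisonResult]
    subset_chi2: Optional[ComparisonResult]
    persistence: dict[str, CohortPersistence]
    logrank_test: ComparisonResult
    exam_summary: pd.DataFrame
    surgery: pd.DataFrame
    screen: pd.DataFrame

    def to_dict(self) -> dict:
        def comp(c: Optional[ComparisonResult]) -> Optional[dict]:
            if c is None:
                return None
            return {
                "test": c.test,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "bonferroni_significant": c.bonferroni_significant,
            }

        persistence = {}
        for cohort, cp in self.persistence.items():
            hw_low, hw_high, hw_flag = hall_wellner_band(cp.estimate)
            persistence[cohort] = {
                "event_times": cp.estimate.event_times.tolist(),
                "survival": cp.estimate.survival.tolist(),
                "ci_low": cp.estimate.ci_low.tolist(),
                "ci_high": cp.estimate.ci_high.tolist(),
                "hall_wellner_low": hw_low.tolist(),
                "hall_wellner_high": hw_high.tolist(),
                "hall_wellner_degenerate": hw_flag,
                "persistence_6m_percent": cp.persistence_6m,
                "persistence_12m_percent": cp.persistence_12m,
                "n_subjects": cp.estimate.n_subjects,
            }
        return {
            "attrition": self.attrition.to_dict(orient="records"),
            "pdc_summary": self.pdc_summary.to_dict(orient="records"),
            "pdc_t_test": comp(self.pdc_t_test),
            "pdc_chi2": comp(self.pdc_chi2),
            "subset_summary": self.subset_summary.to_dict(orient="records"),
            "subset_t_test": comp(self.subset_t_test),
            "subset_chi2": comp(self.subset_chi2),
            "persistence": persistence,
            "logrank": comp(self.logrank_test),
            "exam_summary": self.exam_summary.to_dict(orient="records"),
            "surgery": self.surgery.to_dict(orient="records"),
            "screen": self.screen.to_dict(orient="records"),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))


def _adherence_split(results: list[PDCResult]) -> tuple[int, int]:
    adherent = sum(1 for r in results if r.pdc_percent >= 80.0)
    return adherent, len(results) - adherent


def _compare_pdc(
    a: list[PDCResult], b: list[PDCResult], stats_cfg: StatsConfig
) -> tuple[ComparisonResult, ComparisonResult]:
    va = np.array([r.pdc_percent for r in a])
    vb = np.array([r.pdc_percent for r in b])
    t, _, p_t = two_sample_t(
        float(va.mean()), float(va.std(ddof=1)), len(va),
        float(vb.mean()), float(vb.std(ddof=1)), len(vb),
        stats_cfg.t_test_variant,
    )
    a1, a0 = _adherence_split(a)
    b1, b0 = _adherence_split(b)
    chi2, p_c = chi_square_2x2(a1, a0, b1, b0, stats_cfg.chi_square_continuity_correction)
    return (
        ComparisonResult("t_test_pooled", t, p_t, bonferroni_significant(p_t, stats_cfg)),
        ComparisonResult("pearson_chi2", chi2, p_c, bonferroni_significant(p_c, stats_cfg)),
    )


def run_study(config: StudyConfig, data: Optional[SimulatedData] = None) -> StudyReport:
    """Execute every stage on simulated (or supplied) data.

    ``data`` defaults to a fresh simulation from ``config.simulation``;
    pass pre-generated tables to rerun the analysis stages only.
    """
    if data is None:
        data = generate(config.simulation)
    formulary = data.formulary
    cohort_cfg = config.cohort_config()
    stats_cfg = config.stats_config()

    timelines = timelines_from_tables(
        data.pharmacy, data.diagnosis, data.procedure, data.coverage
    )
    assignments: list[CohortAssignment] = [
        build_assignment(tl, formulary, cohort_cfg)
        for tl in sorted(timelines.values(), key=lambda t: t.patient_id)
    ]
    attrition = attrition_report(assignments)
    for row in attrition.itertuples(index=False):
        logger.info("attrition: %-28s %6d", row.stage, row.n)

    analyzed = {
        a.patient_id: a
        for a in assignments
        if a.eligibility is Eligibility.ELIGIBLE
        and a.cohort in (Cohort.GL_COMPLIANT, Cohort.GL_NONCOMPLIANT)
    }
    pdc_by_cohort: dict[str, list[PDCResult]] = {
        Cohort.GL_COMPLIANT.value: [],
        Cohort.GL_NONCOMPLIANT.value: [],
    }
    records_by_cohort: dict[str, list[PersistenceRecord]] = {
        Cohort.GL_COMPLIANT.value: [],
        Cohort.GL_NONCOMPLIANT.value: [],
    }
    exams_by_cohort: dict[str, list] = {
        Cohort.GL_COMPLIANT.value: [],
        Cohort.GL_NONCOMPLIANT.value: [],
    }
    surgery_rows = []
    surgery_by_cohort: dict[str, list] = {
        Cohort.GL_COMPLIANT.value: [],
        Cohort.GL_NONCOMPLIANT.value: [],
    }

    for pid, a in analyzed.items():
        tl = timelines[pid]
        post = [c for c in tl.claims if c.dispense_date >= a.index_date]
        intervals = build_supply_intervals(post, formulary, scope="all")
        pdc_by_cohort[a.cohort.value].append(
            compute_pdc(intervals, a.index_date, config.pdc_window_days)
        )
        records_by_cohort[a.cohort.value].append(
            time_to_discontinuation(
                post, formulary, a.index_date, a.first_line_regimen,
                grace_days=config.grace_days, horizon_days=config.followup_days,
            )
        )
        exams_by_cohort[a.cohort.value].append(
            count_exams(tl.procedures, pid, a.index_date, config.followup_days)
        )
        surgery_by_cohort[a.cohort.value].append(
            surgery_outcome(tl.procedures, pid, a.index_date, config.followup_days)
        )

    for cohort, results in pdc_by_cohort.items():
        if not results:
            raise RuntimeError(f"stage pdc: cohort {cohort} is empty")

    pdc_summary = summarize_pdc(pdc_by_cohort)
    pdc_t, pdc_chi2 = _compare_pdc(
        pdc_by_cohort[Cohort.GL_COMPLIANT.value],
        pdc_by_cohort[Cohort.GL_NONCOMPLIANT.value],
        stats_cfg,
    )

    # representative-pattern subset: mono starter on the chosen generic who
    # stepped up to the chosen fixed combination, vs first-line starters on
    # that same fixed combination
    def generic_of(codes: tuple[str, ...]) -> str:
        return formulary[codes[0]].generic_name if len(codes) == 1 else ""

    subset_mono_ids = [
        pid for pid, a in analyzed.items()
        if a.cohort is Cohort.GL_COMPLIANT
        and generic_of(a.first_line_products) == config.subset_mono_generic
        and a.second_line_start is not None
        and any(
            c.dispense_date == a.second_line_start
            and formulary[c.product_code].generic_name == config.subset_fixed_generic
            for c in timelines[pid].claims
        )
    ]
    subset_fixed_ids = [
        pid for pid, a in analyzed.items()
        if a.cohort is Cohort.GL_NONCOMPLIANT
        and generic_of(a.first_line_products) == config.subset_fixed_generic
    ]
    idx_of = {
        cohort: {r.patient_id: r for r in results}
        for cohort, results in pdc_by_cohort.items()
    }
    subset_mono = [idx_of[Cohort.GL_COMPLIANT.value][p] for p in subset_mono_ids]
    subset_fixed = [idx_of[Cohort.GL_NONCOMPLIANT.value][p] for p in subset_fixed_ids]
    if subset_mono and subset_fixed:
        subset_summary = summarize_pdc(
            {"mono_then_fixed": subset_mono, "first_line_fixed": subset_fixed}
        )
        subset_t, subset_chi2 = _compare_pdc(subset_mono, subset_fixed, stats_cfg)
    else:
        subset_summary = pd.DataFrame()
        subset_t = subset_chi2 = None

    persistence: dict[str, CohortPersistence] = {}
    for cohort, records in records_by_cohort.items():
        est = km_fit(records)
        persistence[cohort] = CohortPersistence(
            estimate=est,
            persistence_6m=persistence_at(est, SIX_MONTHS_DAYS),
            persistence_12m=persistence_at(est, TWELVE_MONTHS_DAYS),
            records=records,
        )
    lr_chi2, lr_p = logrank(
        records_by_cohort[Cohort.GL_COMPLIANT.value],
        records_by_cohort[Cohort.GL_NONCOMPLIANT.value],
    )
    lr = ComparisonResult(
        "logrank", lr_chi2, lr_p, bonferroni_significant(lr_p, stats_cfg)
    )

    exam_summary = summarize_exams(exams_by_cohort)
    for cohort, outcomes in surgery_by_cohort.items():
        n_events, percent, rate = surgery_incidence(outcomes)
        surgery_rows.append(
            {
                "cohort": cohort,
                "n": len(outcomes),
                "n_events": n_events,
                "percent": percent,
                "rate_per_100_pyo": rate,
            }
        )
    surgery = pd.DataFrame(surgery_rows)

    checkup = data.checkup.set_index("patient_id")
    screen_ids = [pid for pid in analyzed if pid in checkup.index]
    covariate_cols = [
        c for c in checkup.columns if c not in ("checkup_date",)
    ]
    covariates = checkup.loc[screen_ids, covariate_cols]
    outcome = pd.Series(
        [int(analyzed[pid].cohort is Cohort.GL_NONCOMPLIANT) for pid in screen_ids],
        index=covariates.index,
    )
    screened = univariate_screen(covariates, outcome, stats_cfg)
    final = stepwise_logistic(covariates, outcome, screened, stats_cfg)
    screen = screen_to_frame(final)

    return StudyReport(
        attrition=attrition,
        pdc_summary=pdc_summary,
        pdc_t_test=pdc_t,
        pdc_chi2=pdc_chi2,
        subset_summary=subset_summary,
        subset_t_test=subset_t,
        subset_chi2=subset_chi2,
        persistence=persistence,
        logrank_test=lr,
        exam_summary=exam_summary,
        surgery=surgery,
        screen=screen,
    )


def fixture_report() -> dict:
    """The documentation example: packaged fixtures through the pipeline.

    Runs the worked one-patient claims table through the bottle/supply
    conversion and the two published 2x2 adherence tables through the
    chi-square comparison.
    """
    from .formulary import default_formulary
    from .synthetic import inject_worked_example

    formulary = default_formulary()
    pharmacy = inject_worked_example()
    claims = [
        PharmacyClaim(
            patient_id=str(r.patient_id),
            dispense_date=pd.Timestamp(r.dispense_date).date(),
            product_code=str(r.product_code),
            quantity_ml=float(r.quantity_ml),
            period_field=str(r.period_field),
        )
        for r in pharmacy.itertuples(index=False)
    ]
    intervals = build_supply_intervals(claims, formulary)
    index_date = min(c.dispense_date for c in claims)
    pdc = compute_pdc(intervals, index_date)
    chi2_overall, p_overall = chi_square_2x2(483, 700, 235, 307)
    chi2_subset, p_subset = chi_square_2x2(76, 113, 71, 56)
    cfg = StatsConfig()
    return {
        "worked_claim_bottles": 3,
        "worked_claim_days_supplied": (intervals[0].end - intervals[0].start).days + 1,
        "bilateral_claim_eyes": intervals[-1].eyes,
        "intervals": [
            {
                "start": str(iv.start),
                "end": str(iv.end),
                "n_bottles": iv.n_bottles,
                "eyes": iv.eyes,
            }
            for iv in intervals
        ],
        "pdc_percent": pdc.pdc_percent,
        "chi2_adherence_overall": {"chi2": chi2_overall, "p": round(p_overall, 4)},
        "chi2_adherence_subset": {"chi2": chi2_subset, "p": round(p_subset, 4)},
        "bonferroni_threshold": cfg.bonferroni_threshold,
    }
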