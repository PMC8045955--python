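"""Synthetic pharmacy-claims generator with known ground truth.

Emulates the structure of a Japanese employment-based claims database for
the glaucoma first-line-therapy analysis: per-patient refill streams driven
by a latent adherence propensity theta (gaps inflate by 1/theta), a latent
discontinuation day from a constant daily hazard, guideline-compliant
(mono then fixed-combination), guideline-noncompliant (fixed first), other
(mono only, or mono then unfixed) and ineligible paths, plus diagnosis,
procedure (exams and rare surgery), health-checkup and observability
tables. Every latent quantity is recorded in a ground-truth table so each
downstream stage can be validated against what was simulated.

Default mixing weights and product frequencies reflect the published
first-line landscape for Japanese glaucoma care (prostaglandin analogs
dominate monotherapy; dorzolamide/timolol and latanoprost/timolol dominate
fixed combinations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .adherence import days_supplied
from .codes import ProcedureCategory
from .formulary import Formulary, default_formulary
from .tables import write_table

#: First-line monotherapy frequencies (prostaglandins ~70%, beta blockers
#: ~24%, the rest rare).
DEFAULT_MONO_DISTRIBUTION = {
    "latanoprost": 0.329,
    "tafluprost": 0.206,
    "travoprost": 0.139,
    "bimatoprost": 0.033,
    "timolol": 0.140,
    "carteolol": 0.098,
    "dorzolamide": 0.020,
    "brimonidine": 0.020,
    "ripasudil": 0.015,
}

#: First-line fixed-combination frequencies.
DEFAULT_FIXED_DISTRIBUTION = {
    "dorzolamide/timolol": 0.423,
    "latanoprost/timolol": 0.234,
    "travoprost/timolol": 0.203,
    "brinzolamide/timolol": 0.140,
}

#: Second-line fixed combination chosen at a guideline-compliant switch
#: (prostaglandin/beta-blocker combinations dominate).
DEFAULT_SECOND_LINE_DISTRIBUTION = {
    "latanoprost/timolol": 0.50,
    "travoprost/timolol": 0.20,
    "dorzolamide/timolol": 0.20,
    "brinzolamide/timolol": 0.10,
}

INELIGIBLE_RULES = ("SHORT_WASHOUT", "PRIOR_SURGERY", "SHORT_FOLLOWUP")

_EXTRACTION_START = date(2012, 4, 1)
_INDEX_SPAN_DAYS = 1095  # index dates over three years of the extraction window


class SimulationConfig(BaseModel):
    """Study conditions for the generator.

    The cohort mix gives, within the eligible population, the published
    10.1% / 4.6% / 85.3% split between guideline-compliant, noncompliant
    and other first-line paths, with a 20% ineligible arm on top.
    """

    n_patients: int = Field(gt=0)
    seed: int = 0
    cohort_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "compliant": 0.0808,
            "noncompliant": 0.0368,
            "other": 0.6824,
            "ineligible": 0.2,
        }
    )
    first_line_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MONO_DISTRIBUTION)
    )
    fixed_first_line_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FIXED_DISTRIBUTION)
    )
    second_line_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SECOND_LINE_DISTRIBUTION)
    )
    adherence_alpha: float = Field(default=2.0, gt=0)
    adherence_beta: float = Field(default=1.0, gt=0)
    adherence_fixed_theta: Optional[float] = Field(default=None, gt=0, le=1)
    discontinuation_hazard_per_day: float = Field(default=0.003, ge=0)
    switch_probability: float = Field(default=1.0, ge=0, le=1)
    switch_day_min: int = Field(default=30, ge=1)
    switch_day_max: int = Field(default=330, le=365)
    unfixed_switch_fraction: float = Field(default=0.09, ge=0, le=1)
    bottles_per_fill: dict[int, float] = Field(
        default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2}
    )
    bilateral_fraction: float = Field(default=0.10, ge=0, le=1)
    exam_rate_per_year: dict[str, float] = Field(
        default_factory=lambda: {
            "OPHTHALMOSCOPY_TONOMETRY": 5.0,
            "PERIMETRY": 0.04,
            "OCT": 1.2,
        }
    )
    surgery_probability_12m: float = Field(default=0.015, ge=0, le=1)
    diagnosis_h401_probability: float = Field(default=0.8, ge=0, le=1)
    checkup_missingness: float = Field(default=0.45, ge=0, le=1)
    washout_days: int = Field(default=365, gt=0)
    followup_days: int = Field(default=365, gt=0)

    @field_validator(
        "cohort_mix",
        "first_line_distribution",
        "fixed_first_line_distribution",
        "second_line_distribution",
        "bottles_per_fill",
    )
    @classmethod
    def _probabilities_valid(cls, v: dict) -> dict:
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {sum(v.values())}")
        return v

    @model_validator(mode="after")
    def _mix_keys(self) -> "SimulationConfig":
        expected = {"compliant", "noncompliant", "other", "ineligible"}
        if set(self.cohort_mix) != expected:
            raise ValueError(f"cohort_mix keys must be {sorted(expected)}")
        if self.switch_day_min > self.switch_day_max:
            raise ValueError("switch_day_min must not exceed switch_day_max")
        return self


@dataclass
class SimulatedData:
    """The five input tables, the formulary used, and the latent truth."""

    pharmacy: pd.DataFrame
    diagnosis: pd.DataFrame
    procedure: pd.DataFrame
    checkup: pd.DataFrame
    coverage: pd.DataFrame
    formulary: Formulary
    ground_truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(self.pharmacy, out_dir / "pharmacy.csv", "pharmacy")
        write_table(self.diagnosis, out_dir / "diagnosis.csv", "diagnosis")
        write_table(self.procedure, out_dir / "procedure.csv", "procedure")
        write_table(self.checkup, out_dir / "checkup.csv", "checkup")
        write_table(self.coverage, out_dir / "coverage.csv", "coverage")
        gt = self.ground_truth.copy()
        for col in ("index_date",):
            gt[col] = gt[col].astype(str)
        (out_dir / "ground_truth.json").write_text(
            json.dumps(gt.to_dict(orient="records"), indent=1, default=str)
        )


def _products_by_name(formulary: Formulary) -> dict[str, str]:
    """generic name -> brand (non-generic) product code."""
    out: dict[str, str] = {}
    for code, product in formulary.products.items():
        if not product.is_generic and product.generic_name not in out:
            out[product.generic_name] = code
    return out


def _choice(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _refill_stream(
    rng: np.random.Generator,
    formulary: Formulary,
    product_code: str,
    start_rel: int,
    stop_rel: int,
    theta: float,
    disc_rel: float | None,
    bottles_dist: dict[int, float],
    bilateral: bool,
) -> list[tuple[int, str, float]]:
    """Relative-day fills (day, product, quantity_ml) for one regimen segment.

    Refills fall due at supply exhaustion; the realized cycle is the due
    interval inflated by 1/theta. A refill is dispensed only if the latent
    discontinuation clock outlasts the supply it would provide, so the last
    claim's coverage ends at or just before the latent discontinuation day
    and claims-based event times do not overshoot it.
    """
    product = formulary[product_code]
    fills: list[tuple[int, str, float]] = []
    t = start_rel
    first = True
    while t < stop_rel:
        n_bottles = 7 if bilateral else int(_choice(rng, bottles_dist))
        supply = days_supplied(n_bottles, 2 if bilateral else 1)
        if disc_rel is not None and t + supply > disc_rel and not first:
            break
        fills.append((t, product_code, n_bottles * product.bottle_volume_ml))
        first = False
        if disc_rel is not None and t + supply > disc_rel:
            break  # the first fill is always dispensed; nothing after
        t += max(supply, int(round(supply / theta)))
    return fills


def generate(config: SimulationConfig) -> SimulatedData:
    """Generate the five tables and ground truth for ``config``.

    Deterministic: the same config (including seed) yields identical
    tables.
    """
    rng = np.random.default_rng(config.seed)
    formulary = default_formulary()
    by_name = _products_by_name(formulary)
    for name in (
        *config.first_line_distribution,
        *config.fixed_first_line_distribution,
        *config.second_line_distribution,
    ):
        if name not in by_name:
            raise ValueError(f"no product for generic name {name!r} in formulary")

    paths = list(config.cohort_mix)
    path_probs = np.array([config.cohort_mix[p] for p in paths])
    hazard = config.discontinuation_hazard_per_day

    pharmacy_rows: list[tuple] = []
    dx_rows: list[tuple] = []
    proc_rows: list[tuple] = []
    checkup_rows: list[dict] = []
    coverage_rows: list[tuple] = []
    truth_rows: list[dict] = []

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        path = paths[rng.choice(len(paths), p=path_probs)]
        index = _EXTRACTION_START + timedelta(days=int(rng.integers(0, _INDEX_SPAN_DAYS)))
        theta = (
            config.adherence_fixed_theta
            if config.adherence_fixed_theta is not None
            else float(rng.beta(config.adherence_alpha, config.adherence_beta))
        )
        theta = max(theta, 0.05)  # guard against astronomically long cycles
        disc_rel: float | None = None
        if hazard > 0:
            disc_rel = float(rng.exponential(1.0 / hazard))
        bilateral = bool(rng.random() < config.bilateral_fraction)
        followup = config.followup_days

        obs_start = index - timedelta(days=config.washout_days)
        obs_end = index + timedelta(days=followup)
        rule: str | None = None
        claim_limit = followup  # relative day past which no claims are written

        switch_day: int | None = None
        second_product: str | None = None
        unfixed_partner: str | None = None

        if path == "ineligible":
            rule = INELIGIBLE_RULES[int(rng.integers(0, len(INELIGIBLE_RULES)))]
            if rule == "SHORT_WASHOUT":
                obs_start = index - timedelta(days=int(rng.integers(30, config.washout_days)))
            elif rule == "SHORT_FOLLOWUP":
                short = int(rng.integers(30, followup))
                obs_end = index + timedelta(days=short)
                claim_limit = short
            elif rule == "PRIOR_SURGERY":
                surgery_day = index - timedelta(days=int(rng.integers(0, 200)))
                proc_rows.append((pid, surgery_day, ProcedureCategory.SURGERY.value))

        if path == "noncompliant":
            first_product = by_name[_choice(rng, config.fixed_first_line_distribution)]
        else:
            first_product = by_name[_choice(rng, config.first_line_distribution)]

        if path == "compliant" and rng.random() < config.switch_probability:
            switch_day = int(rng.integers(config.switch_day_min, config.switch_day_max + 1))
            second_product = by_name[_choice(rng, config.second_line_distribution)]
        if path == "other" and rng.random() < config.unfixed_switch_fraction:
            switch_day = int(rng.integers(config.switch_day_min, config.switch_day_max + 1))
            partner_name = "timolol" if formulary[first_product].generic_name != "timolol" else "latanoprost"
            unfixed_partner = by_name[partner_name]

        segment_end = min(claim_limit, switch_day) if switch_day is not None else claim_limit
        fills = _refill_stream(
            rng, formulary, first_product, 0, segment_end, theta, disc_rel,
            config.bottles_per_fill, bilateral,
        )
        if switch_day is not None and switch_day < claim_limit:
            if second_product is not None:
                # guideline-compliant step-up to a fixed combination; the
                # second-line stream is not subject to the first-line clock
                fills += _refill_stream(
                    rng, formulary, second_product, switch_day, claim_limit,
                    theta, None, config.bottles_per_fill, bilateral,
                )
            elif unfixed_partner is not None:
                fills += _refill_stream(
                    rng, formulary, first_product, switch_day, claim_limit,
                    theta, None, config.bottles_per_fill, bilateral,
                )
                fills += _refill_stream(
                    rng, formulary, unfixed_partner, switch_day, claim_limit,
                    theta, None, config.bottles_per_fill, bilateral,
                )
        for rel, code, qty in fills:
            pharmacy_rows.append(
                (pid, index + timedelta(days=rel), code, qty, "1")
            )

        dx_code = "H401" if rng.random() < config.diagnosis_h401_probability else "H409"
        dx_rows.append((pid, index, dx_code))

        exam_limit = min(claim_limit, followup)
        for cat_name, rate in config.exam_rate_per_year.items():
            n_exams = int(rng.poisson(rate * exam_limit / 365.0))
            for day in sorted(rng.integers(0, max(exam_limit, 1), size=n_exams).tolist()):
                proc_rows.append((pid, index + timedelta(days=int(day)), cat_name))
        if path != "ineligible" and rng.random() < config.surgery_probability_12m:
            # strictly after index: an index-day surgery would collide with
            # the prior-surgery exclusion and contradict the ground truth
            day = int(rng.integers(1, followup))
            proc_rows.append(
                (pid, index + timedelta(days=day), ProcedureCategory.SURGERY.value)
            )

        row: dict[str, object] = {
            "patient_id": pid,
            "checkup_date": index,
            "age": float(np.clip(np.round(rng.normal(52, 12)), 20, 74)),
            "sex_male": int(rng.random() < 0.57),
            "bmi": float(np.round(rng.normal(23.2, 3.7), 1)),
            "sbp": float(np.round(rng.normal(122, 16), 0)),
            "gamma_gtp": float(np.round(rng.lognormal(3.37, 0.8), 1)),
            "smoking": int(rng.random() < 0.18),
            "asthma_copd": int(rng.random() < 0.15),
        }
        for field_name in ("bmi", "sbp", "gamma_gtp", "smoking", "asthma_copd"):
            if rng.random() < config.checkup_missingness:
                row[field_name] = np.nan
        checkup_rows.append(row)

        coverage_rows.append((pid, obs_start, obs_end))
        if path == "compliant":
            true_label = "GL_COMPLIANT" if switch_day is not None else "OTHER"
        elif path == "noncompliant":
            true_label = "GL_NONCOMPLIANT"
        elif path == "other":
            true_label = "OTHER"
        else:
            true_label = "EXCLUDED"
        truth_rows.append(
            {
                "patient_id": pid,
                "path": path,
                "true_label": true_label,
                "theta": theta,
                "disc_day": disc_rel,
                "eyes": 2 if bilateral else 1,
                "switch_day": switch_day,
                "ineligible_rule": rule,
                "index_date": index,
                "first_product": first_product,
            }
        )

    pharmacy = pd.DataFrame(
        pharmacy_rows,
        columns=["patient_id", "dispense_date", "product_code", "quantity_ml", "period_field"],
    )
    diagnosis = pd.DataFrame(dx_rows, columns=["patient_id", "diagnosis_date", "icd10_code"])
    procedure = pd.DataFrame(proc_rows, columns=["patient_id", "procedure_date", "category"])
    checkup = pd.DataFrame(checkup_rows)
    coverage = pd.DataFrame(coverage_rows, columns=["patient_id", "obs_start", "obs_end"])
    ground_truth = pd.DataFrame(truth_rows)
    return SimulatedData(
        pharmacy=pharmacy,
        diagnosis=diagnosis,
        procedure=procedure,
        checkup=checkup,
        coverage=coverage,
        formulary=formulary,
        ground_truth=ground_truth,
    )


def inject_worked_example() -> pd.DataFrame:
    """A fixed one-patient pharmacy table exercising the conversion rules.

    Contains the canonical claim (7.5 mL of a 2.5 mL once-daily product
    with a period field of "1" — three bottles, 90 days, whatever the
    period field says), a seven-bottle claim triggering the bilateral rule,
    and an early refill that overlaps the first claim's supply.
    """
    rows = [
        ("WEX001", date(2013, 4, 1), "LAT01", 7.5, "1"),
        ("WEX001", date(2013, 6, 15), "LAT01", 2.5, "1"),
        ("WEX001", date(2013, 8, 1), "LAT01", 17.5, "3"),
    ]
    return pd.DataFrame(
        rows,
        columns=["patient_id", "dispense_date", "product_code", "quantity_ml", "period_field"],
    )
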