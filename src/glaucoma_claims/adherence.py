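"""Proportion-of-days-covered (PDC) adherence from pharmacy claims.

Dispensed eye-drop volume is converted to bottles (the claim's period field
is untrustworthy and ignored), bottles to days of supply — one bottle covers
one eye for 30 dispensed days — and supply to non-overlapping coverage
intervals with carry-forward of early-refill stockpile. PDC over a fixed
12-month post-index window is the fraction of days covered by at least one
interval, reported as a percent with the conventional 80% adherence cutoff.

A prescription of seven or more bottles at once marks bilateral treatment:
the supply is consumed twice as fast.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formulary import DrugProduct, Formulary

DAYS_PER_BOTTLE_PER_EYE = 30
BILATERAL_BOTTLE_THRESHOLD = 7
DEFAULT_WINDOW_DAYS = 365
ADHERENT_PDC_CUTOFF = 80.0


class PDCCategory(str, enum.Enum):
    """Adherence bands: >=80, 60-<80, 40-<60, 20-<40, <20 percent."""

    GE80 = "GE80"
    FROM60TO79 = "60TO79"
    FROM40TO59 = "40TO59"
    FROM20TO39 = "20TO39"
    LT20 = "LT20"


@dataclass(frozen=True)
class PharmacyClaim:
    """One dispensing event. ``period_field`` is retained but never trusted."""

    patient_id: str
    dispense_date: date
    product_code: str
    quantity_ml: float
    period_field: str = ""


@dataclass(frozen=True)
class SupplyInterval:
    """An inclusive date range of medication coverage."""

    patient_id: str
    start: date
    end: date
    product_code: str
    n_bottles: int
    eyes: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")


@dataclass(frozen=True)
class PDCResult:
    patient_id: str
    covered_days: int
    window_days: int
    pdc_percent: float
    category: PDCCategory


def bottles_from_claim(claim: PharmacyClaim, product: DrugProduct) -> int:
    """Convert dispensed mL to a bottle count for the product's bottle size.

    The canonical example: 7.5 mL of a 2.5 mL once-daily product is three
    bottles. Quantities that are not a whole number of bottles (beyond a
    1e-6 relative tolerance) are rounded to the nearest bottle, minimum 1.
    """
    if claim.quantity_ml <= 0:
        raise ValueError(
            f"{claim.patient_id}: nonpositive dispensed quantity {claim.quantity_ml}"
        )
    ratio = claim.quantity_ml / product.bottle_volume_ml
    if abs(ratio - round(ratio)) > 1e-6:
        # flagged: payer claims occasionally carry partial volumes
        return max(1, round(ratio))
    return max(1, round(ratio))


def detect_eyes(n_bottles: int) -> int:
    """2 (bilateral treatment) iff the single prescription has >=7 bottles."""
    if n_bottles < 1:
        raise ValueError("bottle count must be >= 1")
    return 2 if n_bottles >= BILATERAL_BOTTLE_THRESHOLD else 1


def days_supplied(n_bottles: int, eyes: int) -> int:
    """Days of supply: floor(bottles x 30 / eyes)."""
    if n_bottles < 1:
        raise ValueError("bottle count must be >= 1")
    if eyes not in (1, 2):
        raise ValueError(f"eyes must be 1 or 2, got {eyes}")
    return (n_bottles * DAYS_PER_BOTTLE_PER_EYE) // eyes


def build_supply_intervals(
    claims: Iterable[PharmacyClaim],
    formulary: Formulary,
    scope: set[str] | str = "all",
) -> list[SupplyInterval]:
    """Turn one patient's claims into ordered non-overlapping coverage.

    ``scope`` restricts to a set of product codes ("all" keeps everything).
    Early refills carry forward: a claim's interval starts at the later of
    its dispense date and the day after the previous interval ends, so
    stockpiled supply extends coverage instead of being discarded. Claims on
    the same day pool their supply sequentially.
    """
    kept = [
        c for c in claims
        if scope == "all" or c.product_code in scope
    ]
    kept.sort(key=lambda c: (c.dispense_date, c.product_code))
    intervals: list[SupplyInterval] = []
    prev_end: date | None = None
    for claim in kept:
        product = formulary[claim.product_code]
        n_bottles = bottles_from_claim(claim, product)
        eyes = detect_eyes(n_bottles)
        length = days_supplied(n_bottles, eyes)
        start = claim.dispense_date
        if prev_end is not None and prev_end + timedelta(days=1) > start:
            start = prev_end + timedelta(days=1)
        end = start + timedelta(days=length - 1)
        intervals.append(
            SupplyInterval(
                patient_id=claim.patient_id,
                start=start,
                end=end,
                product_code=claim.product_code,
                n_bottles=n_bottles,
                eyes=eyes,
            )
        )
        prev_end = end
    return intervals


def _categorize(pdc_percent: float) -> PDCCategory:
    if pdc_percent >= 80.0:
        return PDCCategory.GE80
    if pdc_percent >= 60.0:
        return PDCCategory.FROM60TO79
    if pdc_percent >= 40.0:
        return PDCCategory.FROM40TO59
    if pdc_percent >= 20.0:
        return PDCCategory.FROM20TO39
    return PDCCategory.LT20


def compute_pdc(
    intervals: Sequence[SupplyInterval],
    index_date: date,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> PDCResult:
    """PDC over ``[index_date, index_date + window_days - 1]``.

    The index date is day 0 and is covered by a fill dispensed on it.
    Intervals built with carry-forward never overlap, so covered days are
    just the summed clipped interval lengths.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    window_start = index_date
    window_end = index_date + timedelta(days=window_days - 1)
    covered = 0
    for iv in intervals:
        lo = max(iv.start, window_start)
        hi = min(iv.end, window_end)
        if lo <= hi:
            covered += (hi - lo).days + 1
    patient_id = intervals[0].patient_id if intervals else ""
    pdc = 100.0 * covered / window_days
    return PDCResult(
        patient_id=patient_id,
        covered_days=covered,
        window_days=window_days,
        pdc_percent=pdc,
        category=_categorize(pdc),
    )


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Sample-size-weighted mean of per-cohort means."""
    if len(means) != len(ns) or not means:
        raise ValueError("means and ns must be equal-length and non-empty")
    total = sum(ns)
    return sum(m * n for m, n in zip(means, ns)) / total


def pooled_proportion(counts: Sequence[int], ns: Sequence[int]) -> float:
    """Pooled percent: summed counts over summed cohort sizes, x100."""
    if len(counts) != len(ns) or not counts:
        raise ValueError("counts and ns must be equal-length and non-empty")
    return 100.0 * sum(counts) / sum(ns)


_CATEGORY_ORDER = [
    PDCCategory.GE80,
    PDCCategory.FROM60TO79,
    PDCCategory.FROM40TO59,
    PDCCategory.FROM20TO39,
    PDCCategory.LT20,
]


def summarize_pdc(results_by_cohort: dict[str, Sequence[PDCResult]]) -> pd.DataFrame:
    """Per-cohort and pooled adherence summary.

    One row per cohort plus a "pooled" row: n, mean PDC, sample SD (n-1
    denominator; 0 with ``sd_defined=False`` for a single patient), count
    and percent per adherence band, and count adherent at the 80% cutoff.
    """
    if not results_by_cohort:
        raise ValueError("no cohorts to summarize")
    rows = []
    pooled: list[PDCResult] = []
    for cohort, results in results_by_cohort.items():
        if len(results) == 0:
            raise ValueError(f"cohort {cohort!r} is empty")
        pooled.extend(results)
    for cohort, results in [*results_by_cohort.items(), ("pooled", pooled)]:
        values = np.array([r.pdc_percent for r in results])
        n = len(values)
        row: dict[str, object] = {
            "cohort": cohort,
            "n": n,
            "mean_pdc": float(values.mean()),
            "sd_pdc": float(values.std(ddof=1)) if n > 1 else 0.0,
            "sd_defined": n > 1,
            "n_adherent": int(sum(r.pdc_percent >= ADHERENT_PDC_CUTOFF for r in results)),
        }
        for cat in _CATEGORY_ORDER:
            count = sum(r.category is cat for r in results)
            row[f"n_{cat.value}"] = count
            row[f"pct_{cat.value}"] = 100.0 * count / n
        rows.append(row)
    return pd.DataFrame(rows)
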