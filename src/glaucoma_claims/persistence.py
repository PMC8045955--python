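"""Time to discontinuation of first-line therapy and Kaplan–Meier persistence.

A patient persists on the index regimen *category* (monotherapies for a
monotherapy starter, fixed combinations for a fixed-combination starter)
as long as refills keep coverage gaps within a 30-day grace period and no
switch out of the category occurs. Switching within the category — for
example timolol to latanoprost, or one fixed combination to another — is
continuation. Discontinuation time is anchored at supply exhaustion: the
last fill date plus its days supplied. Patients still on first-line therapy
at 12 months are censored there.

The product-limit (Kaplan–Meier) estimator, Greenwood variance, plain-scale
Wald confidence intervals, the two-group log-rank test and Hall–Wellner
simultaneous bands are implemented here directly; persistence percent is
100 minus the cumulative discontinuation percent by construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .adherence import PharmacyClaim, build_supply_intervals
from .formulary import Formulary, Regimen

DEFAULT_GRACE_DAYS = 30
DEFAULT_HORIZON_DAYS = 365


class DiscontinuationReason(str, enum.Enum):
    SUPPLY_GAP = "SUPPLY_GAP"
    SWITCH_TO_SECOND_LINE = "SWITCH_TO_SECOND_LINE"
    SWITCH_OFF_FIXED = "SWITCH_OFF_FIXED"
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class PersistenceRecord:
    patient_id: str
    duration_days: int
    event: bool
    reason: DiscontinuationReason

    def __post_init__(self) -> None:
        if self.duration_days < 0:
            raise ValueError("duration_days must be nonnegative")
        if not self.event and self.reason is not DiscontinuationReason.CENSORED:
            raise ValueError("censored records must carry reason CENSORED")


def _day_regimens(
    claims: Sequence[PharmacyClaim], formulary: Formulary
) -> dict[date, Regimen]:
    """Regimen category dispensed on each distinct fill date."""
    by_day: dict[date, set[str]] = {}
    for c in claims:
        by_day.setdefault(c.dispense_date, set()).add(c.product_code)
    out = {}
    for day, codes in by_day.items():
        if len(codes) >= 2:
            out[day] = Regimen.UNFIXED
        else:
            (code,) = codes
            out[day] = (
                Regimen.FIXED if formulary[code].is_fixed_combination else Regimen.MONO
            )
    return out


def time_to_discontinuation(
    claims: Iterable[PharmacyClaim],
    formulary: Formulary,
    index_date: date,
    first_line_regimen: Regimen,
    grace_days: int = DEFAULT_GRACE_DAYS,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
) -> PersistenceRecord:
    """Scan one patient's claims forward from index for a discontinuation event.

    ``first_line_regimen`` must be MONO or FIXED (unfixed starters are not
    analyzed). The event is the earlier of (a) a switch out of the index
    category — the first day a combination is dispensed for a monotherapy
    starter, or a monotherapy / multi-product day for a fixed starter — and
    (b) supply exhaustion followed by a refill gap longer than the grace
    period. A same-day tie resolves to the switch, the more specific reason.
    Duration for a gap event is last fill date minus index plus its days
    supplied (the exhaustion day); for a switch it is the switch date minus
    index. No event by the horizon means censoring at the horizon.
    """
    if first_line_regimen not in (Regimen.MONO, Regimen.FIXED):
        raise ValueError(
            f"persistence is defined for MONO or FIXED starters, got {first_line_regimen}"
        )
    claims = [c for c in claims if c.dispense_date >= index_date]
    if not claims:
        raise ValueError("no post-index claims to scan")
    patient_id = claims[0].patient_id
    regimens = _day_regimens(claims, formulary)

    switch_reason = (
        DiscontinuationReason.SWITCH_TO_SECOND_LINE
        if first_line_regimen is Regimen.MONO
        else DiscontinuationReason.SWITCH_OFF_FIXED
    )
    switch_rel: int | None = None
    for day in sorted(regimens):
        if regimens[day] is not first_line_regimen:
            rel = (day - index_date).days
            if rel < horizon_days:
                switch_rel = rel
            break

    # coverage from in-category fills only, up to any switch day
    in_category = [
        c
        for c in claims
        if regimens[c.dispense_date] is first_line_regimen
        and (switch_rel is None or (c.dispense_date - index_date).days <= switch_rel)
    ]
    gap_rel: int | None = None
    if in_category:
        intervals = build_supply_intervals(in_category, formulary)
        prev_end = intervals[0].end
        for iv in intervals[1:]:
            gap = (iv.start - prev_end).days - 1
            if gap > grace_days:
                gap_rel = (prev_end - index_date).days + 1
                break
            prev_end = iv.end
        if gap_rel is None:
            exhausted = (prev_end - index_date).days + 1
            if exhausted < horizon_days and (horizon_days - exhausted) > grace_days:
                gap_rel = exhausted
    else:
        # index-day dispensing already out of category is not analyzable here
        raise ValueError(f"{patient_id}: no in-category claims from index")

    candidates: list[tuple[int, DiscontinuationReason]] = []
    if switch_rel is not None:
        candidates.append((switch_rel, switch_reason))
    if gap_rel is not None and gap_rel < horizon_days:
        candidates.append((gap_rel, DiscontinuationReason.SUPPLY_GAP))
    if not candidates:
        return PersistenceRecord(
            patient_id, horizon_days, False, DiscontinuationReason.CENSORED
        )
    # tie resolves to the switch: sort gap after switch at equal time
    candidates.sort(key=lambda t: (t[0], t[1] is DiscontinuationReason.SUPPLY_GAP))
    duration, reason = candidates[0]
    return PersistenceRecord(patient_id, duration, True, reason)


@dataclass
class KMEstimate:
    """Product-limit persistence estimate with Greenwood variance and Wald CIs.

    ``survival`` is the step function value just after each entry of
    ``event_times``; persistence percent at t is 100 x survival(t).
    ``degenerate_variance`` flags times where the at-risk set was exhausted
    (survival 0), where the Greenwood formula is undefined and 0 is reported.
    """

    event_times: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_subjects: int
    degenerate_variance: bool = False

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be nonnegative")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def cumulative_discontinuation_percent(self, t: float) -> float:
        return 100.0 - 100.0 * self.survival_at(t)


def km_fit(records: Sequence[PersistenceRecord], level: float = 0.95) -> KMEstimate:
    """Fit the Kaplan–Meier product-limit estimator to one cohort.

    Wald confidence intervals are computed on the plain survival scale,
    survival +/- z * sqrt(Greenwood variance), clipped to [0, 1].
    """
    if not records:
        raise ValueError("km_fit requires at least one record")
    durations = np.array([r.duration_days for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    times = np.unique(durations[events])
    n = len(records)
    z = stats.norm.ppf(0.5 + level / 2)

    surv = np.empty(len(times))
    var = np.empty(len(times))
    at_risk = np.empty(len(times), dtype=int)
    n_ev = np.empty(len(times), dtype=int)
    s = 1.0
    gw_sum = 0.0  # running sum of d / (n (n - d))
    degenerate = False
    for i, t in enumerate(times):
        r = int(np.sum(durations >= t))
        d = int(np.sum(durations[events] == t))
        at_risk[i] = r
        n_ev[i] = d
        s *= 1.0 - d / r
        if d < r:
            gw_sum += d / (r * (r - d))
            var[i] = s * s * gw_sum
        else:
            s = 0.0
            var[i] = 0.0
            degenerate = True
        surv[i] = s
    half = z * np.sqrt(var)
    return KMEstimate(
        event_times=times,
        n_at_risk=at_risk,
        n_events=n_ev,
        survival=surv,
        greenwood_var=var,
        ci_low=np.clip(surv - half, 0.0, 1.0),
        ci_high=np.clip(surv + half, 0.0, 1.0),
        n_subjects=n,
        degenerate_variance=degenerate,
    )


def persistence_at(estimate: KMEstimate, t_days: float) -> tuple[float, float, float]:
    """Persistence percent and Wald CI bounds (percent) at ``t_days``."""
    if t_days < 0:
        raise ValueError("t_days must be nonnegative")
    idx = np.searchsorted(estimate.event_times, t_days, side="right") - 1
    if idx < 0:
        return 100.0, 100.0, 100.0
    return (
        100.0 * float(estimate.survival[idx]),
        100.0 * float(estimate.ci_low[idx]),
        100.0 * float(estimate.ci_high[idx]),
    )


def logrank(
    records_a: Sequence[PersistenceRecord],
    records_b: Sequence[PersistenceRecord],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, df=1 p-value)."""
    if not records_a or not records_b:
        raise ValueError("log-rank requires two non-empty groups")
    dur_a = np.array([r.duration_days for r in records_a], dtype=float)
    ev_a = np.array([r.event for r in records_a], dtype=bool)
    dur_b = np.array([r.duration_days for r in records_b], dtype=float)
    ev_b = np.array([r.event for r in records_b], dtype=bool)
    times = np.unique(np.concatenate([dur_a[ev_a], dur_b[ev_b]]))
    o_minus_e = 0.0
    v = 0.0
    for t in times:
        na = np.sum(dur_a >= t)
        nb = np.sum(dur_b >= t)
        da = np.sum(dur_a[ev_a] == t)
        db = np.sum(dur_b[ev_b] == t)
        n_tot = na + nb
        d_tot = da + db
        if n_tot < 2 or d_tot == 0:
            continue
        e_a = d_tot * na / n_tot
        o_minus_e += da - e_a
        v += d_tot * (na / n_tot) * (nb / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if v == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e * o_minus_e / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hall_wellner_band(
    estimate: KMEstimate, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Hall–Wellner simultaneous confidence band at the event times.

    Half-width at t is h * n^{-1/2} * (1 + n sigma^2(t)) * S(t), with
    sigma^2 the Greenwood variance over S^2 and h the sup-Brownian-bridge
    (Kolmogorov) quantile — 1.3581 at 95%. This full-bridge quantile is
    conservative and makes the band everywhere at least as wide as the
    pointwise Wald interval. Returns (lower, upper, degenerate); with no
    events the band collapses to the point estimate and is flagged.
    """
    if len(estimate.event_times) == 0:
        return np.array([]), np.array([]), True
    h = float(stats.kstwobign.ppf(level))
    n = estimate.n_subjects
    s = estimate.survival
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = np.where(s > 0, estimate.greenwood_var / (s * s), 0.0)
    half = h / np.sqrt(n) * (1.0 + n * sigma2) * s
    return (
        np.clip(s - half, 0.0, 1.0),
        np.clip(s + half, 0.0, 1.0),
        bool(np.all(~estimate.n_events.astype(bool))),
    )
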