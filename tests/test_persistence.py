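"""Discontinuation scanning, product-limit estimation, log-rank, bands."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glaucoma_claims.persistence import (
    DiscontinuationReason,
    PersistenceRecord,
    hall_wellner_band,
    km_fit,
    logrank,
    persistence_at,
    time_to_discontinuation,
)
from glaucoma_claims.formulary import Regimen
from conftest import BASE_DATE, make_claims


def _record(duration, event):
    reason = DiscontinuationReason.SUPPLY_GAP if event else DiscontinuationReason.CENSORED
    return PersistenceRecord("P", duration, event, reason)


# ---------------------------------------------------------------- timelines


def test_switch_to_fixed_is_second_line_event(formulary):
    claims = make_claims([(0, 3), (90, 1)]) + make_claims([(100, 1)],
                                                          product_code="LTFC01")
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO)
    assert rec.event and rec.duration_days == 100
    assert rec.reason is DiscontinuationReason.SWITCH_TO_SECOND_LINE


def test_single_fill_exhaustion_is_supply_gap(formulary):
    rec = time_to_discontinuation(make_claims([(0, 3)]), formulary, BASE_DATE,
                                  Regimen.MONO)
    assert (rec.duration_days, rec.event) == (90, True)
    assert rec.reason is DiscontinuationReason.SUPPLY_GAP


def test_mono_to_mono_switch_is_continuation(formulary):
    claims = (
        make_claims([(0, 3)], product_code="TIM01", bottle_ml=5.0)
        + make_claims([(90, 3), (180, 3), (270, 4)])
    )
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO)
    assert not rec.event and rec.duration_days == 365
    assert rec.reason is DiscontinuationReason.CENSORED


def test_fixed_cohort_switch_off_fixed(formulary):
    claims = make_claims([(0, 3)], product_code="LTFC01") + make_claims([(60, 1)])
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.FIXED)
    assert rec.reason is DiscontinuationReason.SWITCH_OFF_FIXED
    assert rec.duration_days == 60


def test_fixed_to_fixed_switch_is_continuation(formulary):
    claims = make_claims([(0, 3)], product_code="LTFC01") + make_claims(
        [(90, 3), (180, 3), (270, 3)], product_code="DTFC01", bottle_ml=5.0
    )
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.FIXED)
    assert not rec.event


def test_gap_within_grace_is_continuation(formulary):
    # 90-day supply, refill 25 days after exhaustion: inside the 30-day grace
    claims = make_claims([(0, 3), (115, 3), (205, 3), (295, 3)])
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO)
    assert not rec.event


def test_late_exhaustion_is_censored(formulary):
    # coverage ends day 340; only 25 days remain in the window, less than
    # the grace period, so no gap can be observed
    claims = make_claims([(0, 3), (90, 3), (180, 3), (250, 3)])
    rec = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO)
    assert not rec.event and rec.duration_days == 365


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(st.tuples(st.integers(0, 360), st.integers(1, 4)), min_size=1, max_size=6),
    st.integers(0, 60),
    st.integers(1, 60),
)
def test_longer_grace_never_shortens_duration(formulary, day_bottles, grace, extra):
    """Increasing the grace period can only extend persistence."""
    day_bottles = sorted(set(day_bottles))
    if day_bottles[0][0] != 0:
        day_bottles = [(0, 1)] + day_bottles
    claims = make_claims(day_bottles)
    short = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO,
                                    grace_days=grace)
    long = time_to_discontinuation(claims, formulary, BASE_DATE, Regimen.MONO,
                                   grace_days=grace + extra)
    assert long.duration_days >= short.duration_days


# ------------------------------------------------------------ product-limit


def test_km_hand_example():
    records = [_record(10, True), _record(20, True), _record(365, False)]
    est = km_fit(records)
    assert est.event_times.tolist() == [10, 20]
    assert est.survival[0] == pytest.approx(2 / 3)
    assert est.survival[1] == pytest.approx((2 / 3) * (1 / 2))


def test_km_all_censored_and_degenerate():
    est = km_fit([_record(365, False)] * 4)
    assert len(est.event_times) == 0
    assert persistence_at(est, 365) == (100.0, 100.0, 100.0)
    single = km_fit([_record(5, True)])
    assert single.survival[0] == 0.0
    assert single.greenwood_var[0] == 0.0 and single.degenerate_variance


def _oracle_km(durations, events):
    """Naive product-limit: explicit risk-set recount at every event time."""
    out = []
    s = 1.0
    for t in sorted({d for d, e in zip(durations, events) if e}):
        at_risk = sum(1 for d in durations if d >= t)
        deaths = sum(1 for d, e in zip(durations, events) if e and d == t)
        s *= (at_risk - deaths) / at_risk
        out.append((t, s))
    return out


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(1, 365), st.booleans()), min_size=1, max_size=20
    )
)
def test_km_matches_brute_force_oracle(pairs):
    records = [_record(d, e) for d, e in pairs]
    est = km_fit(records)
    oracle = _oracle_km(*zip(*pairs))
    assert len(est.event_times) == len(oracle)
    for (t, s), st_, sv in zip(oracle, est.event_times, est.survival):
        assert st_ == t
        assert sv == pytest.approx(s)
    # survival nonincreasing, CIs bracket the estimate
    assert (np.diff(est.survival) <= 1e-12).all()
    assert (est.ci_low <= est.survival + 1e-12).all()
    assert (est.survival <= est.ci_high + 1e-12).all()


def test_km_agrees_with_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(0)
    durations = rng.integers(1, 365, size=200)
    events = rng.random(200) < 0.7
    est = km_fit([_record(int(d), bool(e)) for d, e in zip(durations, events)])
    kmf = lifelines.KaplanMeierFitter().fit(durations, events)
    for t in (30, 90, 180, 364):
        assert est.survival_at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-10
        )


def test_persistence_plus_cumulative_discontinuation_is_100():
    rng = np.random.default_rng(1)
    records = [
        _record(int(d), bool(e))
        for d, e in zip(rng.integers(1, 366, 150), rng.random(150) < 0.6)
    ]
    est = km_fit(records)
    for t in [0, *est.event_times.tolist(), 365, 400]:
        rate, _, _ = persistence_at(est, t)
        assert rate + est.cumulative_discontinuation_percent(t) == pytest.approx(100.0)


def test_persistence_at_step_semantics():
    est = km_fit([_record(10, True), _record(20, False)])
    assert persistence_at(est, 0)[0] == 100.0
    assert persistence_at(est, 9)[0] == 100.0
    assert persistence_at(est, 10)[0] == pytest.approx(50.0)
    assert persistence_at(est, 1000)[0] == pytest.approx(50.0)  # carried forward
    with pytest.raises(ValueError):
        persistence_at(est, -1)


def test_km_geometric_survival_recovery():
    """KM at 12 months recovers the closed-form (1-h)^365 geometric survival
    when daily discontinuation is Bernoulli(h)."""
    h, n = 0.004, 4000
    rng = np.random.default_rng(5)
    days = rng.geometric(h, size=n)  # day of first failure
    records = [
        _record(int(min(d, 365)), bool(d <= 365)) for d in days
    ]
    est = km_fit(records)
    rate, _, _ = persistence_at(est, 365)
    target = 100 * (1 - h) ** 365
    se = 100 * np.sqrt((target / 100) * (1 - target / 100) / n)
    assert abs(rate - target) < 3 * se


# ------------------------------------------------------------------ logrank


def test_logrank_identical_groups():
    records = [_record(10, True), _record(50, True), _record(365, False)]
    chi2, p = logrank(records, list(records))
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_logrank_hand_tally():
    """4-patient example against a hand expected/observed computation."""
    a = [_record(10, True), _record(30, False)]
    b = [_record(20, True), _record(40, True)]
    # t=10: na=2 nb=2 d=1 -> E_a=0.5, V=4/12... per-time V = d*(na/n)*(nb/n)*(n-d)/(n-1)
    # t=10: V=1*(2/4)*(2/4)*(3/3)=0.25; O-E = 1-0.5 = 0.5
    # t=20: na=1 nb=2 d=1 -> E_a=1/3, V=(1/3)*(2/3)*1=2/9; O-E = -1/3
    # t=40: na=0 nb=1 -> E_a=0, V=0
    o_minus_e = 0.5 - 1 / 3
    v = 0.25 + 2 / 9
    chi2, p = logrank(a, b)
    assert chi2 == pytest.approx(o_minus_e**2 / v)


def test_logrank_agrees_with_lifelines():
    stats_ll = pytest.importorskip("lifelines.statistics")
    rng = np.random.default_rng(2)
    a = [_record(int(d), bool(e)) for d, e in
         zip(rng.integers(1, 300, 80), rng.random(80) < 0.7)]
    b = [_record(int(d), bool(e)) for d, e in
         zip(rng.integers(1, 365, 90), rng.random(90) < 0.5)]
    chi2, p = logrank(a, b)
    res = stats_ll.logrank_test(
        [r.duration_days for r in a], [r.duration_days for r in b],
        [r.event for r in a], [r.event for r in b],
    )
    assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
    assert p == pytest.approx(res.p_value, rel=1e-9)


def test_logrank_rejects_empty_group():
    with pytest.raises(ValueError):
        logrank([], [_record(1, True)])


# ------------------------------------------------------------- Hall–Wellner


def test_hall_wellner_wider_than_pointwise():
    rng = np.random.default_rng(3)
    records = [
        _record(int(d), bool(e))
        for d, e in zip(rng.integers(1, 366, 120), rng.random(120) < 0.5)
    ]
    est = km_fit(records)
    low, high, degenerate = hall_wellner_band(est)
    assert not degenerate
    assert (low <= est.ci_low + 1e-12).all()
    assert (high >= est.ci_high - 1e-12).all()
    assert (low >= 0).all() and (high <= 1).all()


def test_hall_wellner_three_event_worked_example():
    """Bounds match a from-scratch evaluation of the band formula."""
    records = [_record(10, True), _record(20, True), _record(30, True),
               _record(365, False), _record(365, False)]
    est = km_fit(records)
    low, high, _ = hall_wellner_band(est, level=0.95)
    from scipy.stats import kstwobign

    h = kstwobign.ppf(0.95)
    n = 5
    s = 1.0
    gw = 0.0
    for t, r, d in [(10, 5, 1), (20, 4, 1), (30, 3, 1)]:
        s *= 1 - d / r
        gw += d / (r * (r - d))
        half = h / np.sqrt(n) * (1 + n * gw) * s
        i = [10, 20, 30].index(t)
        assert low[i] == pytest.approx(max(0.0, s - half))
        assert high[i] == pytest.approx(min(1.0, s + half))


def test_hall_wellner_degenerate_without_events():
    est = km_fit([_record(365, False)] * 3)
    low, high, degenerate = hall_wellner_band(est)
    assert degenerate and len(low) == 0
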