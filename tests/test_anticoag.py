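import numpy as np
import pytest

from warfdose.core import TargetRange
from warfdose.anticoag import (
    InrSeries,
    cohort_inr_proportions,
    inr_proportions,
    rosendaal_ttr,
    windowed_summary,
)


def _series(days, inrs, low=2.0, high=2.5):
    return InrSeries(tuple(days), tuple(inrs), TargetRange(low, high))


def test_all_in_range_is_100():
    assert rosendaal_ttr(_series([0, 7, 14], [2.2, 2.4, 2.1])) == pytest.approx(100.0)


def test_hand_interpolation_crossings():
    # rises 2.0 -> 3.0 over 10 days with range 2.0-2.5: crosses 2.5 at day 5
    assert rosendaal_ttr(_series([0, 10], [2.0, 3.0])) == pytest.approx(50.0)
    # rises 1.5 -> 2.5 over 4 days with range 2.0-3.0: crosses 2.0 at day 2
    assert rosendaal_ttr(_series([0, 4], [1.5, 2.5], low=2.0, high=3.0)) == pytest.approx(50.0)


def test_single_measurement_undefined():
    assert rosendaal_ttr(_series([3], [2.2])) is None


def test_gap_exclusion_drops_segment_from_both_sides():
    # 10-day in-range segment + 100-day out-of-range segment beyond max_gap
    ttr = rosendaal_ttr(_series([0, 10, 110], [2.2, 2.2, 5.0]), max_gap=56)
    assert ttr == pytest.approx(100.0)
    assert rosendaal_ttr(_series([0, 100], [2.2, 2.2]), max_gap=56) is None


def test_boundary_value_counts_in_range():
    assert rosendaal_ttr(_series([0, 10], [2.5, 2.5])) == pytest.approx(100.0)
    assert rosendaal_ttr(_series([0, 10], [2.0, 2.0])) == pytest.approx(100.0)


def test_time_shift_invariance():
    base = rosendaal_ttr(_series([0, 6, 20], [1.8, 2.4, 2.6]))
    shifted = rosendaal_ttr(_series([100, 106, 120], [1.8, 2.4, 2.6]))
    assert base == pytest.approx(shifted)


def _dense_oracle(series: InrSeries, max_gap=56.0, points=10_000, clip_to=None):
    """Midpoint-sampled piecewise-linear oracle for TTR."""
    total = in_range = 0.0
    for i in range(len(series.days) - 1):
        t0, t1 = series.days[i], series.days[i + 1]
        if t1 - t0 > max_gap:
            continue
        y0, y1 = series.inrs[i], series.inrs[i + 1]
        if clip_to is not None:
            c0, c1 = max(t0, clip_to[0]), min(t1, clip_to[1])
            if c1 <= c0:
                continue
            slope = (y1 - y0) / (t1 - t0)
            y0, y1 = y0 + slope * (c0 - t0), y0 + slope * (c1 - t0)
            t0, t1 = c0, c1
        ts = np.linspace(t0, t1, points, endpoint=False) + (t1 - t0) / (2 * points)
        ys = np.interp(ts, [t0, t1], [y0, y1])
        dt = (t1 - t0) / points
        total += t1 - t0
        in_range += dt * np.sum((ys >= series.target.low) & (ys <= series.target.high))
    return None if total == 0 else 100.0 * in_range / total


def _random_series(rng):
    n = rng.integers(2, 12)
    days = np.cumsum(rng.integers(1, 15, size=n))
    inrs = np.clip(rng.normal(2.2, 0.6, size=n), 0.5, 6.0)
    return InrSeries(tuple(days.astype(float)), tuple(inrs), TargetRange(2.0, 2.5))


def test_ttr_matches_dense_oracle_on_random_series():
    rng = np.random.default_rng(123)
    worst = 0.0
    for _ in range(200):
        s = _random_series(rng)
        exact = rosendaal_ttr(s)
        approx = _dense_oracle(s)
        worst = max(worst, abs(exact - approx))
    assert worst < 0.1  # percentage points


@pytest.mark.parametrize(
    "in_count, above_count, total, expected",
    [(749, 0, 1210, 61.9), (0, 145, 1210, 12.0)],
)
def test_inr_proportions_printed_values(in_count, above_count, total, expected):
    vals = [2.2] * in_count + [3.5] * above_count + [1.5] * (total - in_count - above_count)
    p = inr_proportions(vals, TargetRange(2.0, 2.5))
    got = p.in_range_pct if in_count else p.above_pct
    assert got == expected


def test_inr_proportions_all_in_range():
    p = inr_proportions([2.0, 2.2, 2.5], TargetRange(2.0, 2.5))
    assert (p.in_range_pct, p.above_pct, p.below_pct) == (100.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        inr_proportions([], TargetRange(2.0, 2.5))


def test_windowed_summary_clipping_matches_oracle(tiny_cohort):
    table = windowed_summary(tiny_cohort, windows=(30, 60, 90))
    assert list(table["window_days"]) == [30, 60, 90]
    # per-patient clipped TTR agrees with the dense oracle at day 30
    for rec in tiny_cohort[:10]:
        s = InrSeries.from_record(rec)
        exact = rosendaal_ttr(s, clip_to=(0.0, 30.0))
        approx = _dense_oracle(s, clip_to=(0.0, 30.0))
        if exact is None:
            assert approx is None
        else:
            assert exact == pytest.approx(approx, abs=0.1)


def test_windowed_summary_identical_when_data_within_first_window():
    series_rec = [
        r for r in []
    ]
    from warfdose.core import FixedCovariates, PatientRecord, Visit

    rec = PatientRecord(
        "w", FixedCovariates(60, 165, 70),
        (Visit(3, 2.2, 2.5), Visit(10, 2.3, 2.5), Visit(25, 2.1, 2.5)),
        indication="mechanical_valve",
    )
    table = windowed_summary([rec], windows=(30, 60, 90))
    assert table["median_ttr_pct"].nunique() == 1
    assert table["n_inr"].nunique() == 1


def test_windowed_summary_empty_window_reports_missing():
    from warfdose.core import FixedCovariates, PatientRecord, Visit

    rec = PatientRecord(
        "late", FixedCovariates(60, 165, 70),
        (Visit(50, 2.2, 2.5), Visit(60, 2.3, 2.5)),
        indication="mechanical_valve",
    )
    table = windowed_summary([rec], windows=(30,))
    row = table.iloc[0]
    assert row["n_inr"] == 0 and row["median_ttr_pct"] is None


def test_cohort_proportions_pool_measurements(tiny_cohort):
    p = cohort_inr_proportions(tiny_cohort)
    assert p.n == sum(r.n_visits for r in tiny_cohort)
    assert p.counts["in_range"] + p.counts["above"] + p.counts["below"] == p.n
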