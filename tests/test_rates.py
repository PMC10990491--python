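import math

import numpy as np
import pandas as pd
import pytest

from osmopulse import (
    FrameCountsSeries,
    TrackingWindow,
    compare_conditions,
    doubling_time,
    fold_by_phase,
    frame_counts,
    instantaneous_rates,
    interval_rates,
    make_schedule,
    mean_rate,
    period_from_frequency,
    population_growth_rate,
    replicate_summary,
    true_rates,
)
from osmopulse.rates import RateEstimate

from conftest import make_table


def counts_from(intervals):
    """FrameCountsSeries from (t_start, t_end, N_start, N_end, new, in, out, death) rows."""
    df = pd.DataFrame(
        intervals,
        columns=[
            "t_start", "t_end", "N_window_start", "N_window_end",
            "N_new", "N_in", "N_out", "N_death",
        ],
    )
    df["N_death_removed"] = df["N_death"]
    return FrameCountsSeries(df)


class TestFrameCounts:
    def window_table(self, parent_inside=True):
        # frame 0: A stationary inside; B inside near edge; D outside; P parent
        # frame 1: B exits (x 70 -> 50), C new with parent, D enters (x 40 -> 65)
        parent_pos = (510.0, 505.0) if parent_inside else (30.0, 505.0)
        rows = [
            ("A", 0, 0.0, 1, None, 500.0, 500.0, 90.0, False),
            ("A", 0, 0.0, 2, None, 70.0, 500.0, 90.0, False),
            ("A", 0, 0.0, 4, None, 40.0, 500.0, 90.0, False),
            ("A", 0, 0.0, 5, None, *parent_pos, 90.0, False),
            ("A", 1, 6.0, 1, None, 500.0, 500.0, 90.0, False),
            ("A", 1, 6.0, 2, None, 50.0, 500.0, 90.0, False),
            ("A", 1, 6.0, 3, 5, 512.0, 505.0, 60.0, False),
            ("A", 1, 6.0, 4, None, 65.0, 500.0, 90.0, False),
            ("A", 1, 6.0, 5, None, *parent_pos, 90.0, False),
        ]
        return make_table(rows)

    def test_hand_enumerated_conservation(self):
        c = frame_counts(self.window_table(parent_inside=True))
        row = c.data.iloc[0]
        assert row["N_window_start"] == 3 and row["N_window_end"] == 4
        assert row["N_new"] == 1 and row["N_in"] == 1 and row["N_out"] == 1
        assert c.conservation_violations() == 0

    def test_new_object_with_outside_parent_counts_as_entry(self):
        c = frame_counts(self.window_table(parent_inside=False))
        row = c.data.iloc[0]
        assert row["N_new"] == 0 and row["N_in"] == 2  # C reclassified as entry, plus D
        assert c.conservation_violations() == 0

    def test_empty_and_single_frame_raise(self):
        with pytest.raises(ValueError, match="empty"):
            frame_counts(make_table([]))
        one = make_table([("A", 0, 0.0, 1, None, 500.0, 500.0, 90.0, False)])
        with pytest.raises(ValueError, match="two frames"):
            frame_counts(one)

    def test_dead_cells_excluded_from_living_count(self):
        rows = [
            ("A", 0, 0.0, 1, None, 500.0, 500.0, 90.0, False),
            ("A", 0, 0.0, 2, None, 600.0, 500.0, 90.0, False),
            ("A", 1, 6.0, 1, None, 500.0, 500.0, 90.0, False),
            ("A", 1, 6.0, 2, None, 600.0, 500.0, 90.0, True),
        ]
        c = frame_counts(make_table(rows))
        row = c.data.iloc[0]
        assert row["N_window_start"] == 2 and row["N_window_end"] == 1
        assert row["N_death"] == 1 and row["N_death_removed"] == 1
        assert c.conservation_violations() == 0


class TestMeanRate:
    def test_event_free_rate_is_exactly_zero(self):
        c = counts_from([(6 * i, 6 * (i + 1), 50, 50, 0, 0, 0, 0) for i in range(10)])
        assert mean_rate(c, "division").rate == 0.0

    def test_perfect_line_slope(self):
        # each interval contributes 0.06 over 6 min: slope exactly 0.01/min
        c = counts_from([(6 * i, 6 * (i + 1), 100, 100, 6, 0, 0, 0) for i in range(5)])
        est = mean_rate(c, "division")
        assert est.rate == pytest.approx(0.01, abs=1e-12)
        assert est.n_intervals == 5

    def test_too_few_intervals_raise(self):
        c = counts_from([(0, 6, 50, 50, 0, 0, 0, 0), (6, 12, 50, 50, 0, 0, 0, 0)])
        with pytest.raises(ValueError, match="intervals"):
            mean_rate(c, "division")

    def test_zero_denominator_interval_skipped(self):
        rows = [(6 * i, 6 * (i + 1), 100 if i != 2 else 0, 100, 6, 0, 0, 0) for i in range(6)]
        est = mean_rate(counts_from(rows), "division")
        assert est.n_skipped == 1
        assert est.n_intervals == 5

    def test_monotone_dilution(self):
        """Extra non-dividing residents strictly decrease the per-capita rate."""
        base = [(6 * i, 6 * (i + 1), 100, 100, 3, 0, 0, 0) for i in range(8)]
        diluted = [(a, b, n + 40, m + 40, nn, ni, no, nd) for a, b, n, m, nn, ni, no, nd in base]
        assert mean_rate(counts_from(diluted), "division").rate < mean_rate(
            counts_from(base), "division"
        ).rate

    def test_recovery_against_simulation_truth(self, homogeneous_run):
        table, truth, schedule, _ = homogeneous_run
        c = frame_counts(table)
        est = mean_rate(c, "division", schedule=schedule)
        t_div, _ = true_rates(truth, est.t0, est.t1)
        assert est.rate == pytest.approx(t_div, rel=0.15)

    def test_incomplete_period_excluded_with_schedule(self):
        sched = make_schedule("IPS", period=96, total_duration=60 + 96 * 2 + 50)
        c = counts_from(
            [(6 * i, 6 * (i + 1), 50, 50, 1, 0, 0, 0) for i in range(int(sched.total_duration // 6))]
        )
        est = mean_rate(c, "division", schedule=sched)
        assert est.t0 >= 60.0
        assert est.t1 <= 60 + 2 * 96


class TestInstantaneousRates:
    def test_event_free_series_is_zero(self):
        c = counts_from([(6 * i, 6 * (i + 1), 50, 50, 0, 0, 0, 0) for i in range(20)])
        out = instantaneous_rates(c)
        assert np.allclose(out["rate"].dropna(), 0.0)

    def test_localized_burst_peaks_at_right_time(self):
        rows = [(6 * i, 6 * (i + 1), 50, 50, 10 if i == 10 else 0, 0, 0, 0) for i in range(20)]
        out = instantaneous_rates(counts_from(rows))
        peak_t = out.loc[out["rate"].idxmax(), "time"]
        assert 48 <= peak_t <= 78  # windows containing the burst interval [60, 66]
        far = out[(out["time"] < 30) | (out["time"] > 100)]["rate"].dropna()
        assert np.allclose(far, 0.0)

    def test_time_average_matches_global_estimate(self, homogeneous_run):
        table, _, schedule, _ = homogeneous_run
        c = frame_counts(table)
        glob = mean_rate(c, "division", schedule=schedule)
        inst = instantaneous_rates(c)
        inner = inst[~inst["truncated"]]["rate"].dropna()
        assert inner.mean() == pytest.approx(glob.rate, rel=0.10)

    def test_short_series_raises(self):
        c = counts_from([(0, 6, 50, 50, 0, 0, 0, 0)] * 1)
        with pytest.raises(ValueError, match="shorter"):
            instantaneous_rates(c)


class TestPhaseFolding:
    def test_single_period_profile_reindexes_series(self):
        sched = make_schedule("IPS", period=48, total_duration=60 + 48)
        t = 60 + np.arange(8) * 6.0
        r = np.linspace(0.001, 0.008, 8)
        prof = fold_by_phase([pd.DataFrame({"time": t, "rate": r})], sched)
        assert np.allclose(prof.bins["mean_rate"], r)
        assert np.allclose(prof.bins["phase_center"], np.arange(8) * 6 + 3)

    def test_two_periods_average(self):
        sched = make_schedule("IPS", period=48, total_duration=60 + 96)
        t = 60 + np.arange(16) * 6.0
        r = np.concatenate([np.full(8, 0.002), np.full(8, 0.006)])
        prof = fold_by_phase([pd.DataFrame({"time": t, "rate": r})], sched)
        assert np.allclose(prof.bins["mean_rate"], 0.004)
        assert prof.half_period_means == pytest.approx((0.004, 0.004))

    def test_non_periodic_schedule_rejected(self):
        sched = make_schedule("constant", total_duration=300)
        with pytest.raises(ValueError, match="periodic"):
            fold_by_phase([pd.DataFrame({"time": [60.0], "rate": [0.001]})], sched)


class TestDerivedQuantities:
    @pytest.mark.parametrize(
        "rate,minutes",
        [(0.0051, 136), (0.0027, 257), (1.67e-3, 415), (9.4e-4, 737), (math.log(2), 1)],
    )
    def test_doubling_time(self, rate, minutes):
        assert round(doubling_time(rate)) == minutes

    @pytest.mark.parametrize("freq,minutes", [(0.039, 26), (0.5, 2), (1 / 96, 96)])
    def test_period_from_frequency(self, freq, minutes):
        assert round(period_from_frequency(freq)) == minutes

    def test_non_positive_inputs_signalled(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)
        with pytest.raises(ValueError):
            period_from_frequency(-1.0)

    def test_growth_rate_is_difference(self):
        div = RateEstimate(2.0e-3, 0, 0, 100, 60, 660, "division")
        dth = RateEstimate(0.5e-3, 0, 0, 100, 60, 660, "death")
        assert population_growth_rate(div, dth) == pytest.approx(1.5e-3)

    def test_growth_rate_reproduces_reported_deficit(self):
        """Division 9.4e-4 minus death 2.4e-3 gives -1.46e-3, i.e. -1.4e-3
        once rounded the way its inputs are."""
        div = RateEstimate(9.4e-4, 0, 0, 100, 60, 660, "division")
        dth = RateEstimate(2.4e-3, 0, 0, 100, 60, 660, "death")
        g = population_growth_rate(div, dth)
        assert g == pytest.approx(-1.46e-3)
        assert round(g * 1e3, 1) == pytest.approx(-1.5, abs=0.11)


class TestReplicateStatistics:
    def test_identical_values_zero_width_ci(self):
        mean, (lo, hi), n = replicate_summary([0.003] * 4)
        assert mean == lo == hi == 0.003 and n == 4

    def test_hand_t_interval(self):
        mean, (lo, hi), n = replicate_summary([1.0, 2.0, 3.0])
        assert mean == 2.0
        half = 4.302652729911275 * 1.0 / math.sqrt(3)
        assert hi - mean == pytest.approx(half, rel=1e-9)

    def test_single_value_has_undefined_ci(self):
        mean, (lo, hi), n = replicate_summary([0.005])
        assert mean == 0.005 and math.isnan(lo) and math.isnan(hi)

    def test_identical_groups_give_t0_p1(self):
        t, p = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_give_tiny_p(self):
        t, p = compare_conditions([1.0, 1.1, 0.9, 1.05], [10.0, 10.2, 9.9, 10.1])
        assert p < 1e-6

    def test_insufficient_replicates_raise(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])


def test_interval_rates_matches_event_arithmetic():
    c = counts_from([(0, 6, 100, 100, 3, 0, 0, 1), (6, 12, 0, 50, 2, 0, 0, 0)])
    r = interval_rates(c, "division")
    assert r["rate"].iloc[0] == pytest.approx(3 / (100 * 6))
    assert math.isnan(r["rate"].iloc[1])
    d = interval_rates(c, "death")
    assert d["rate"].iloc[0] == pytest.approx(1 / (100 * 6))
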