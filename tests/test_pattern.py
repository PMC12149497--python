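import numpy as np
import pandas as pd
import pytest

from feedpattern.pattern import (
    HORIZON_S,
    DayFilterConfig,
    FeedDeliverySchedule,
    assign_day_windows,
    cumulative_curve,
    daily_curves,
    filter_days,
    remove_outlier_days,
    summarize_cows,
    trapezoid_auc,
)
from feedpattern.sim import uniform_day


def visit_row(cow, date, entry, exit_, intake, pen="pen0"):
    e = pd.Timestamp(f"{date} {entry}")
    x = pd.Timestamp(f"{date} {exit_}")
    if x < e:
        x += pd.Timedelta(days=1)
    return {
        "cow_id": cow,
        "pen_id": pen,
        "date": pd.Timestamp(date).date(),
        "entry": e,
        "exit": x,
        "intake": intake,
        "duration": (x - e).total_seconds(),
    }


class TestDayWindows:
    def test_time0_is_first_visit_after_delivery(self):
        visits = pd.DataFrame(
            [
                visit_row("c1", "2022-06-01", "09:30:00", "09:40:00", 2.0),
                visit_row("c1", "2022-06-01", "11:20:00", "11:30:00", 3.0),
                visit_row("c2", "2022-06-01", "12:00:00", "12:10:00", 3.0),
            ]
        )
        schedule = FeedDeliverySchedule(first_delivery="11:20:00")
        windows, assigned = assign_day_windows(visits, schedule)
        assert windows.loc[0, "time0"] == pd.Timestamp("2022-06-01 11:20:00")
        # the 09:30 visit precedes the first window
        assert assigned["day_index"].tolist() == [-1, 0, 0]

    def test_visit_before_time0_joins_previous_window(self):
        visits = pd.DataFrame(
            [
                visit_row("c1", "2022-06-01", "11:30:00", "11:40:00", 3.0),
                visit_row("c1", "2022-06-02", "10:55:00", "11:05:00", 2.0),  # before day-2 time0
                visit_row("c1", "2022-06-02", "11:30:00", "11:40:00", 3.0),
            ]
        )
        windows, assigned = assign_day_windows(visits, FeedDeliverySchedule())
        assert len(windows) == 2
        assert assigned["day_index"].tolist() == [0, 0, 1]

    def test_single_window_collects_all_visits(self):
        visits = pd.DataFrame(
            [
                visit_row("c1", "2022-06-01", "11:30:00", "11:40:00", 3.0),
                visit_row("c1", "2022-06-01", "19:00:00", "19:10:00", 3.0),
            ]
        )
        windows, assigned = assign_day_windows(visits, FeedDeliverySchedule())
        assert len(windows) == 1
        assert (assigned["day_index"] == 0).all()

    def test_inference_finds_post_lockout_gap(self):
        # morning visits end at 10:10, lockout silence, feeding resumes 11:25
        visits = pd.DataFrame(
            [
                visit_row("c1", "2022-06-01", "10:05:00", "10:10:00", 1.0),
                visit_row("c2", "2022-06-01", "11:25:00", "11:35:00", 3.0),
                visit_row("c1", "2022-06-01", "11:26:00", "11:36:00", 3.0),
            ]
        )
        windows, _ = assign_day_windows(visits, schedule=None)
        assert windows.loc[0, "time0"] == pd.Timestamp("2022-06-01 11:25:00")


class TestCurvesAndAuc:
    @pytest.mark.parametrize("n", [1, 5, 24, 31])
    def test_uniform_feeding_gives_half_day_exactly(self, n):
        offsets, intakes = uniform_day(n, 43.8)
        curve = cumulative_curve("c", 0, offsets, intakes)
        assert curve.auc == 43_200.0

    def test_hand_computed_trapezoid(self):
        x = [0, 21_600, 43_200, 86_400]
        y = [0.0, 0.5, 1.0, 1.0]
        assert trapezoid_auc(x, y) == pytest.approx(64_800.0)

    def test_all_intake_at_delivery(self):
        curve = cumulative_curve("c", 0, [0.0], [5.0])
        assert curve.auc == pytest.approx(86_400.0)

    def test_worked_example_proportions(self):
        # first visits of a 43.8 kg day: 0.4, 0.2 and 5.3 kg
        props = np.array([0.4, 0.2, 5.3]) / 43.8
        assert round(props[0], 3) == 0.009
        assert round(props[1], 3) == 0.005
        assert round(props[2], 3) == 0.121
        rest = 43.8 - 5.9  # remainder of the day in one later meal
        curve = cumulative_curve(
            "c", 0, [100.0, 200.0, 300.0, 20_000.0], [0.4, 0.2, 5.3, rest]
        )
        assert np.allclose(curve.cumprops[1:4], np.cumsum(props), atol=5e-7)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(1, 40)
            curve = cumulative_curve(
                "c", 0, np.sort(rng.uniform(0, HORIZON_S, n)), rng.uniform(0.1, 5, n)
            )
            assert curve.cumprops[-2] == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= curve.auc <= HORIZON_S

    def test_shifting_mass_earlier_increases_auc(self):
        late = cumulative_curve("c", 0, [10_000, 50_000], [2.0, 8.0])
        early = cumulative_curve("c", 0, [10_000, 40_000], [2.0, 8.0])
        assert early.auc > late.auc

    def test_trapezoid_matches_fine_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 50))
            curve = cumulative_curve(
                "c", 0, np.sort(rng.uniform(0, HORIZON_S, n)), rng.uniform(0.05, 6, n)
            )
            grid = np.arange(0, HORIZON_S + 1.0)
            interp = np.interp(grid, curve.offsets, curve.cumprops)
            oracle = np.trapezoid(interp, grid)
            assert curve.auc == pytest.approx(oracle, rel=1e-6)

    def test_unordered_offsets_rejected(self):
        with pytest.raises(ValueError):
            trapezoid_auc([0, 100, 50], [0, 0.5, 1.0])

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            cumulative_curve("c", 0, [100.0], [0.0])


def day_frame(rows):
    return pd.DataFrame(
        rows, columns=["cow_id", "pen_id", "day_index", "n_visits", "total_intake_kg", "auc"]
    )


class TestDayFilters:
    @pytest.mark.parametrize(
        "n_visits,total,kept",
        [
            (4, 40.0, False),  # fewer than 5 visits
            (5, 40.0, True),
            (10, 12.0, False),  # at the minimum: removed
            (10, 12.1, True),
            (10, 115.0, True),  # at the maximum: retained
            (10, 115.1, False),
        ],
    )
    def test_boundaries(self, n_visits, total, kept):
        days = day_frame([("c", "p", 0, n_visits, total, 50_000.0)])
        out, rep = filter_days(days, DayFilterConfig())
        assert (len(out) == 1) is kept
        assert rep["n_read"] == rep["n_retained"] + sum(
            v for k, v in rep.items() if k.startswith("removed_")
        )

    def test_outlier_rule_matches_manual_z(self):
        rng = np.random.default_rng(5)
        aucs = rng.normal(56_000, 1_000, 40)
        days = day_frame([("c", "p", i, 10, 40.0, a) for i, a in enumerate(aucs)])
        out, rep = remove_outlier_days(days, z_threshold=3.5)
        z = np.abs(aucs - aucs.mean()) / aucs.std(ddof=1)
        assert rep["removed_auc_outlier"] == int((z > 3.5).sum())
        assert set(out["day_index"]) == set(np.flatnonzero(z <= 3.5))

    def test_removal_boundary_sits_at_3_5_sd(self):
        """Days just beyond 3.5 SD of the cow mean are removed, days just
        inside are kept; the candidate day itself enters the mean and SD
        (single pass over the whole period)."""
        base = np.array([55_000.0, 57_000.0] * 15)

        def z_of(v):
            aucs = np.append(base, v)
            return abs(v - aucs.mean()) / aucs.std(ddof=1)

        # locate the AUC value whose inclusive z score crosses 3.5
        lo, hi = 57_000.0, 90_000.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lo, hi = (mid, hi) if z_of(mid) < 3.5 else (lo, mid)
        for candidate, expect_removed in [(hi + 200, True), (lo - 200, False)]:
            aucs = np.append(base, candidate)
            days = day_frame([("c", "p", i, 10, 40.0, a) for i, a in enumerate(aucs)])
            out, _ = remove_outlier_days(days)
            assert (candidate not in out["auc"].to_numpy()) is expect_removed

    def test_identical_days_all_retained(self):
        days = day_frame([("c", "p", i, 10, 40.0, 50_000.0) for i in range(5)])
        out, rep = remove_outlier_days(days)
        assert len(out) == 5
        assert rep["removed_auc_outlier"] == 0


class TestCowSummary:
    def test_hand_computed_phenotype(self):
        days = day_frame(
            [("c", "p", 0, 10, 40.0, 55_000.0), ("c", "p", 1, 10, 40.0, 57_000.0)]
        )
        pheno, _ = summarize_cows(days, min_days=2)
        row = pheno.iloc[0]
        assert row["auc_mean"] == pytest.approx(56_000.0)
        assert row["var_dauc"] == pytest.approx(2_000_000.0)
        assert row["log_var_dauc"] == pytest.approx(14.5087, abs=1e-4)

    def test_zero_variance_flagged(self):
        days = day_frame([("c", "p", i, 10, 40.0, 50_000.0) for i in range(3)])
        pheno, rep = summarize_cows(days, min_days=2)
        assert not pheno.iloc[0]["log_var_defined"]
        assert np.isnan(pheno.iloc[0]["log_var_dauc"])
        assert rep["flagged_zero_variance"] == 1

    def test_min_days_exclusion(self):
        days = day_frame([("c", "p", i, 10, 40.0, 50_000.0 + i) for i in range(6)])
        pheno, rep = summarize_cows(days, min_days=10)
        assert len(pheno) == 0
        assert rep["excluded_min_days"] == 1


def test_pipeline_stage_determinism():
    """Identical visit table + config give byte-identical phenotype tables."""
    rng = np.random.default_rng(2)
    rows = []
    for cow in ("c1", "c2"):
        for d in range(1, 5):
            date = f"2022-06-{d:02d}"
            for off in np.sort(rng.uniform(0, 10 * 3600, 8)):
                t = pd.Timestamp(f"{date} 11:05:00") + pd.Timedelta(seconds=float(off))
                rows.append(
                    {
                        "cow_id": cow,
                        "pen_id": "pen0",
                        "date": pd.Timestamp(date).date(),
                        "entry": t,
                        "exit": t + pd.Timedelta(seconds=120),
                        "intake": float(rng.uniform(1, 5)),
                        "duration": 120.0,
                    }
                )
    visits = pd.DataFrame(rows)

    def run():
        windows, assigned = assign_day_windows(visits, FeedDeliverySchedule())
        days = daily_curves(assigned, windows)
        days, _ = filter_days(days)
        days, _ = remove_outlier_days(days)
        pheno, _ = summarize_cows(days, min_days=2)
        return pheno

    pd.testing.assert_frame_equal(run(), run())
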