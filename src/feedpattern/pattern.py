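"""Within-day feeding-pattern phenotypes from cleaned visit logs.

The daily phenotype is built per cow and feeding day:

1. order bunk visits in time across all cows of a pen;
2. set Time 0 to the first visit by any cow after the lockout that precedes
   the day's first fresh-feed delivery;
3. express each of the cow's visit intakes as a proportion of her total
   intake that day;
4. accumulate the proportions over the day (anchored at (0, 0) and at
   (86 400 s, 1));
5. integrate the cumulative curve by the trapezoid rule.

The resulting AUC lives in seconds: 43 200 (half a day) for perfectly
uniform feeding, larger when intake concentrates early after delivery,
smaller when the cow defers her feeding. Day-level filters remove sparse or
implausible cow-days, a 3.5 SD rule removes a cow's outlying days, and the
per-cow phenotypes are the mean daily AUC (feeding pattern) and the natural
log of the variance of daily AUC (consistency, log-Var-dAUC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HORIZON_S",
    "FeedDeliverySchedule",
    "DayFilterConfig",
    "DailyCurve",
    "assign_day_windows",
    "cumulative_curve",
    "trapezoid_auc",
    "daily_curves",
    "filter_days",
    "remove_outlier_days",
    "summarize_cows",
]

HORIZON_S = 86_400  # integration horizon: one day, in seconds


@dataclass
class FeedDeliverySchedule:
    """Clock times of the two daily fresh-feed deliveries.

    ``first_delivery`` marks the end of the lockout for the morning feeding:
    Time 0 is the first pen visit at or after it. Per pen-date overrides can
    be supplied as a frame with pen_id, date, first_delivery columns.
    """

    first_delivery: str = "11:00:00"
    second_delivery: str = "17:00:00"
    lockout_minutes: float = 60.0
    overrides: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if pd.Timedelta(self.first_delivery) >= pd.Timedelta(self.second_delivery):
            raise ValueError("first delivery must precede the second within the day")

    def first_delivery_at(self, pen_id, date) -> pd.Timestamp:
        clock = self.first_delivery
        if self.overrides is not None:
            hit = self.overrides[
                (self.overrides["pen_id"] == pen_id)
                & (pd.to_datetime(self.overrides["date"]).dt.date == date)
            ]
            if len(hit):
                clock = hit["first_delivery"].iloc[0]
        return pd.Timestamp(date) + pd.Timedelta(clock)


def assign_day_windows(
    visits: pd.DataFrame,
    schedule: FeedDeliverySchedule | None = None,
    inference_window: tuple[str, str] = ("10:00:00", "12:00:00"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a pen's visits into feeding-day windows anchored at Time 0.

    With a schedule, each date's Time 0 is the earliest pen visit entering at
    or after the first-delivery time. Without one, delivery time is inferred
    as the end of the longest pen-wide visit gap inside ``inference_window``
    (the nominal morning delivery window): the lockout empties the bunks, so
    the delivery shows up as the day's longest morning silence.

    Returns ``(windows, visits)`` where ``windows`` has one row per pen
    feeding day (pen_id, day_index, time0, end) and ``visits`` gains a
    ``day_index`` column (-1 for visits before the first window). A visit
    belongs to the window containing its exit time, the point at which its
    intake is realised.
    """
    visits = visits.copy()
    visits["day_index"] = -1
    windows_rows = []
    for pen, pen_visits in visits.groupby("pen_id", sort=False):
        time0s = []
        for date, day_visits in pen_visits.groupby("date", sort=True):
            entries = day_visits["entry"].sort_values()
            if schedule is not None:
                delivery = schedule.first_delivery_at(pen, date)
            else:
                lo = pd.Timestamp(date) + pd.Timedelta(inference_window[0])
                hi = pd.Timestamp(date) + pd.Timedelta(inference_window[1])
                inside = entries[(entries >= lo) & (entries <= hi)].to_list()
                edges = [lo, *inside]
                gaps = np.diff([e.value for e in edges])
                if len(inside) == 0:
                    continue  # no morning activity: no window for this date
                delivery = inside[int(np.argmax(gaps))] if len(gaps) else inside[0]
            after = entries[entries >= delivery]
            if after.empty:
                continue  # nobody visited after delivery: skip the date
            time0s.append((date, after.iloc[0]))
        time0s.sort(key=lambda t: t[1])
        mask = visits["pen_id"] == pen
        exits = visits.loc[mask, "exit"]
        stamps = pd.Series([t for _, t in time0s])
        idx = stamps.searchsorted(exits, side="right") - 1
        visits.loc[mask, "day_index"] = idx
        for k, (date, t0) in enumerate(time0s):
            end = time0s[k + 1][1] if k + 1 < len(time0s) else t0 + pd.Timedelta(seconds=HORIZON_S)
            windows_rows.append(
                {"pen_id": pen, "day_index": k, "date": date, "time0": t0, "end": end}
            )
    windows = pd.DataFrame(
        windows_rows, columns=["pen_id", "day_index", "date", "time0", "end"]
    )
    return windows, visits


@dataclass
class DailyCurve:
    """One cow-day's anchored cumulative intake-proportion curve."""

    cow_id: object
    day_index: int
    offsets: np.ndarray  # seconds since Time 0, anchored at 0 and HORIZON_S
    cumprops: np.ndarray  # cumulative proportions, 0 -> 1
    n_visits: int
    total_intake_kg: float
    auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc = trapezoid_auc(self.offsets, self.cumprops)


def cumulative_curve(
    cow_id,
    day_index: int,
    offsets_s: np.ndarray,
    intakes_kg: np.ndarray,
    horizon_s: float = HORIZON_S,
) -> DailyCurve:
    """Anchored cumulative proportion curve for one cow-day.

    ``offsets_s`` are visit times (seconds since Time 0, non-decreasing);
    intakes are converted to proportions of the day's total. Anchors (0, 0)
    and (horizon, 1) are prepended/appended; offsets beyond the horizon are
    clamped onto it (their intake still counts).
    """
    offsets = np.asarray(offsets_s, dtype=float)
    intakes = np.asarray(intakes_kg, dtype=float)
    if offsets.shape != intakes.shape or offsets.size == 0:
        raise ValueError("offsets and intakes must be equal-length, non-empty")
    order = np.argsort(offsets, kind="stable")
    offsets, intakes = offsets[order], intakes[order]
    total = float(intakes.sum())
    if total <= 0:
        raise ValueError("total intake must be positive to form proportions")
    cum = np.cumsum(intakes) / total
    if abs(cum[-1] - 1.0) > 1e-9:
        raise AssertionError("cumulative proportions failed to reach 1")
    offsets = np.clip(offsets, 0.0, horizon_s)
    anchored_x = np.concatenate([[0.0], offsets, [float(horizon_s)]])
    anchored_y = np.concatenate([[0.0], cum, [1.0]])
    return DailyCurve(
        cow_id=cow_id,
        day_index=day_index,
        offsets=anchored_x,
        cumprops=anchored_y,
        n_visits=int(len(intakes)),
        total_intake_kg=total,
    )


def trapezoid_auc(offsets: np.ndarray, cumprops: np.ndarray) -> float:
    """Trapezoid-rule area under the cumulative proportion curve, in seconds."""
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(cumprops, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("curve offsets must be non-decreasing")
    return float(np.trapezoid(y, x))


def daily_curves(
    visits: pd.DataFrame,
    windows: pd.DataFrame,
    horizon_s: float = HORIZON_S,
    keep_curves: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[DailyCurve]]:
    """Build the per-cow-day curve summary from window-assigned visits.

    ``visits`` must carry the ``day_index`` column from
    :func:`assign_day_windows`. Returns a frame with one row per cow-day
    (cow_id, pen_id, day_index, n_visits, total_intake_kg, auc), plus the
    full :class:`DailyCurve` objects when ``keep_curves`` is set.
    """
    t0 = windows.set_index(["pen_id", "day_index"])["time0"]
    rows = []
    curves: list[DailyCurve] = []
    valid = visits[visits["day_index"] >= 0]
    for (pen, day, cow), grp in valid.groupby(["pen_id", "day_index", "cow_id"], sort=True):
        start = t0.loc[(pen, day)]
        offsets = (grp["exit"] - start).dt.total_seconds().to_numpy()
        curve = cumulative_curve(cow, day, offsets, grp["intake"].to_numpy(), horizon_s)
        rows.append(
            {
                "cow_id": cow,
                "pen_id": pen,
                "day_index": day,
                "n_visits": curve.n_visits,
                "total_intake_kg": curve.total_intake_kg,
                "auc": curve.auc,
            }
        )
        if keep_curves:
            curves.append(curve)
    summary = pd.DataFrame(
        rows,
        columns=["cow_id", "pen_id", "day_index", "n_visits", "total_intake_kg", "auc"],
    )
    return (summary, curves) if keep_curves else summary


@dataclass
class DayFilterConfig:
    """Cow-day exclusion thresholds: retained iff ``n_visits >= min_visits``
    and ``min_intake_exclusive < total intake <= max_intake_inclusive``."""

    min_visits: int = 5
    min_intake_exclusive: float = 12.0
    max_intake_inclusive: float = 115.0


def filter_days(
    days: pd.DataFrame, config: DayFilterConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Remove sparse or implausible cow-days (few visits, intake out of range)."""
    config = config or DayFilterConfig()
    few = days["n_visits"].to_numpy() < config.min_visits
    low = days["total_intake_kg"].to_numpy() <= config.min_intake_exclusive
    high = days["total_intake_kg"].to_numpy() > config.max_intake_inclusive
    removed = {
        "too_few_visits": int(few.sum()),
        "intake_at_or_below_min": int((low & ~few).sum()),
        "intake_above_max": int((high & ~few & ~low).sum()),
    }
    keep = ~(few | low | high)
    return days.loc[keep].reset_index(drop=True), {
        "n_read": len(days),
        "n_retained": int(keep.sum()),
        **{f"removed_{k}": v for k, v in removed.items()},
    }


def remove_outlier_days(
    days: pd.DataFrame, z_threshold: float = 3.5
) -> tuple[pd.DataFrame, dict]:
    """Drop a cow's days whose AUC sits more than ``z_threshold`` sample SDs
    from her mean AUC over the whole period.

    Single pass: the mean and SD are computed once from all of the cow's
    days (not re-estimated after removals). Cows with identical days
    (SD = 0) lose nothing.
    """
    days = days.reset_index(drop=True)
    keep = np.ones(len(days), dtype=bool)
    for _, grp in days.groupby("cow_id", sort=False):
        auc = grp["auc"].to_numpy()
        if len(auc) < 2:
            continue
        sd = auc.std(ddof=1)
        if sd == 0:
            continue
        z = np.abs(auc - auc.mean()) / sd
        keep[grp.index.to_numpy()[z > z_threshold]] = False
    out = days.loc[keep].reset_index(drop=True)
    return out, {
        "n_read": len(days),
        "n_retained": int(keep.sum()),
        "removed_auc_outlier": int((~keep).sum()),
    }


def summarize_cows(
    days: pd.DataFrame, min_days: int = 20
) -> tuple[pd.DataFrame, dict]:
    """Per-cow phenotypes: mean daily AUC and log variance of daily AUC.

    Cows with fewer than ``max(2, min_days)`` retained days are excluded.
    ``var_dauc`` is the sample (n-1) variance; when it is exactly zero the
    log is undefined, the cow is flagged (``log_var_defined = False``) and
    her ``log_var_dauc`` is NaN.
    """
    min_days = max(2, min_days)
    rows = []
    n_excluded = 0
    for cow, grp in days.groupby("cow_id", sort=True):
        auc = grp["auc"].to_numpy()
        if len(auc) < min_days:
            n_excluded += 1
            continue
        var = float(auc.var(ddof=1))
        rows.append(
            {
                "cow_id": cow,
                "n_days": len(auc),
                "auc_mean": float(auc.mean()),
                "var_dauc": var,
                "log_var_dauc": float(np.log(var)) if var > 0 else np.nan,
                "log_var_defined": var > 0,
            }
        )
    pheno = pd.DataFrame(
        rows,
        columns=["cow_id", "n_days", "auc_mean", "var_dauc", "log_var_dauc", "log_var_defined"],
    )
    report = {
        "n_cows_in": int(days["cow_id"].nunique()),
        "n_cows_out": len(pheno),
        "excluded_min_days": n_excluded,
        "flagged_zero_variance": int((~pheno["log_var_defined"]).sum()) if len(pheno) else 0,
    }
    return pheno, report
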