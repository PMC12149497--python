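"""Reading and cleaning automated-feeder (bunk) visit logs.

A visit record is one animal's stay at one feeder: entry/exit timestamps and
the feed weight in the bin at entry and exit. Derived per visit:
``intake = weight_in - weight_out`` (kg as-fed) and ``duration`` in seconds,
with exits that wrap past midnight resolved to the next calendar day.

Cleaning removes visits with non-positive or implausibly large intakes and
implausibly short or long durations; retained sets are intake in (0, 20] kg
and duration in [5, 3000] s by default, with the removal conditions read as
strict inequalities. Every removal is attributed to the first matching rule
so the cleaning report reconciles exactly with the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "VisitFilterConfig",
    "CleaningReport",
    "read_visits",
    "filter_visits",
    "select_first_trial",
]

REQUIRED_COLUMNS = (
    "cow_id",
    "feeder_id",
    "date",
    "entry_time",
    "exit_time",
    "weight_in_kg",
    "weight_out_kg",
)
OPTIONAL_COLUMNS = ("pen_id",)


@dataclass
class VisitFilterConfig:
    """Visit-level exclusion thresholds.

    A visit is retained iff
    ``min_intake_exclusive < intake <= max_intake_inclusive`` and
    ``min_duration_inclusive <= duration <= max_duration_inclusive``.
    """

    min_intake_exclusive: float = 0.0
    max_intake_inclusive: float = 20.0
    min_duration_inclusive: float = 5.0
    max_duration_inclusive: float = 3000.0

    def __post_init__(self) -> None:
        if self.min_intake_exclusive >= self.max_intake_inclusive:
            raise ValueError("intake bounds must satisfy min < max")
        if self.min_duration_inclusive >= self.max_duration_inclusive:
            raise ValueError("duration bounds must satisfy min < max")


@dataclass
class CleaningReport:
    """Counts of records read, removed per rule (first match) and retained."""

    n_read: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def __post_init__(self) -> None:
        assert self.n_read == self.n_retained + sum(self.removed.values()), (
            "cleaning report does not reconcile"
        )

    def as_dict(self) -> dict:
        out = {"n_read": self.n_read, "n_retained": self.n_retained}
        out.update({f"removed_{k}": v for k, v in self.removed.items()})
        return out

    def to_text(self) -> str:
        return "\n".join(f"{k}\t{v}" for k, v in self.as_dict().items()) + "\n"


def read_visits(path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited visit log into a typed visit table.

    Expected columns: cow_id, feeder_id, date (ISO-8601), entry_time,
    exit_time (HH:MM:SS), weight_in_kg, weight_out_kg, plus an optional
    pen_id passthrough. Returns a frame with parsed ``entry``/``exit``
    timestamps (exit rolled to the next day when it precedes entry),
    ``intake`` (kg) and ``duration`` (s).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"visit log {path} is missing columns: {missing}")
    unknown = [
        c for c in raw.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    ]
    if unknown:
        raise ValueError(f"visit log {path} has unknown columns: {unknown}")
    if raw.empty:
        out = pd.DataFrame(
            columns=[*REQUIRED_COLUMNS, "pen_id", "entry", "exit", "intake", "duration"]
        )
        return out

    def parse(col: str, values: pd.Series, fmt: str) -> pd.Series:
        parsed = pd.to_datetime(values, errors="coerce", format=fmt)
        bad = parsed.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ValueError(f"{path}: malformed {col} at line {line}: {values[bad].iloc[0]!r}")
        return parsed

    stamp = "%Y-%m-%d %H:%M:%S"
    date = parse("date", raw["date"], "%Y-%m-%d")
    entry = parse("entry_time", raw["date"].str.cat(raw["entry_time"], sep=" "), stamp)
    exit_ = parse("exit_time", raw["date"].str.cat(raw["exit_time"], sep=" "), stamp)
    rollover = exit_ < entry
    exit_ = exit_ + pd.to_timedelta(rollover.astype(int), unit="D")

    def numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(f"{path}: malformed {col} at line {line}")
        return vals.to_numpy(dtype=float)

    w_in = numeric("weight_in_kg")
    w_out = numeric("weight_out_kg")
    return pd.DataFrame(
        {
            "cow_id": raw["cow_id"],
            "feeder_id": raw["feeder_id"],
            "pen_id": raw["pen_id"] if "pen_id" in raw.columns else "pen0",
            "date": date.dt.date,
            "entry": entry,
            "exit": exit_,
            "weight_in_kg": w_in,
            "weight_out_kg": w_out,
            "intake": w_in - w_out,
            "duration": (exit_ - entry).dt.total_seconds(),
        }
    )


def filter_visits(
    visits: pd.DataFrame, config: VisitFilterConfig | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the visit-level exclusion rules.

    Removals are attributed to the first matching rule, intake rules before
    duration rules; the retained set does not depend on the order.
    """
    config = config or VisitFilterConfig()
    intake = visits["intake"].to_numpy(dtype=float)
    duration = visits["duration"].to_numpy(dtype=float)
    rules = {
        "intake_nonpositive": intake <= config.min_intake_exclusive,
        "intake_above_max": intake > config.max_intake_inclusive,
        "duration_below_min": duration < config.min_duration_inclusive,
        "duration_above_max": duration > config.max_duration_inclusive,
    }
    removed_by: dict[str, int] = {}
    already = np.zeros(len(visits), dtype=bool)
    for name, mask in rules.items():
        first_match = mask & ~already
        removed_by[name] = int(first_match.sum())
        already |= mask
    retained = visits.loc[~already].reset_index(drop=True)
    report = CleaningReport(
        n_read=len(visits), removed=removed_by, n_retained=len(retained)
    )
    return retained, report


def select_first_trial(
    visits: pd.DataFrame,
    trials: pd.DataFrame,
    on_missing_cow: str = "warn",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Keep only records inside each cow's earliest trial window.

    ``trials`` needs cow_id, trial_id, start_date, end_date (inclusive).
    Cows with multiple trials contribute data from the first trial only;
    records dated outside every trial window are dropped and counted.
    ``on_missing_cow`` controls handling of cows absent from the table:
    ``warn`` drops their records with a counted warning, ``error`` raises.
    """
    if on_missing_cow not in {"warn", "error"}:
        raise ValueError("on_missing_cow must be 'warn' or 'error'")
    t = trials.copy()
    t["start_date"] = pd.to_datetime(t["start_date"]).dt.date
    t["end_date"] = pd.to_datetime(t["end_date"]).dt.date
    first = (
        t.sort_values(["cow_id", "start_date"]).groupby("cow_id", as_index=True).first()
    )
    missing = set(visits["cow_id"]) - set(first.index)
    if missing and on_missing_cow == "error":
        raise ValueError(f"cows missing from trial assignment: {sorted(missing)[:10]}")

    in_window = np.zeros(len(visits), dtype=bool)
    known = visits["cow_id"].isin(first.index).to_numpy()
    if known.any():
        sub = visits.loc[known]
        start = first.loc[sub["cow_id"], "start_date"].to_numpy()
        end = first.loc[sub["cow_id"], "end_date"].to_numpy()
        d = sub["date"].to_numpy()
        in_window[known] = (d >= start) & (d <= end)
    retained = visits.loc[in_window].reset_index(drop=True)
    report = CleaningReport(
        n_read=len(visits),
        removed={
            "cow_not_in_trial_table": int((~known).sum()),
            "outside_first_trial_window": int((known & ~in_window).sum()),
        },
        n_retained=len(retained),
    )
    return retained, report
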