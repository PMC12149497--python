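"""Feed-efficiency trait derivation for lactating dairy cows.

Per-cow traits:

* ``MilkE`` — secreted milk energy (Mcal/day), a linear combination of fat,
  protein and lactose percentages scaled by milk yield, computed weekly and
  averaged per cow;
* ``mBW`` — metabolic body weight, the cow's average ``BW**0.75``;
* ``dBW`` — body-weight change over the trial, taken from the endpoints of a
  per-cow linear regression of BW on trial day (robust to weighing noise);
* ``RFI`` — residual feed intake, the residual of an ordinary least-squares
  regression of dry matter intake on days-in-milk class, lactation number,
  cohort (trial-treatment) and the covariates MilkE, mBW and dBW.

Low RFI marks a cow eating less than expected for her production, body size
and weight change, i.e. a more feed-efficient cow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "MILKE_COEFFICIENTS",
    "DIM_CLASS_LABELS",
    "RFIModelSpec",
    "dim_class",
    "milk_energy",
    "cow_milke",
    "impute_bw",
    "metabolic_bw",
    "delta_bw",
    "fit_rfi",
]

# Mcal of secreted milk energy per kg of milk, per percentage point of component
MILKE_COEFFICIENTS = {"fat": 0.0929, "protein": 0.0563, "lactose": 0.0395}

# 16-day days-in-milk classes for mid-lactation cows (DIM >= 50); days above
# the last printed class boundary fall in the open-ended top class
DIM_CLASS_LABELS = (
    "50-66",
    "67-83",
    "84-100",
    "101-117",
    "118-134",
    "135-151",
    "152-168",
    "169-185",
    ">186",
)


def dim_class(dim: int) -> str:
    """16-day days-in-milk class label for a DIM value.

    The printed class boundaries run 50-66, ..., 169-185 and then an
    open-ended top class; day 186 itself is assigned to the top class.
    Values below 50 are outside the mid-lactation study window.
    """
    dim = int(dim)
    if dim < 50:
        raise ValueError(f"DIM {dim} is below the study window (>= 50)")
    if dim > 185:
        return DIM_CLASS_LABELS[-1]
    return DIM_CLASS_LABELS[(dim - 50) // 17]


def milk_energy(
    fat_pct, protein_pct, lactose_pct, milk_yield_kg
):
    """Secreted milk energy (Mcal) for one week's component test.

    ``(0.0929*fat% + 0.0563*protein% + 0.0395*lactose%) * milk yield (kg)``.
    Accepts scalars or aligned arrays.
    """
    fat = np.asarray(fat_pct, dtype=float)
    prot = np.asarray(protein_pct, dtype=float)
    lac = np.asarray(lactose_pct, dtype=float)
    yld = np.asarray(milk_yield_kg, dtype=float)
    if np.any(fat < 0) or np.any(prot < 0) or np.any(lac < 0) or np.any(yld < 0):
        raise ValueError("milk components and yield must be non-negative")
    e = (
        MILKE_COEFFICIENTS["fat"] * fat
        + MILKE_COEFFICIENTS["protein"] * prot
        + MILKE_COEFFICIENTS["lactose"] * lac
    ) * yld
    return float(e) if e.ndim == 0 else e


def cow_milke(milk_records: pd.DataFrame) -> pd.Series:
    """Per-cow MilkE: weekly milk energy averaged across weeks.

    Expects columns cow_id, milk_yield, fat_pct, protein_pct, lactose_pct.
    """
    weekly = milk_energy(
        milk_records["fat_pct"],
        milk_records["protein_pct"],
        milk_records["lactose_pct"],
        milk_records["milk_yield"],
    )
    out = (
        pd.Series(np.asarray(weekly), index=milk_records["cow_id"].to_numpy())
        .groupby(level=0)
        .mean()
        .rename("milke")
    )
    out.index.name = "cow_id"
    return out


def _bw_line(days: np.ndarray, bw: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of BW on trial day."""
    if len(days) < 2:
        raise ValueError("body-weight regression needs at least 2 measurements")
    slope, intercept = np.polyfit(days, bw, 1)
    return float(slope), float(intercept)


def impute_bw(
    series: pd.DataFrame, day_range: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Fill missing daily BW with a per-cow linear regression on trial day.

    ``series`` holds cow_id, day, bw for the measured days. The output covers
    every day in ``day_range`` (default: each cow's own measured span) with a
    boolean ``imputed`` column; measured values are kept as observed.
    """
    out = []
    for cow, grp in series.groupby("cow_id"):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        bw = grp["bw"].to_numpy(dtype=float)
        slope, intercept = _bw_line(days, bw)
        lo, hi = day_range if day_range is not None else (int(days[0]), int(days[-1]))
        all_days = np.arange(lo, hi + 1)
        measured = dict(zip(grp["day"].astype(int), bw))
        vals = [measured.get(int(d), slope * d + intercept) for d in all_days]
        out.append(
            pd.DataFrame(
                {
                    "cow_id": cow,
                    "day": all_days,
                    "bw": vals,
                    "imputed": [int(d) not in measured for d in all_days],
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def metabolic_bw(bw: np.ndarray) -> float:
    """Metabolic body weight: the average of daily BW**0.75 (kg^0.75)."""
    bw = np.asarray(bw, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weights must be positive")
    return float(np.mean(bw**0.75))


def delta_bw(series: pd.DataFrame, day_range: tuple[int, int] | None = None) -> float:
    """BW change over the trial: regression-line BW at trial end minus start.

    Using the fitted endpoints rather than raw first/last weighings keeps the
    trait insensitive to single-day scale noise.
    """
    days = series["day"].to_numpy(dtype=float)
    bw = series["bw"].to_numpy(dtype=float)
    slope, _ = _bw_line(days, bw)
    lo, hi = day_range if day_range is not None else (days.min(), days.max())
    return float(slope * (hi - lo))


def derive_efficiency_traits(
    milk: pd.DataFrame,
    bw: pd.DataFrame,
    dmi: pd.DataFrame,
    cows: pd.DataFrame,
    day_range: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Assemble the per-cow trait table feeding the RFI model.

    ``milk``/``bw``/``dmi`` are the record tables (weekly components,
    body-weight series, average daily intake); ``cows`` carries cow_id plus
    the factor columns (lactation, dim_class, cohort). Body weights are
    first completed by per-cow linear imputation over ``day_range``.
    """
    milke = cow_milke(milk).reset_index()
    full_bw = impute_bw(bw, day_range)
    rows = []
    for cow, grp in full_bw.groupby("cow_id"):
        measured = grp[~grp["imputed"]]
        rows.append(
            {
                "cow_id": cow,
                "mbw": metabolic_bw(grp["bw"].to_numpy()),
                "delta_bw": delta_bw(measured, day_range),
            }
        )
    return (
        pd.DataFrame(rows)
        .merge(milke, on="cow_id")
        .merge(dmi, on="cow_id")
        .merge(cows, on="cow_id")
    )


@dataclass
class RFIModelSpec:
    """Right-hand side of the residual-feed-intake regression."""

    response: str = "dmi"
    factors: tuple[str, ...] = ("dim_class", "lactation", "cohort")
    covariates: tuple[str, ...] = ("milke", "mbw", "delta_bw")

    def formula(self) -> str:
        terms = [f"C({f})" for f in self.factors] + list(self.covariates)
        return f"{self.response} ~ " + " + ".join(terms)


def fit_rfi(
    traits: pd.DataFrame, spec: RFIModelSpec | None = None
) -> tuple[pd.DataFrame, dict]:
    """Fit the RFI model by OLS and attach per-cow residuals.

    Returns the input frame with an ``rfi`` column plus a report holding the
    partial regression coefficients (b1 = MilkE, b2 = mBW, b3 = dBW by the
    default spec), factor-level estimates and fit summary statistics.
    Reference-level coding with an intercept; RFI is invariant to the coding.
    """
    spec = spec or RFIModelSpec()
    missing = [
        c
        for c in (spec.response, *spec.factors, *spec.covariates)
        if c not in traits.columns
    ]
    if missing:
        raise ValueError(f"trait table is missing columns: {missing}")
    model = smf.ols(spec.formula(), data=traits)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify aliased columns by pivoted QR on the design
        from scipy.linalg import qr

        _, _, piv = qr(model.exog, mode="economic", pivoting=True)
        aliased = [model.exog_names[i] for i in sorted(piv[rank:])]
        raise ValueError(f"RFI design is rank deficient; aliased columns: {aliased}")
    fit = model.fit()
    out = traits.copy()
    out["rfi"] = fit.resid.to_numpy()
    report = {
        "coefficients": dict(zip(fit.params.index, fit.params.to_numpy())),
        "covariate_coefficients": {c: float(fit.params[c]) for c in spec.covariates},
        "n": int(fit.nobs),
        "r_squared": float(fit.rsquared),
        "sigma2_e": float(fit.mse_resid),
    }
    return out, report
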