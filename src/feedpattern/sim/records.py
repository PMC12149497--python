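"""Milk, body-weight and intake record simulation for feed-efficiency traits.

Weekly milk component tests, a body-weight series with linear trend, noise
and a configurable weighing schedule, and a daily dry matter intake built
from the residual-feed-intake model's own right-hand side: DMI is the sum
of an intercept, partial regressions on secreted milk energy, metabolic
body weight and body-weight change, factor effects, and a true-RFI residual
with known variance. Because DMI is generated from the model that will be
fitted, the fitted residual recovers the injected true RFI up to estimation
error — the property the downstream tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..efficiency import milk_energy

__all__ = ["EfficiencySimConfig", "simulate_efficiency_records"]


@dataclass
class EfficiencySimConfig:
    """Trait-level simulation settings.

    Component means mirror typical Holstein mid-lactation values; the DMI
    intercept is derived from ``dmi_mean_kg`` and the expected covariate
    means, so the simulated herd average lands on the configured DMI no
    matter how the other settings move.
    """

    n_weeks: int = 6
    fat_pct: tuple[float, float] = (4.0, 0.5)
    protein_pct: tuple[float, float] = (3.2, 0.3)
    lactose_pct: tuple[float, float] = (4.8, 0.15)
    milk_yield_kg: tuple[float, float] = (40.0, 7.0)
    bw_start_kg: tuple[float, float] = (625.0, 60.0)
    bw_slope_kg_day: tuple[float, float] = (0.10, 0.15)
    bw_noise_sd_kg: float = 8.0
    bw_every_days: int = 7  # weighing schedule; 1 = daily (no missingness)
    dmi_mean_kg: float = 24.8
    b_milke: float = 0.35
    b_mbw: float = 0.09
    b_delta_bw: float = 0.02
    rfi_sd_kg: float = 1.63
    factor_effect_sd_kg: float = 0.5

    @property
    def trial_days(self) -> int:
        return self.n_weeks * 7

    def expected_milke(self) -> float:
        return milk_energy(
            self.fat_pct[0], self.protein_pct[0], self.lactose_pct[0], self.milk_yield_kg[0]
        )

    def dmi_intercept(self) -> float:
        mid_bw = self.bw_start_kg[0] + self.bw_slope_kg_day[0] * self.trial_days / 2
        return (
            self.dmi_mean_kg
            - self.b_milke * self.expected_milke()
            - self.b_mbw * mid_bw**0.75
            - self.b_delta_bw * self.bw_slope_kg_day[0] * self.trial_days
        )


def simulate_efficiency_records(
    cows: pd.DataFrame,
    config: EfficiencySimConfig | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate milk, body-weight and DMI records for a cow table.

    ``cows`` needs a ``cow_id`` column; optional ``lactation``, ``dim_class``
    and ``cohort`` columns contribute randomly drawn level effects to DMI
    (so the RFI model has real factor structure to absorb). Returns a dict
    with ``milk``, ``bw``, ``dmi`` and a ``truth`` table holding each cow's
    true RFI, covariate values and the generating coefficients.
    """
    config = config or EfficiencySimConfig()
    if config.n_weeks < 3:
        raise ValueError("trials shorter than 3 weeks cannot anchor the BW regression")
    rng = np.random.default_rng(seed)
    n = len(cows)
    cow_ids = cows["cow_id"].to_numpy()

    # weekly milk components
    weeks = np.arange(1, config.n_weeks + 1)
    milk_rows = []
    for w in weeks:
        milk_rows.append(
            pd.DataFrame(
                {
                    "cow_id": cow_ids,
                    "week": w,
                    "milk_yield": np.clip(
                        rng.normal(*config.milk_yield_kg, size=n), 5.0, None
                    ),
                    "fat_pct": np.clip(rng.normal(*config.fat_pct, size=n), 1.5, 9.0),
                    "protein_pct": np.clip(
                        rng.normal(*config.protein_pct, size=n), 1.5, 7.0
                    ),
                    "lactose_pct": np.clip(
                        rng.normal(*config.lactose_pct, size=n), 3.0, 6.5
                    ),
                }
            )
        )
    milk = pd.concat(milk_rows, ignore_index=True).sort_values(["cow_id", "week"])

    # true BW line per cow; measured on the weighing schedule with noise
    start = rng.normal(*config.bw_start_kg, size=n)
    slope = rng.normal(*config.bw_slope_kg_day, size=n)
    days = np.arange(0, config.trial_days + 1)
    measured_days = days[:: config.bw_every_days]
    if measured_days[-1] != days[-1]:
        measured_days = np.append(measured_days, days[-1])
    bw_rows = []
    for i in range(n):
        true_line = start[i] + slope[i] * measured_days
        bw_rows.append(
            pd.DataFrame(
                {
                    "cow_id": cow_ids[i],
                    "day": measured_days,
                    "bw": true_line + rng.normal(0.0, config.bw_noise_sd_kg, len(measured_days)),
                }
            )
        )
    bw = pd.concat(bw_rows, ignore_index=True)

    # true covariates from the generating lines (not the noisy measurements)
    milke_true = (
        milk.groupby("cow_id", sort=False)
        .apply(
            lambda g: float(
                np.mean(
                    milk_energy(
                        g["fat_pct"], g["protein_pct"], g["lactose_pct"], g["milk_yield"]
                    )
                )
            ),
            include_groups=False,
        )
        .reindex(cow_ids)
        .to_numpy()
    )
    mbw_true = np.array(
        [np.mean((start[i] + slope[i] * days) ** 0.75) for i in range(n)]
    )
    dbw_true = slope * config.trial_days

    rfi_true = rng.normal(0.0, config.rfi_sd_kg, size=n)
    dmi = (
        config.dmi_intercept()
        + config.b_milke * milke_true
        + config.b_mbw * mbw_true
        + config.b_delta_bw * dbw_true
        + rfi_true
    )
    for factor in ("lactation", "dim_class", "cohort"):
        if factor in cows.columns:
            levels = pd.unique(cows[factor])
            eff = {lv: rng.normal(0.0, config.factor_effect_sd_kg) for lv in levels}
            dmi = dmi + np.array([eff[lv] for lv in cows[factor]])

    dmi_table = pd.DataFrame({"cow_id": cow_ids, "dmi": dmi})
    truth = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "rfi_true": rfi_true,
            "milke_true": milke_true,
            "mbw_true": mbw_true,
            "delta_bw_true": dbw_true,
            "bw_start_true": start,
            "bw_slope_true": slope,
        }
    )
    truth.attrs["coefficients"] = {
        "intercept": config.dmi_intercept(),
        "b_milke": config.b_milke,
        "b_mbw": config.b_mbw,
        "b_delta_bw": config.b_delta_bw,
    }
    return {"milk": milk, "bw": bw, "dmi": dmi_table, "truth": truth}
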