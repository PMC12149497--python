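"""End-to-end orchestration: simulate -> clean -> phenotype -> traits -> genetics.

The pipeline wires the library stages together behind one configuration
object whose fields name every cleaning threshold with its standard default,
runs the stages in order with per-stage record-count logging, and writes a
manifest (config hash, seed, stage counts, output paths) sufficient to
reproduce the run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, efficiency, events, pattern
from .gibbs import gibbs_univariate
from .pedigree import Pedigree, trace_pedigree
from .posterior import summarize
from .sim import (
    EfficiencySimConfig,
    FeedingSimConfig,
    PedigreeSpec,
    TrueParameters,
    assign_design,
    simulate_breeding_values,
    simulate_efficiency_records,
    simulate_pedigree,
    simulate_visit_events,
)

__all__ = ["PipelineConfig", "RunManifest", "make_demo_data", "run_pipeline"]

log = logging.getLogger("feedpattern")

# cleaning thresholds that a config file must state explicitly: silent
# defaults for these would make the cleaning funnel unauditable
REQUIRED_THRESHOLDS = (
    "visit_min_intake_exclusive",
    "visit_max_intake_inclusive",
    "visit_min_duration_inclusive",
    "visit_max_duration_inclusive",
    "day_min_visits",
    "day_min_intake_exclusive",
    "day_max_intake_inclusive",
    "outlier_sd_threshold",
    "min_days_per_cow",
)


@dataclass
class PipelineConfig:
    """Full-run configuration; round-trips losslessly through YAML."""

    input_dir: str = "inputs"
    output_dir: str = "outputs"
    seed: int = 0
    # visit-level cleaning
    visit_min_intake_exclusive: float = 0.0
    visit_max_intake_inclusive: float = 20.0
    visit_min_duration_inclusive: float = 5.0
    visit_max_duration_inclusive: float = 3000.0
    # day-level cleaning
    day_min_visits: int = 5
    day_min_intake_exclusive: float = 12.0
    day_max_intake_inclusive: float = 115.0
    outlier_sd_threshold: float = 3.5
    min_days_per_cow: int = 20
    # feeding-day anchoring
    first_delivery: str = "11:00:00"
    second_delivery: str = "17:00:00"
    lockout_minutes: float = 60.0
    # genetic analysis
    trace_generations: int = 5
    chain_iterations: int = 20_000
    chain_burn_in: int = 4_000
    chain_thin: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(asdict(cls()).keys())
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        missing = [k for k in REQUIRED_THRESHOLDS if k not in raw]
        if missing:
            raise ValueError(f"config is missing required threshold fields: {missing}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def visit_filter(self) -> events.VisitFilterConfig:
        return events.VisitFilterConfig(
            min_intake_exclusive=self.visit_min_intake_exclusive,
            max_intake_inclusive=self.visit_max_intake_inclusive,
            min_duration_inclusive=self.visit_min_duration_inclusive,
            max_duration_inclusive=self.visit_max_duration_inclusive,
        )

    def day_filter(self) -> pattern.DayFilterConfig:
        return pattern.DayFilterConfig(
            min_visits=self.day_min_visits,
            min_intake_exclusive=self.day_min_intake_exclusive,
            max_intake_inclusive=self.day_max_intake_inclusive,
        )

    def schedule(self) -> pattern.FeedDeliverySchedule:
        return pattern.FeedDeliverySchedule(
            first_delivery=self.first_delivery,
            second_delivery=self.second_delivery,
            lockout_minutes=self.lockout_minutes,
        )


@dataclass
class RunManifest:
    """Record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    complete: bool = False

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


# ---------------------------------------------------------------------------
# demo data


_DEMO_SCALES = {
    # cows, days of visit data, founders, generations
    "small": {"n_cows": 60, "n_days": 26, "n_founders": 30},
    "medium": {"n_cows": 1200, "n_days": 8, "n_founders": 200},
}


def make_demo_data(out_dir, scale: str = "small", seed: int = 0) -> dict[str, Path]:
    """Write a self-contained synthetic study to ``out_dir``.

    Produces pedigree.csv, visits.csv, trials.csv, milk.csv, bw.csv,
    dmi.csv, cows.csv and truth tables. The feeding-pattern targets embed
    additive-genetic structure in both the cow-mean AUC and the day-to-day
    AUC variance, so the full pipeline recovers heritable phenotypes.
    ``medium`` scales the herd up for recovery work but keeps fewer visit
    days per cow.
    """
    if scale not in _DEMO_SCALES:
        raise ValueError(f"scale must be one of {sorted(_DEMO_SCALES)}")
    dims = _DEMO_SCALES[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_cows = dims["n_cows"]
    ped_frame = simulate_pedigree(
        PedigreeSpec(
            n_founders=dims["n_founders"],
            n_generations=5,
            n_per_generation=max(n_cows // 5, 2),
            seed=seed,
        )
    )
    ped = Pedigree.from_frame(ped_frame)
    candidates = ped_frame.loc[ped_frame["generation"] >= 1, "animal"].to_numpy()
    cow_animals = candidates[-n_cows:]
    cow_ids = [f"cow{a:05d}" for a in cow_animals]

    # genetic structure: trait 1 = mean AUC (s), trait 2 = log day-variance
    params = TrueParameters(
        sigma2_a=[1_315_780.0, 0.017],
        sigma2_e=[800_000.0, 0.05],
        mean=[56_345.0, 16.94],
    )
    u = simulate_breeding_values(ped, params, seed=seed + 1)
    rows = ped.index_of(cow_animals)
    design = assign_design(n_cows, n_cohorts=max(4, n_cows // 60), seed=seed + 2)
    cow_truth = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "animal": cow_animals,
            "u_auc": u[rows, 0],
            "u_logvar": u[rows, 1],
        }
    )
    latent = params.mean + u[rows] + np.random.default_rng(seed + 3).standard_normal(
        (n_cows, 2)
    ) * np.sqrt([params.sigma2_e[0], params.sigma2_e[1]])

    # visit-level targets: per cow-day AUC around the cow's latent mean with
    # her latent day-to-day SD; totals and visit counts around herd averages
    fcfg = FeedingSimConfig()
    start = pd.Timestamp("2022-06-01")
    tg_rows = []
    for i, cow in enumerate(cow_ids):
        day_sd = float(np.sqrt(np.exp(latent[i, 1])))
        for d in range(dims["n_days"]):
            tg_rows.append(
                {
                    "cow_id": cow,
                    "pen_id": "pen0",
                    "date": (start + pd.Timedelta(days=d)).date().isoformat(),
                    "target_auc": float(
                        np.clip(latent[i, 0] + rng.normal(0.0, day_sd), 36_000, 72_000)
                    ),
                    "total_intake_kg": float(
                        np.clip(rng.normal(fcfg.daily_intake_mean_kg, fcfg.daily_intake_sd_kg), 13, 90)
                    ),
                    "n_visits": int(rng.poisson(fcfg.visits_per_day_mean - 5) + 5),
                }
            )
    targets = pd.DataFrame(tg_rows)
    visits = simulate_visit_events(targets, fcfg, seed=seed + 4)

    # trial metadata: every cow's first (only) trial covers the visit span
    trials = pd.DataFrame(
        {
            "cow_id": cow_ids,
            "trial_id": "T1",
            "start_date": targets["date"].min(),
            "end_date": (pd.Timestamp(targets["date"].max()) + pd.Timedelta(days=1)).date().isoformat(),
        }
    )

    cows = pd.DataFrame({"cow_id": cow_ids, "animal": cow_animals}).join(design)
    recs = simulate_efficiency_records(cows, EfficiencySimConfig(), seed=seed + 5)

    paths = {}
    tables = {
        "pedigree": ped_frame,
        "visits": visits,
        "trials": trials,
        "cows": cows,
        "milk": recs["milk"],
        "bw": recs["bw"],
        "dmi": recs["dmi"],
        "truth_cows": cow_truth,
        "truth_efficiency": recs["truth"],
        "targets": targets,
    }
    for name, frame in tables.items():
        p = out / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: PipelineConfig, base_dir=".") -> RunManifest:
    """Execute the full analysis on the inputs under ``config.input_dir``.

    Expects the table layout written by :func:`make_demo_data` (visit log,
    trial table, pedigree, milk/BW/DMI records, cow metadata). Writes the
    cleaned-funnel reports, phenotype and trait tables, posterior summaries
    and the run manifest into ``config.output_dir``.
    """
    t_start = time.time()
    base = Path(base_dir)
    ind = base / config.input_dir
    outd = base / config.output_dir
    outd.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=__version__
    )

    def stage(name: str, **counts) -> None:
        manifest.stages[name] = counts
        log.info("stage %-18s %s", name, counts)

    try:
        # 1. visit cleaning
        visits = events.read_visits(ind / "visits.csv")
        visits, visit_report = events.filter_visits(visits, config.visit_filter())
        trials_path = ind / "trials.csv"
        if trials_path.exists():
            trials = pd.read_csv(trials_path)
            visits, trial_report = events.select_first_trial(visits, trials)
            stage("first_trial", **trial_report.as_dict())
        stage("clean_visits", **visit_report.as_dict())
        (outd / "visit_cleaning.txt").write_text(visit_report.to_text())

        # 2. feeding-pattern phenotypes
        windows, visits = pattern.assign_day_windows(visits, config.schedule())
        days = pattern.daily_curves(visits, windows)
        days, day_report = pattern.filter_days(days, config.day_filter())
        days, outlier_report = pattern.remove_outlier_days(
            days, config.outlier_sd_threshold
        )
        pheno, cow_report = pattern.summarize_cows(days, config.min_days_per_cow)
        stage("filter_days", **day_report)
        stage("outlier_days", **outlier_report)
        stage("summarize_cows", **cow_report)
        pheno.to_csv(outd / "phenotypes.csv", index=False)
        manifest.outputs["phenotypes"] = str(outd / "phenotypes.csv")

        # 3. feed-efficiency traits
        cows = pd.read_csv(ind / "cows.csv")
        traits = efficiency.derive_efficiency_traits(
            milk=pd.read_csv(ind / "milk.csv"),
            bw=pd.read_csv(ind / "bw.csv"),
            dmi=pd.read_csv(ind / "dmi.csv"),
            cows=cows,
        )
        traits, rfi_report = efficiency.fit_rfi(traits)
        keep_cols = [
            "cow_id", "animal", "dmi", "milke", "mbw", "delta_bw", "rfi",
            "lactation", "dim_class", "cohort",
        ]
        traits[[c for c in keep_cols if c in traits.columns]].to_csv(
            outd / "efficiency_traits.csv", index=False
        )
        with open(outd / "rfi_coefficients.json", "w") as fh:
            json.dump(rfi_report, fh, indent=2, default=float)
        stage("efficiency", n_cows=len(traits))
        manifest.outputs["efficiency_traits"] = str(outd / "efficiency_traits.csv")

        # 4. genetic parameters for the two feeding-pattern phenotypes
        ped_frame = pd.read_csv(ind / "pedigree.csv")
        full_ped = Pedigree.from_frame(ped_frame)
        gen = pheno.merge(cows[["cow_id", "animal"]], on="cow_id")
        summaries = {}
        for trait in ("auc_mean", "log_var_dauc"):
            sub = gen.dropna(subset=[trait])
            ped_t = trace_pedigree(
                full_ped, sub["animal"].to_numpy(), config.trace_generations
            )
            design = sub.merge(cows, on="cow_id")
            X = _design_matrix(design)
            chain = gibbs_univariate(
                sub[trait].to_numpy(),
                X,
                ped_t.index_of(sub["animal"].to_numpy()),
                ped_t.a_inverse(),
                n_iter=config.chain_iterations,
                burn_in=config.chain_burn_in,
                thin=config.chain_thin,
                seed=config.seed,
            )
            summaries[trait] = summarize(chain).drop(index="b", errors="ignore")
            stage(f"gibbs_{trait}", n_records=len(sub), n_animals=ped_t.n)
        posterior = pd.concat(summaries, names=["trait", "parameter"])
        posterior.to_csv(outd / "posterior_summaries.csv")
        manifest.outputs["posterior_summaries"] = str(outd / "posterior_summaries.csv")

        manifest.complete = True
    finally:
        manifest.stages["elapsed_s"] = {"value": round(time.time() - t_start, 2)}
        manifest.write(outd / "manifest.yaml")
    return manifest


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    """Intercept + reference-coded dummies for lactation, DIM class, cohort."""
    X = pd.get_dummies(
        design[["lactation", "dim_class", "cohort"]].astype(str),
        drop_first=True,
        dtype=float,
    )
    X.insert(0, "intercept", 1.0)
    return X.to_numpy()
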