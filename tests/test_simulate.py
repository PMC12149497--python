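import numpy as np
import pandas as pd
import pytest

from feedpattern.events import filter_visits, read_visits
from feedpattern.pattern import FeedDeliverySchedule, assign_day_windows, daily_curves
from feedpattern.pedigree import Pedigree
from feedpattern.sim import (
    CalibrationError,
    EfficiencySimConfig,
    FeedingSimConfig,
    PedigreeSpec,
    TrueParameters,
    assign_design,
    calibrate_theta,
    simulate_breeding_values,
    simulate_efficiency_records,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_visit_events,
)

from conftest import random_pedigree


class TestPedigreeSim:
    def test_counts_and_generations(self):
        frame = simulate_pedigree(
            PedigreeSpec(n_founders=100, n_generations=5, n_per_generation=100, seed=0)
        )
        assert len(frame) == 600
        assert sorted(frame["generation"].unique()) == [0, 1, 2, 3, 4, 5]
        founders = frame[frame["generation"] == 0]
        assert len(founders) == 100
        assert (founders[["sire", "dam"]] == 0).all().all()

    def test_two_founders_one_offspring(self):
        frame = simulate_pedigree(
            PedigreeSpec(n_founders=2, n_generations=1, n_per_generation=1, seed=0)
        )
        child = frame.iloc[-1]
        assert {child["sire"], child["dam"]} == {1, 2}

    def test_parents_born_earlier(self):
        frame = simulate_pedigree(
            PedigreeSpec(n_founders=20, n_generations=4, n_per_generation=30, seed=3)
        )
        ped = Pedigree.from_frame(frame)  # raises if not topological
        assert ped.n == len(frame)

    def test_seed_determinism(self):
        spec = PedigreeSpec(n_founders=30, n_generations=3, n_per_generation=40, seed=9)
        a = simulate_pedigree(spec).to_csv()
        b = simulate_pedigree(spec).to_csv()
        assert a == b

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PedigreeSpec(n_founders=0)
        with pytest.raises(ValueError):
            PedigreeSpec(n_founders=10, n_generations=0)


class TestBreedingValues:
    def test_founder_variance_matches_sigma2a(self):
        ped = Pedigree.from_frame(
            pd.DataFrame({"animal": np.arange(1, 5001), "sire": 0, "dam": 0})
        )
        u = simulate_breeding_values(ped, TrueParameters(sigma2_a=[1.0], sigma2_e=[1.0]), seed=0)
        assert 0.92 <= u.var(ddof=1) <= 1.08

    def test_parent_offspring_covariance_is_half_sigma2a(self):
        frame = simulate_pedigree(
            PedigreeSpec(n_founders=2000, n_generations=1, n_per_generation=6000, seed=1)
        )
        ped = Pedigree.from_frame(frame)
        u = simulate_breeding_values(
            ped, TrueParameters(sigma2_a=[2.0], sigma2_e=[1.0]), seed=2
        )[:, 0]
        pos = {a: i for i, a in enumerate(ped.ids)}
        child = frame[frame["generation"] == 1]
        uc = u[[pos[a] for a in child["animal"]]]
        us = u[[pos[a] for a in child["sire"]]]
        cov = np.cov(uc, us)[0, 1]
        assert cov == pytest.approx(0.5 * 2.0, rel=0.12)

    def test_zero_genetic_variance_gives_zero_values(self):
        ped = random_pedigree(50, 0)
        u = simulate_breeding_values(ped, TrueParameters(sigma2_a=[0.0], sigma2_e=[1.0]))
        assert np.all(u == 0.0)

    def test_perfect_genetic_correlation_duplicates_traits(self):
        ped = random_pedigree(200, 1)
        params = TrueParameters(
            sigma2_a=[1.0, 1.0], sigma2_e=[1.0, 1.0], genetic_corr=[[1, 1], [1, 1]]
        )
        u = simulate_breeding_values(ped, params, seed=3)
        assert np.allclose(u[:, 0], u[:, 1])

    def test_pair_covariance_matches_relationship_matrix(self, fullsib_mating_pedigree):
        """Empirical covariance over replicate simulations reproduces A*sigma2_a
        entry-wise on a small pedigree with inbreeding."""
        ped = fullsib_mating_pedigree
        params = TrueParameters(sigma2_a=[1.0], sigma2_e=[1.0])
        draws = np.stack(
            [simulate_breeding_values(ped, params, seed=s)[:, 0] for s in range(3000)]
        )
        emp = np.cov(draws.T)
        A = ped.relationship_matrix()
        assert np.abs(emp - A).max() < 0.12

    def test_nonpositive_definite_correlation_rejected(self):
        params = TrueParameters(
            sigma2_a=[1.0, 1.0],
            sigma2_e=[1.0, 1.0],
            genetic_corr=[[1.0, 1.2], [1.2, 1.0]],
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_breeding_values(random_pedigree(10, 0), params)


class TestPhenotypes:
    def test_phenotypic_variance_adds_components(self):
        ped = Pedigree.from_frame(
            pd.DataFrame({"animal": np.arange(1, 2001), "sire": 0, "dam": 0})
        )
        params = TrueParameters(sigma2_a=[1_315_780.0], sigma2_e=[2_421_331.0])
        u = simulate_breeding_values(ped, params, seed=4)
        y = simulate_phenotypes(u, params, seed=5)
        total = params.sigma2_a[0] + params.sigma2_e[0]
        assert abs(y.var(ddof=1) / total - 1) < 0.15

    def test_fixed_effects_only_limit(self):
        params = TrueParameters(sigma2_a=[1e-12], sigma2_e=[1e-12])
        design = assign_design(50, n_cohorts=4, seed=6)
        u = np.zeros((50, 1))
        y, effects = simulate_phenotypes(u, params, design, seed=7, return_effects=True)
        predicted = np.zeros(50)
        for factor, eff in effects.items():
            predicted += np.array([eff[lv][0] for lv in design[factor]])
        assert np.abs(y[:, 0] - predicted).max() < 6e-6  # 6 SD of the tiny noise


class TestVisitEvents:
    def targets(self, aucs, n_visits=31, total=43.8):
        return pd.DataFrame(
            {
                "cow_id": [f"c{i}" for i in range(len(aucs))],
                "date": "2022-06-01",
                "target_auc": aucs,
                "total_intake_kg": total,
                "n_visits": n_visits,
            }
        )

    def pipeline_aucs(self, log, tmp_path):
        p = tmp_path / "log.csv"
        log.to_csv(p, index=False)
        visits, _ = filter_visits(read_visits(p))
        windows, assigned = assign_day_windows(visits, FeedDeliverySchedule())
        return daily_curves(assigned, windows)

    def test_round_trip_recovers_targets_across_range(self, tmp_path):
        aucs = np.linspace(48_000, 66_000, 6)
        log = simulate_visit_events(self.targets(aucs), seed=0)
        days = self.pipeline_aucs(log, tmp_path)
        recovered = days.set_index("cow_id")["auc"]
        for i, target in enumerate(aucs):
            assert abs(recovered[f"c{i}"] - target) < 600

    def test_emitted_visits_survive_filters(self, tmp_path):
        log = simulate_visit_events(self.targets([52_000, 60_000]), seed=1)
        p = tmp_path / "log.csv"
        log.to_csv(p, index=False)
        visits, report = filter_visits(read_visits(p))
        assert sum(report.removed.values()) <= 1  # weight rounding may zero one tiny visit
        days = self.pipeline_aucs(log, tmp_path)
        assert (days["n_visits"] >= 5).all()
        assert ((days["total_intake_kg"] > 12) & (days["total_intake_kg"] <= 115)).all()

    def test_fault_injection_produces_removals(self, tmp_path):
        cfg = FeedingSimConfig(fault_injection=True, fault_fraction=0.2)
        log = simulate_visit_events(self.targets([56_000]), cfg, seed=2)
        p = tmp_path / "log.csv"
        log.to_csv(p, index=False)
        _, report = filter_visits(read_visits(p))
        assert sum(report.removed.values()) >= 4

    def test_seed_determinism(self):
        t = self.targets([50_000, 62_000])
        a = simulate_visit_events(t, seed=5).to_csv()
        b = simulate_visit_events(t, seed=5).to_csv()
        assert a == b

    def test_unattainable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_theta(86_000.0, np.full(31, 1 / 31), FeedingSimConfig())

    def test_out_of_range_totals_rejected(self):
        with pytest.raises(ValueError):
            simulate_visit_events(self.targets([50_000], total=10.0))


class TestEfficiencyRecords:
    def test_daily_weighing_needs_no_imputation(self):
        from feedpattern.efficiency import impute_bw

        cows = pd.DataFrame({"cow_id": ["a", "b"]})
        recs = simulate_efficiency_records(
            cows, EfficiencySimConfig(bw_every_days=1), seed=0
        )
        full = impute_bw(recs["bw"], day_range=(0, 42))
        assert not full["imputed"].any()

    def test_zero_true_rfi_variance_collapses_fitted_rfi(self):
        from feedpattern.efficiency import derive_efficiency_traits, fit_rfi

        n = 1500
        cows = assign_design(n, n_cohorts=15, seed=1)
        cows.insert(0, "cow_id", [f"c{i}" for i in range(n)])
        recs = simulate_efficiency_records(
            cows, EfficiencySimConfig(rfi_sd_kg=0.0), seed=2
        )
        traits = derive_efficiency_traits(
            recs["milk"], recs["bw"], recs["dmi"], cows, day_range=(0, 42)
        )
        out, _ = fit_rfi(traits)
        assert out["rfi"].var() / out["dmi"].var() < 0.01

    def test_short_trials_rejected(self):
        with pytest.raises(ValueError):
            simulate_efficiency_records(
                pd.DataFrame({"cow_id": ["a"]}), EfficiencySimConfig(n_weeks=2)
            )
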