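import numpy as np
import pandas as pd
import pytest

from feedpattern.gibbs import gibbs_bivariate, gibbs_univariate
from feedpattern.pedigree import Pedigree
from feedpattern.posterior import (
    diagnostics,
    gelman_rubin,
    geweke_z,
    heidelberger_welch,
    hpd_interval,
    summarize,
)
from feedpattern.sim import TrueParameters, simulate_breeding_values, simulate_phenotypes
from feedpattern.studies import bivariate_recovery, simulated_herd, univariate_recovery

from conftest import random_pedigree


class TestUnivariate:
    def test_fixed_variance_posterior_matches_gls(self):
        """With variances held fixed the location posterior is Gaussian and the
        posterior mean of the fixed effect equals the GLS solution."""
        rng = np.random.default_rng(0)
        n = 25
        ped = random_pedigree(n, 3)
        A = ped.relationship_matrix()
        siga, sige = 2.0, 1.5
        u = rng.multivariate_normal(np.zeros(n), siga * A)
        mu = 3.7
        y = mu + u + rng.normal(0, np.sqrt(sige), n)
        X = np.ones((n, 1))
        chain = gibbs_univariate(
            y, X, np.arange(n), ped.a_inverse(),
            n_iter=6000, burn_in=1000, seed=1,
            start=(siga, sige), sample_variances=False,
        )
        V = siga * A + sige * np.eye(n)
        Vi = np.linalg.inv(V)
        gls = float((X.T @ Vi @ y).item() / (X.T @ Vi @ X).item())
        se = float(1.0 / np.sqrt((X.T @ Vi @ X).item()))
        b = chain["b"][:, 0]
        assert abs(b.mean() - gls) < 4 * se / np.sqrt(50)  # generous ESS bound
        assert b.std() == pytest.approx(se, rel=0.25)

    def test_zero_heritability_truth_recovered(self):
        r = univariate_recovery(0.0, 1.0, n_cows=500, n_iter=8000, burn_in=2000, seed=3)
        assert r["h2_mean"] < 0.1

    def test_permutation_exchangeability(self):
        """Reordering animals (with consistent pedigree reindexing) leaves the
        posterior unchanged up to Monte Carlo error."""
        params = TrueParameters(sigma2_a=[1.0], sigma2_e=[1.0])
        herd = simulated_herd(params, n_cows=300, seed=5)
        ped, rows, y = herd["pedigree"], herd["pheno_rows"], herd["y"][:, 0]

        def run(order):
            frame = ped.to_frame().iloc[order].reset_index(drop=True)
            p2 = Pedigree.from_frame(frame)
            idx = p2.index_of(ped.ids[rows])
            return gibbs_univariate(
                y, herd["X"], idx, p2.a_inverse(),
                n_iter=6000, burn_in=1500, seed=11,
            )["h2"].mean()

        base = run(np.arange(ped.n))
        rng = np.random.default_rng(4)
        shuffled = run(rng.permutation(ped.n))
        assert abs(base - shuffled) < 0.06

    def test_invalid_chain_settings_rejected(self):
        with pytest.raises(ValueError):
            gibbs_univariate(
                np.zeros(3), np.ones((3, 1)), np.arange(3),
                np.eye(3), n_iter=100, burn_in=100,
            )

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))  # duplicated intercept
        with pytest.raises(ValueError, match="rank deficient"):
            gibbs_univariate(np.zeros(10), X, np.arange(10), np.eye(10))


class TestBivariate:
    def test_perfect_genetic_correlation_recovered(self):
        r = bivariate_recovery(
            0.4, 0.4, 1.0, n_cows=400, n_iter=6000, burn_in=1500, thin=2, seed=2
        )
        assert r["rg_mean"] > 0.9

    def test_null_genetic_correlation(self):
        r = bivariate_recovery(
            0.3, 0.3, 0.0, n_cows=800, n_iter=10_000, burn_in=2_000, thin=2, seed=6
        )
        assert abs(r["rg_mean"]) < 0.15

    def test_marginals_agree_with_univariate_sampler(self):
        """Under a zero-correlation truth the bivariate marginal heritability
        matches a univariate run on the same trait records."""
        params = TrueParameters(
            sigma2_a=[0.35, 0.35], sigma2_e=[0.65, 0.65]
        )
        herd = simulated_herd(params, n_cows=600, seed=7)
        ainv = herd["pedigree"].a_inverse()
        uni = gibbs_univariate(
            herd["y"][:, 0], herd["X"], herd["pheno_rows"], ainv,
            n_iter=8000, burn_in=2000, seed=8,
        )
        biv = gibbs_bivariate(
            herd["y"][:, 0], herd["X"], herd["y"][:, 1], herd["X"],
            herd["pheno_rows"], ainv,
            n_iter=8000, burn_in=2000, thin=2, seed=9,
        )
        assert abs(uni["h2"].mean() - biv["h2_1"].mean()) < 0.08

    def test_complete_case_requirement(self):
        with pytest.raises(ValueError, match="complete cases"):
            gibbs_bivariate(
                np.zeros(5), np.ones((5, 1)), np.zeros(4), np.ones((4, 1)),
                np.arange(5), np.eye(5),
            )


class TestPosteriorSummaries:
    def test_constant_chain(self):
        s = summarize({"theta": np.full(200, 4.2)})
        row = s.loc["theta"]
        assert row["mean"] == pytest.approx(4.2)
        assert row["sd"] == pytest.approx(0.0, abs=1e-12)
        assert (row["hpd_low"], row["hpd_high"]) == (4.2, 4.2)

    def test_hpd_of_standard_normal(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = hpd_interval(x, 0.90)
        assert lo == pytest.approx(-1.645, abs=0.03)
        assert hi == pytest.approx(1.645, abs=0.03)

    def test_heritability_identity_from_point_mass_chains(self):
        sa = np.full(200, 1_315_780.0)
        se = np.full(200, 2_421_331.0)
        s = summarize({"h2": sa / (sa + se)})
        assert round(float(s.loc["h2", "mean"]), 2) == 0.35

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize({"x": np.zeros(50)})


class TestDiagnostics:
    def test_geweke_null_distribution(self):
        zs = [
            abs(geweke_z(np.random.default_rng(s).standard_normal(3000)))
            for s in range(120)
        ]
        assert np.mean(np.array(zs) < 3.0) >= 0.99

    def test_identical_chains_have_unit_rhat(self):
        c = np.random.default_rng(1).standard_normal(1000)
        assert gelman_rubin([c, c.copy()]) == 1.0

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        assert gelman_rubin([rng.standard_normal(800), 5 + rng.standard_normal(800)]) > 1.5

    def test_mean_shift_fails_stationarity(self):
        rng = np.random.default_rng(3)
        chain = np.concatenate([rng.standard_normal(2000), 4 + rng.standard_normal(2000)])
        assert not heidelberger_welch(chain)["stationary"]

    def test_stationary_chain_passes(self):
        chain = np.random.default_rng(4).standard_normal(4000)
        assert heidelberger_welch(chain)["stationary"]

    def test_report_on_real_chain(self):
        r = univariate_recovery(0.3, 0.7, n_cows=200, n_iter=4000, burn_in=1000, seed=10)
        rep = diagnostics(r["chain"])
        assert set(rep.geweke) >= {"sigma2_a", "sigma2_e", "h2"}
        assert rep.rhat is None
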