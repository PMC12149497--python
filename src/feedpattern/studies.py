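"""Parameter-recovery simulation studies for the animal-model samplers.

Each study builds a discrete-generation herd (five descendant generations on
a founder population), simulates breeding values down the pedigree and
phenotypes under the animal model at a chosen truth, then re-estimates the
genetic parameters with the Gibbs samplers. Because the generating model and
the fitted model coincide, posterior means recover the truth up to sampling
noise — the standard way to validate variance-component machinery when the
original data are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gibbs import GibbsChain, gibbs_bivariate, gibbs_univariate
from .pedigree import Pedigree
from .sim import (
    PedigreeSpec,
    TrueParameters,
    assign_design,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)

__all__ = ["simulated_herd", "univariate_recovery", "bivariate_recovery"]


def _subseeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31 derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def simulated_herd(
    params: TrueParameters,
    n_cows: int = 1200,
    n_generations: int = 5,
    n_cohorts: int = 15,
    seed: int = 0,
) -> dict:
    """Herd with ``n_cows`` phenotyped cows across 5 descendant generations.

    Returns the pedigree, the phenotyped rows' positions, the management
    design, the fixed-effect design matrix and the phenotype matrix.
    """
    s_ped, s_bv, s_design, s_pheno = _subseeds(seed, 4)
    per_gen = max(2, n_cows // n_generations)
    spec = PedigreeSpec(
        n_founders=max(10, n_cows // 6),
        n_generations=n_generations,
        n_per_generation=per_gen,
        seed=s_ped,
    )
    ped_frame = simulate_pedigree(spec)
    ped = Pedigree.from_frame(ped_frame)
    u = simulate_breeding_values(ped, params, seed=s_bv)
    pheno_rows = np.flatnonzero(ped_frame["generation"].to_numpy() >= 1)[-n_cows:]
    design = assign_design(len(pheno_rows), n_cohorts=n_cohorts, seed=s_design)
    y = simulate_phenotypes(u[pheno_rows], params, design, seed=s_pheno)
    X = pd.get_dummies(
        design[["lactation", "dim_class", "cohort"]].astype(str),
        drop_first=True,
        dtype=float,
    )
    X.insert(0, "intercept", 1.0)
    return {
        "pedigree": ped,
        "pheno_rows": pheno_rows,
        "design": design,
        "X": X.to_numpy(),
        "y": y,
        "breeding_values": u,
    }


def univariate_recovery(
    sigma2_a: float,
    sigma2_e: float,
    n_cows: int = 1200,
    n_iter: int = 40_000,
    burn_in: int = 8_000,
    seed: int = 0,
    replicates: int = 1,
) -> dict:
    """Simulate herd(s) at a univariate truth and re-estimate heritability.

    With ``replicates > 1`` the study repeats on independent herds (fresh
    pedigree, breeding values and phenotypes per replicate) and reports the
    mean of the per-replicate posterior means: a single herd of this size
    carries data-realisation noise of the same order as the posterior SD,
    and averaging over herds isolates what the estimation machinery itself
    recovers. Chain settings apply per replicate.
    """
    reps: list[float] = []
    chain: GibbsChain | None = None
    params = TrueParameters(sigma2_a=[sigma2_a], sigma2_e=[sigma2_e])
    for rep_seed in _subseeds(seed * 1000 + 7, replicates):
        herd = simulated_herd(params, n_cows=n_cows, seed=rep_seed)
        chain = gibbs_univariate(
            herd["y"][:, 0],
            herd["X"],
            herd["pheno_rows"],
            herd["pedigree"].a_inverse(),
            n_iter=n_iter,
            burn_in=burn_in,
            seed=_subseeds(rep_seed, 5)[4],
        )
        reps.append(float(chain["h2"].mean()))
    return {
        "h2_mean": float(np.mean(reps)),
        "h2_replicates": reps,
        "h2_true": sigma2_a / (sigma2_a + sigma2_e),
        "sigma2_a_mean": float(chain["sigma2_a"].mean()),
        "sigma2_e_mean": float(chain["sigma2_e"].mean()),
        "n_cows": n_cows,
        "chain": chain,
    }


def bivariate_recovery(
    h2_1: float,
    h2_2: float,
    genetic_corr: float,
    residual_corr: float = 0.0,
    n_cows: int = 800,
    n_iter: int = 30_000,
    burn_in: int = 6_000,
    thin: int = 10,
    seed: int = 0,
    replicates: int = 1,
    intercept_only_trait2: bool = False,
) -> dict:
    """Simulate two-trait herd(s) at given heritabilities/genetic correlation
    and re-estimate the genetic correlation with the bivariate sampler.

    Traits are simulated on the standardised scale (phenotypic variance 1),
    so ``sigma2_a = h2`` per trait. ``intercept_only_trait2`` fits trait 2
    with no management fixed effects, as appropriate for a phenotype that
    was pre-adjusted for them (residual feed intake). ``replicates`` works
    as in :func:`univariate_recovery`: independent herds, averaged
    posterior means.
    """
    params = TrueParameters(
        sigma2_a=[h2_1, h2_2],
        sigma2_e=[1.0 - h2_1, 1.0 - h2_2],
        genetic_corr=[[1.0, genetic_corr], [genetic_corr, 1.0]],
        residual_corr=[[1.0, residual_corr], [residual_corr, 1.0]],
    )
    reps: list[float] = []
    h2s: list[tuple[float, float]] = []
    chain: GibbsChain | None = None
    for rep_seed in _subseeds(seed * 1000 + 13, replicates):
        herd = simulated_herd(params, n_cows=n_cows, n_cohorts=10, seed=rep_seed)
        X2 = np.ones((n_cows, 1)) if intercept_only_trait2 else herd["X"]
        chain = gibbs_bivariate(
            herd["y"][:, 0],
            herd["X"],
            herd["y"][:, 1],
            X2,
            herd["pheno_rows"],
            herd["pedigree"].a_inverse(),
            n_iter=n_iter,
            burn_in=burn_in,
            thin=thin,
            seed=_subseeds(rep_seed, 5)[4],
        )
        reps.append(float(chain["r_g"].mean()))
        h2s.append((float(chain["h2_1"].mean()), float(chain["h2_2"].mean())))
    return {
        "rg_mean": float(np.mean(reps)),
        "rg_replicates": reps,
        "rg_true": genetic_corr,
        "h2_1_mean": float(np.mean([h[0] for h in h2s])),
        "h2_2_mean": float(np.mean([h[1] for h in h2s])),
        "n_cows": n_cows,
        "chain": chain,
    }
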