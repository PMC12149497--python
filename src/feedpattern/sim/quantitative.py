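"""Breeding values and phenotypes with known additive-genetic structure.

Breeding values descend the pedigree: founders are drawn from N(0, G0) and
each non-founder is the parent average plus a Mendelian-sampling deviation
whose variance shrinks with parental inbreeding,
``0.5 * (1 - 0.5*(F_sire + F_dam))`` per unit of genetic variance (3/4 minus
a quarter of the known parent's F when only one parent is recorded).
Phenotypes add fixed effects (lactation, days-in-milk class, cohort) and an
independent residual, i.e. exactly the animal model the samplers fit, so
truth is recoverable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..efficiency import dim_class
from ..pedigree import Pedigree

__all__ = [
    "TrueParameters",
    "simulate_breeding_values",
    "assign_design",
    "simulate_phenotypes",
]


def _corr_factor(corr: np.ndarray, what: str) -> np.ndarray:
    """Square root of a correlation matrix, tolerating singular PSD cases."""
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if not np.allclose(corr, corr.T):
        raise ValueError(f"{what} correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0):
        raise ValueError(f"{what} correlation matrix must have a unit diagonal")
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError(f"{what} correlation matrix is not positive semi-definite")
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


@dataclass
class TrueParameters:
    """Simulation truth for one or more traits.

    ``sigma2_a``/``sigma2_e`` are per-trait additive-genetic and residual
    variances; ``genetic_corr``/``residual_corr`` give the cross-trait
    correlation structure (identity by default). ``fixed_effect_sd`` sets the
    spread of the randomly drawn factor-level effects, in trait SD units of
    each trait's phenotypic SD, so fixed effects stay commensurate with the
    trait scale.
    """

    sigma2_a: np.ndarray
    sigma2_e: np.ndarray
    genetic_corr: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    mean: np.ndarray | None = None
    fixed_effect_sd: dict = field(
        default_factory=lambda: {"lactation": 0.3, "dim_class": 0.2, "cohort": 0.3}
    )

    def __post_init__(self) -> None:
        self.sigma2_a = np.atleast_1d(np.asarray(self.sigma2_a, dtype=float))
        self.sigma2_e = np.atleast_1d(np.asarray(self.sigma2_e, dtype=float))
        t = self.n_traits
        if self.sigma2_e.shape[0] != t:
            raise ValueError("sigma2_a and sigma2_e must list the same traits")
        if np.any(self.sigma2_a < 0) or np.any(self.sigma2_e <= 0):
            raise ValueError("variances must be positive (sigma2_a may be zero)")
        if self.genetic_corr is None:
            self.genetic_corr = np.eye(t)
        if self.residual_corr is None:
            self.residual_corr = np.eye(t)
        self.genetic_corr = np.atleast_2d(np.asarray(self.genetic_corr, dtype=float))
        self.residual_corr = np.atleast_2d(np.asarray(self.residual_corr, dtype=float))
        if self.mean is None:
            self.mean = np.zeros(t)
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))

    @property
    def n_traits(self) -> int:
        return int(self.sigma2_a.shape[0])

    def g0(self) -> np.ndarray:
        """Genetic (co)variance matrix G0 implied by variances and correlations."""
        s = np.sqrt(self.sigma2_a)
        return np.outer(s, s) * self.genetic_corr

    def r0(self) -> np.ndarray:
        s = np.sqrt(self.sigma2_e)
        return np.outer(s, s) * self.residual_corr

    def h2(self) -> np.ndarray:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


def simulate_breeding_values(
    pedigree: Pedigree | pd.DataFrame, params: TrueParameters, seed: int = 0
) -> np.ndarray:
    """Draw breeding values for every pedigree animal; shape (n_animals, n_traits).

    Row order follows the pedigree order; use ``pedigree.ids`` to map back to
    animal labels.
    """
    if isinstance(pedigree, pd.DataFrame):
        pedigree = Pedigree.from_frame(pedigree)
    t = params.n_traits
    G0 = params.g0()
    if np.allclose(G0, 0.0):
        return np.zeros((pedigree.n, t))
    sd_a = np.sqrt(params.sigma2_a)
    corr_f = _corr_factor(params.genetic_corr, "genetic")
    rng = np.random.default_rng(seed)
    d = pedigree.mendelian_variance_ratios()  # founders 1, else Mendelian ratio
    z = rng.standard_normal((pedigree.n, t)) @ corr_f.T * sd_a
    u = np.zeros((pedigree.n, t))
    sire, dam = pedigree.sire, pedigree.dam
    for i in range(pedigree.n):
        pm = np.zeros(t)
        if sire[i] >= 0:
            pm += 0.5 * u[sire[i]]
        if dam[i] >= 0:
            pm += 0.5 * u[dam[i]]
        u[i] = pm + np.sqrt(d[i]) * z[i]
    return u


def assign_design(
    n: int, n_cohorts: int = 10, seed: int = 0, dim_range: tuple[int, int] = (50, 230)
) -> pd.DataFrame:
    """Random management design for n cows: lactation 1-4+, DIM class, cohort."""
    rng = np.random.default_rng(seed)
    lact = rng.choice([1, 2, 3, 4], size=n, p=[0.4, 0.3, 0.2, 0.1])
    dim = rng.integers(dim_range[0], dim_range[1], size=n)
    return pd.DataFrame(
        {
            "lactation": lact,
            "dim": dim,
            "dim_class": [dim_class(d) for d in dim],
            "cohort": rng.integers(1, n_cohorts + 1, size=n),
        }
    )


def simulate_phenotypes(
    breeding_values: np.ndarray,
    params: TrueParameters,
    design: pd.DataFrame | None = None,
    seed: int = 0,
    return_effects: bool = False,
):
    """Phenotypes y = mean + fixed effects + breeding value + residual.

    ``breeding_values`` rows correspond to the phenotyped cows (pass the
    relevant rows of the full pedigree simulation). When ``design`` is given
    it must hold ``lactation``, ``dim_class`` and ``cohort`` columns; level
    effects are drawn once from centred normals scaled by
    ``params.fixed_effect_sd`` times each trait's phenotypic SD.
    Returns an (n, n_traits) array, plus the drawn level effects when
    ``return_effects`` is set.
    """
    u = np.atleast_2d(np.asarray(breeding_values, dtype=float))
    if u.shape[1] != params.n_traits:
        u = u.reshape(-1, params.n_traits)
    n = u.shape[0]
    rng = np.random.default_rng(seed)
    sd_e = np.sqrt(params.sigma2_e)
    corr_f = _corr_factor(params.residual_corr, "residual")
    e = rng.standard_normal((n, params.n_traits)) @ corr_f.T * sd_e
    y = params.mean + u + e
    effects: dict[str, dict] = {}
    if design is not None:
        sd_p = np.sqrt(params.sigma2_a + params.sigma2_e)
        for factor in ("lactation", "dim_class", "cohort"):
            if factor not in design.columns:
                raise ValueError(f"design is missing the {factor!r} column")
            levels = pd.unique(design[factor])
            scale = params.fixed_effect_sd.get(factor, 0.0) * sd_p
            eff = {lv: rng.standard_normal(params.n_traits) * scale for lv in levels}
            effects[factor] = eff
            y = y + np.stack([eff[lv] for lv in design[factor]])
    if return_effects:
        return y, effects
    return y
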