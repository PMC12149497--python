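"""Gibbs samplers for pedigree animal models.

The model for one trait is ``y = Xb + Zu + e`` with a flat prior on the
fixed effects ``b``, additive genetic effects ``u ~ N(0, A sigma2_a)`` for a
pedigree relationship matrix A, and residuals ``e ~ N(0, I sigma2_e)``. The
bivariate model stacks two traits and replaces the scalar variances with the
2x2 genetic and residual (co)variance matrices ``G0`` and ``R0``:
``[u1,u2] ~ N(0, G0 kron A)``, ``[e1,e2] ~ N(0, R0 kron I)``.

The sampler alternates single-site draws of every location effect from its
scalar normal full conditional (a Gauss-Seidel style sweep over the
mixed-model equations, the scheme used by the classical Gibbs programs for
this model class) with conjugate draws of the variance components: scaled
inverse chi-square in the univariate case, inverse Wishart in the bivariate
case. The coefficient matrix keeps a fixed sparsity pattern across
iterations — only the variance ratios rescale its entries — so each sweep is
O(nnz) with no refactorisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.stats import invwishart

__all__ = ["GibbsChain", "gibbs_univariate", "gibbs_bivariate"]


# ---------------------------------------------------------------------------
# chain container


@dataclass
class GibbsChain:
    """Retained (post burn-in, thinned) samples of a Gibbs run.

    ``samples`` maps parameter names to arrays whose first axis indexes the
    retained draws. Univariate chains carry ``sigma2_a``, ``sigma2_e``,
    ``h2`` and the fixed effects ``b``; bivariate chains carry ``G0``, ``R0``
    (shape ``(m, 2, 2)``), per-trait ``h2_1``/``h2_2`` and the genetic and
    residual correlations ``r_g``/``r_e``.
    """

    samples: dict[str, np.ndarray]
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[name]

    @property
    def n_retained(self) -> int:
        return next(iter(self.samples.values())).shape[0]


# ---------------------------------------------------------------------------
# sparse plumbing


@njit(cache=True)
def _sweep(indptr, indices, data, rhs, theta, noise):
    """One Gauss-Seidel Gibbs sweep over all location effects.

    For equation j with coefficient row C_j and right-hand side r_j the full
    conditional is N((r_j - C_j,-j theta_-j)/C_jj, s/C_jj); ``noise`` must be
    N(0, s) draws for the appropriate scale s (sigma2_e univariate, 1 when
    the equations already carry the residual precision).
    """
    nn = theta.shape[0]
    for j in range(nn):
        acc = 0.0
        cjj = 0.0
        for k in range(indptr[j], indptr[j + 1]):
            c = indices[k]
            if c == j:
                cjj = data[k]
            else:
                acc += data[k] * theta[c]
        theta[j] = (rhs[j] - acc) / cjj + noise[j] / np.sqrt(cjj)


@njit(cache=True)
def _sweep_bivariate(indptr, indices, data, rhs, theta, noise, p1, p2, q):
    """Gibbs sweep for the two-trait equations.

    Fixed effects are updated one at a time; the pair of genetic effects of
    each animal (one per trait) is drawn jointly from its bivariate normal
    full conditional. The joint draw is what keeps the genetic-correlation
    chain mobile: with scalar updates the two effects of an animal are so
    strongly coupled through G0 that the sampled correlation sticks near
    +-1 for thousands of iterations.
    """
    m1 = p1 + q
    # scalar updates for both traits' fixed effects
    for block_start, block_len in ((0, p1), (m1, p2)):
        for j in range(block_start, block_start + block_len):
            acc = 0.0
            cjj = 0.0
            for k in range(indptr[j], indptr[j + 1]):
                c = indices[k]
                if c == j:
                    cjj = data[k]
                else:
                    acc += data[k] * theta[c]
            theta[j] = (rhs[j] - acc) / cjj + noise[j] / np.sqrt(cjj)
    # paired updates for the genetic effects
    for i in range(q):
        j1 = p1 + i
        j2 = m1 + p2 + i
        acc1 = 0.0
        c11 = 0.0
        c12 = 0.0
        for k in range(indptr[j1], indptr[j1 + 1]):
            c = indices[k]
            if c == j1:
                c11 = data[k]
            elif c == j2:
                c12 = data[k]
            else:
                acc1 += data[k] * theta[c]
        acc2 = 0.0
        c22 = 0.0
        for k in range(indptr[j2], indptr[j2 + 1]):
            c = indices[k]
            if c == j2:
                c22 = data[k]
            elif c == j1:
                pass  # symmetric partner of c12
            else:
                acc2 += data[k] * theta[c]
        r1 = rhs[j1] - acc1
        r2 = rhs[j2] - acc2
        # solve the 2x2 precision system P mu = r and draw mu + L^{-T} z
        det = c11 * c22 - c12 * c12
        mu1 = (c22 * r1 - c12 * r2) / det
        mu2 = (c11 * r2 - c12 * r1) / det
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(c22 - l21 * l21)
        w2 = noise[j2] / l22
        w1 = (noise[j1] - l21 * w2) / l11
        theta[j1] = mu1 + w1
        theta[j2] = mu2 + w2


def _binary(mat: sparse.spmatrix) -> sparse.csr_matrix:
    out = mat.tocsr(copy=True)
    out.data = np.ones_like(out.data)
    return out


def _align_to_pattern(pattern: sparse.csr_matrix, mat: sparse.spmatrix) -> np.ndarray:
    """Data vector of ``mat`` written into the index layout of ``pattern``.

    Every structural entry of ``mat`` must exist in ``pattern`` (the pattern
    is built as the binarised union of all components, so it does).
    """
    mat = mat.tocsr()
    mat.sort_indices()
    data = np.zeros_like(pattern.data)
    for i in range(pattern.shape[0]):
        m0, m1 = mat.indptr[i], mat.indptr[i + 1]
        if m0 == m1:
            continue
        p0, p1 = pattern.indptr[i], pattern.indptr[i + 1]
        pos = p0 + np.searchsorted(pattern.indices[p0:p1], mat.indices[m0:m1])
        data[pos] = mat.data[m0:m1]
    return data


def _design_matrices(X, animal_index, n_animals):
    X = sparse.csr_matrix(X)
    n = X.shape[0]
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), np.asarray(animal_index, dtype=np.int64))),
        shape=(n, n_animals),
    )
    W = sparse.hstack([X, Z]).tocsr()
    return X, W


def _check_full_rank(X) -> None:
    Xd = X.toarray() if sparse.issparse(X) else np.asarray(X)
    r = np.linalg.matrix_rank(Xd)
    if r < Xd.shape[1]:
        raise ValueError(
            f"fixed-effect design is rank deficient (rank {r} < {Xd.shape[1]} columns); "
            "check factor coding / confounded cohorts"
        )


# ---------------------------------------------------------------------------
# univariate sampler


def gibbs_univariate(
    y: np.ndarray,
    X: np.ndarray,
    animal_index: np.ndarray,
    a_inverse: sparse.spmatrix,
    n_iter: int = 100_000,
    burn_in: int = 20_000,
    thin: int = 1,
    seed: int = 0,
    nu_a: float = -2.0,
    s_a: float = 0.0,
    nu_e: float = -2.0,
    s_e: float = 0.0,
    start: tuple[float, float] | None = None,
    sample_variances: bool = True,
) -> GibbsChain:
    """Gibbs sampler for the univariate animal model.

    Parameters
    ----------
    y
        Phenotypes, one record per animal observation.
    X
        Fixed-effect design matrix (dense or sparse), full column rank; pass a
        single intercept column for a means-only model.
    animal_index
        For each record, the 0-based position of its animal in the pedigree
        order underlying ``a_inverse``.
    a_inverse
        Sparse inverse numerator relationship matrix for all pedigree animals
        (phenotyped or not); its dimension sets the number of genetic effects.
    nu_a, s_a, nu_e, s_e
        Degrees of freedom and scale of the scaled inverse chi-square priors
        on ``sigma2_a`` and ``sigma2_e``. The defaults (-2, 0) make the prior
        flat on the variance.
    start
        Optional ``(sigma2_a, sigma2_e)`` starting values; the default splits
        the phenotypic variance in half.
    sample_variances
        When False the variances stay fixed at ``start`` and only location
        effects are sampled (useful for validating against GLS).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    q = a_inverse.shape[0]
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    X, W = _design_matrices(X, animal_index, q)
    _check_full_rank(X)
    p = X.shape[1]

    WtW = (W.T @ W).tocsr()
    Wty = W.T @ y
    a_inverse = sparse.csr_matrix(a_inverse)
    aaug = sparse.block_diag([sparse.csr_matrix((p, p)), a_inverse], format="csr")
    pattern = _binary(_binary(WtW) + _binary(aaug))
    pattern.sort_indices()
    wtw_data = _align_to_pattern(pattern, WtW)
    ainv_data = _align_to_pattern(pattern, aaug)

    rng = np.random.default_rng(seed)
    if start is None:
        vy = float(np.var(y, ddof=1))
        siga, sige = 0.5 * vy, 0.5 * vy
    else:
        siga, sige = map(float, start)
    if not sample_variances and start is None:
        raise ValueError("fixed-variance runs need explicit start values")

    theta = np.zeros(p + q)
    kept_a, kept_e, kept_b = [], [], []
    for it in range(n_iter):
        lam = sige / max(siga, 1e-300)
        data = wtw_data + lam * ainv_data
        noise = rng.standard_normal(p + q) * np.sqrt(sige)
        _sweep(pattern.indptr, pattern.indices, data, Wty, theta, noise)
        u = theta[p:]
        if sample_variances:
            uau = float(u @ (a_inverse @ u))
            siga = (uau + nu_a * s_a) / rng.chisquare(q + nu_a)
            e = y - W @ theta
            sige = (float(e @ e) + nu_e * s_e) / rng.chisquare(n + nu_e)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_a.append(siga)
            kept_e.append(sige)
            kept_b.append(theta[:p].copy())
    sig_a = np.asarray(kept_a)
    sig_e = np.asarray(kept_e)
    samples = {
        "sigma2_a": sig_a,
        "sigma2_e": sig_e,
        "h2": sig_a / (sig_a + sig_e),
        "b": np.asarray(kept_b),
    }
    return GibbsChain(samples, n_iter, burn_in, thin, seed, meta={"n": n, "q": q})


# ---------------------------------------------------------------------------
# bivariate sampler


def _embed(mat: sparse.spmatrix, row_off: int, col_off: int, neq: int) -> sparse.csr_matrix:
    mat = mat.tocoo()
    return sparse.csr_matrix(
        (mat.data, (mat.row + row_off, mat.col + col_off)), shape=(neq, neq)
    )


def gibbs_bivariate(
    y1: np.ndarray,
    X1: np.ndarray,
    y2: np.ndarray,
    X2: np.ndarray,
    animal_index: np.ndarray,
    a_inverse: sparse.spmatrix,
    n_iter: int = 100_000,
    burn_in: int = 20_000,
    thin: int = 10,
    seed: int = 0,
    nu_g: float = -3.0,
    v_g: np.ndarray | None = None,
    nu_r: float = -3.0,
    v_r: np.ndarray | None = None,
) -> GibbsChain:
    """Gibbs sampler for the two-trait animal model on complete cases.

    Both traits must be observed on the same records (``y1[i]`` and ``y2[i]``
    belong to the same cow); the traits may carry different fixed-effect
    designs — e.g. an intercept-only design for a pre-adjusted trait such as
    residual feed intake.

    Priors on ``G0`` and ``R0`` are of inverse-Wishart form with degrees of
    freedom ``nu_g``/``nu_r`` and scale matrices ``v_g``/``v_r``. The
    defaults (``-3`` = minus (traits+1), zero scale) make the prior density
    flat, mirroring the flat univariate default. A flat prior matters here:
    low-dimensional "minimally informative" inverse-Wishart priors such as
    ``IW(p+1, eps*I)`` have density diverging at singular matrices, and in a
    Gibbs chain that divergence acts as an absorbing boundary — the genetic
    variance of a low-heritability trait collapses and the sampled genetic
    correlation pins at +-1.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.shape[0]
    if y2.shape[0] != n:
        raise ValueError("bivariate sampler needs complete cases: len(y1) == len(y2)")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    q = a_inverse.shape[0]
    a_inverse = sparse.csr_matrix(a_inverse)
    X1, W1 = _design_matrices(X1, animal_index, q)
    X2, W2 = _design_matrices(X2, animal_index, q)
    _check_full_rank(X1)
    _check_full_rank(X2)
    p1, p2 = X1.shape[1], X2.shape[1]
    m1 = p1 + q  # size of trait-1 equation block
    neq = m1 + p2 + q
    u1_sl = slice(p1, m1)
    u2_sl = slice(m1 + p2, neq)

    # components of the coefficient matrix; per-iteration values are linear
    # combinations with the current precision elements
    aaug1 = _embed(a_inverse, p1, p1, neq)
    aaug2 = _embed(a_inverse, m1 + p2, m1 + p2, neq)
    aaug12 = _embed(a_inverse, p1, m1 + p2, neq) + _embed(a_inverse, m1 + p2, p1, neq)
    K11 = _embed((W1.T @ W1).tocsr(), 0, 0, neq)
    K22 = _embed((W2.T @ W2).tocsr(), m1, m1, neq)
    K12 = _embed((W1.T @ W2).tocsr(), 0, m1, neq) + _embed((W2.T @ W1).tocsr(), m1, 0, neq)
    comps = [K11, K22, K12, aaug1, aaug2, aaug12]
    pattern = _binary(comps[0])
    for c in comps[1:]:
        pattern = pattern + _binary(c)
    pattern = _binary(pattern)
    pattern.sort_indices()
    comp_data = np.stack([_align_to_pattern(pattern, c) for c in comps])

    w1y1, w1y2 = W1.T @ y1, W1.T @ y2
    w2y1, w2y2 = W2.T @ y1, W2.T @ y2

    if v_g is None:
        v_g = np.zeros((2, 2))
    if v_r is None:
        v_r = np.zeros((2, 2))

    rng = np.random.default_rng(seed)
    G0 = 0.5 * np.diag([np.var(y1, ddof=1), np.var(y2, ddof=1)])
    R0 = G0.copy()
    theta = np.zeros(neq)
    rhs = np.zeros(neq)
    kept_G, kept_R = [], []
    for it in range(n_iter):
        Rinv = np.linalg.inv(R0)
        Ginv = np.linalg.inv(G0)
        coefs = np.array(
            [Rinv[0, 0], Rinv[1, 1], Rinv[0, 1], Ginv[0, 0], Ginv[1, 1], Ginv[0, 1]]
        )
        data = coefs @ comp_data
        rhs[:m1] = Rinv[0, 0] * w1y1 + Rinv[0, 1] * w1y2
        rhs[m1:] = Rinv[0, 1] * w2y1 + Rinv[1, 1] * w2y2
        noise = rng.standard_normal(neq)
        _sweep_bivariate(
            pattern.indptr, pattern.indices, data, rhs, theta, noise, p1, p2, q
        )

        U = np.column_stack([theta[u1_sl], theta[u2_sl]])
        S_u = U.T @ (a_inverse @ U)
        G0 = invwishart.rvs(df=q + nu_g, scale=S_u + v_g, random_state=rng)
        E = np.column_stack([y1 - W1 @ theta[:m1], y2 - W2 @ theta[m1:]])
        S_e = E.T @ E
        R0 = invwishart.rvs(df=n + nu_r, scale=S_e + v_r, random_state=rng)
        if it >= burn_in and (it - burn_in) % thin == 0:
            kept_G.append(G0.copy())
            kept_R.append(R0.copy())
    G = np.asarray(kept_G)
    R = np.asarray(kept_R)
    samples = {
        "G0": G,
        "R0": R,
        "h2_1": G[:, 0, 0] / (G[:, 0, 0] + R[:, 0, 0]),
        "h2_2": G[:, 1, 1] / (G[:, 1, 1] + R[:, 1, 1]),
        "r_g": G[:, 0, 1] / np.sqrt(G[:, 0, 0] * G[:, 1, 1]),
        "r_e": R[:, 0, 1] / np.sqrt(R[:, 0, 0] * R[:, 1, 1]),
    }
    return GibbsChain(samples, n_iter, burn_in, thin, seed, meta={"n": n, "q": q})
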