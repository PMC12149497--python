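"""Pedigree relationship machinery for the animal model.

A pedigree is a list of animals with sire and dam references. From it we
derive inbreeding coefficients F, the additive (numerator) relationship
matrix A, and the sparse inverse of A assembled directly by Henderson's
rules. A appears in the animal model through ``u ~ N(0, A * sigma2_a)``;
the mixed-model equations only ever need its inverse, which is sparse for
any pedigree.

Internally animals are stored 0-indexed with ``-1`` for an unknown parent;
on disk the convention is 1-indexed with ``0`` for unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = ["Pedigree", "PedigreeError", "trace_pedigree"]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, bad references)."""


@njit(cache=True)
def _inbreeding_ml(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the recursive diagonal (L·D·L') method.

    For animal i, A_ii = sum_j L_ij^2 d_j over its ancestor set, where d_j
    is the Mendelian-sampling variance ratio of ancestor j; F_i = A_ii - 1.
    Requires parents to precede offspring.
    """
    n = sire.shape[0]
    F = np.zeros(n)
    d = np.ones(n)  # Mendelian sampling variance ratios, filled as we go
    L = np.zeros(n)
    for i in range(n):
        s, m = sire[i], dam[i]
        if s >= 0 and m >= 0:
            d[i] = 0.5 - 0.25 * (F[s] + F[m])
        elif s >= 0:
            d[i] = 0.75 - 0.25 * F[s]
        elif m >= 0:
            d[i] = 0.75 - 0.25 * F[m]
        else:
            d[i] = 1.0
            continue  # founder: F = 0
        # accumulate A_ii by tracing ancestors of i (indices <= i)
        a_ii = 0.0
        L[i] = 1.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj, mj = sire[j], dam[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if mj >= 0:
                L[mj] += 0.5 * lj
            a_ii += lj * lj * d[j]
            L[j] = 0.0
        F[i] = a_ii - 1.0
    return F


@njit(cache=True)
def _tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, m = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if m >= 0:
                a += 0.5 * A[j, m]
            A[i, j] = a
            A[j, i] = a
        aii = 1.0
        if s >= 0 and m >= 0:
            aii += 0.5 * A[s, m]
        A[i, i] = aii
    return A


@dataclass
class Pedigree:
    """Topologically ordered pedigree (parents precede offspring).

    Attributes
    ----------
    sire, dam
        0-indexed parent positions, ``-1`` for unknown.
    ids
        External animal labels, parallel to ``sire``/``dam``.
    """

    sire: np.ndarray
    dam: np.ndarray
    ids: np.ndarray
    _F: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        n = self.sire.shape[0]
        if self.dam.shape[0] != n or self.ids.shape[0] != n:
            raise PedigreeError("sire, dam and ids must have equal length")
        idx = np.arange(n)
        for par in (self.sire, self.dam):
            if np.any(par >= idx):
                k = int(np.argmax(par >= idx))
                raise PedigreeError(
                    f"pedigree not topologically ordered: animal at position {k} "
                    "has a parent at the same or later position"
                )
            if np.any(par < -1):
                raise PedigreeError("parent indices must be >= -1")

    def __len__(self) -> int:
        return int(self.sire.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        animal: str = "animal",
        sire: str = "sire",
        dam: str = "dam",
    ) -> "Pedigree":
        """Build from a table using the animal/sire/dam, 0-=-unknown convention.

        Rows are reordered topologically if needed; unknown parents are 0 or NA.
        """
        ids = frame[animal].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(ids)}

        def resolve(col: pd.Series) -> np.ndarray:
            out = np.full(len(ids), -1, dtype=np.int64)
            for i, v in enumerate(col):
                if pd.isna(v) or v == 0:
                    continue
                if v not in pos:
                    raise PedigreeError(f"parent {v!r} is not listed as an animal")
                out[i] = pos[v]
            return out

        s = resolve(frame[sire])
        d = resolve(frame[dam])
        order = _topological_order(s, d)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        s2 = np.where(s[order] >= 0, inv[np.maximum(s[order], 0)], -1)
        d2 = np.where(d[order] >= 0, inv[np.maximum(d[order], 0)], -1)
        return cls(sire=s2, dam=d2, ids=ids[order])

    def to_frame(self) -> pd.DataFrame:
        """Table with external ids and 0 = unknown parent."""
        def ext(par: np.ndarray) -> np.ndarray:
            out = np.zeros(self.n, dtype=object)
            known = par >= 0
            out[known] = self.ids[par[known]]
            return out

        return pd.DataFrame(
            {"animal": self.ids, "sire": ext(self.sire), "dam": ext(self.dam)}
        )

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F for every animal (founders are 0)."""
        if self._F is None:
            self._F = _inbreeding_ml(self.sire, self.dam)
        return self._F

    def mendelian_variance_ratios(self) -> np.ndarray:
        """Within-family (Mendelian sampling) variance as a fraction of sigma2_a."""
        F = self.inbreeding()
        d = np.ones(self.n)
        both = (self.sire >= 0) & (self.dam >= 0)
        d[both] = 0.5 - 0.25 * (F[self.sire[both]] + F[self.dam[both]])
        one_s = (self.sire >= 0) & (self.dam < 0)
        d[one_s] = 0.75 - 0.25 * F[self.sire[one_s]]
        one_d = (self.sire < 0) & (self.dam >= 0)
        d[one_d] = 0.75 - 0.25 * F[self.dam[one_d]]
        return d

    def relationship_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix A by the tabular method.

        O(n^2) memory; intended for small pedigrees and cross-checks against
        :meth:`a_inverse`.
        """
        return _tabular_a(self.sire, self.dam)

    def a_inverse(self) -> sparse.csr_matrix:
        """Sparse A⁻¹ assembled by Henderson's rules with inbreeding."""
        d = self.mendelian_variance_ratios()
        alpha = 1.0 / d
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        idx = np.arange(self.n)

        def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
            rows.append(r)
            cols.append(c)
            vals.append(v)

        add(idx, idx, alpha)
        for par in (self.sire, self.dam):
            k = par >= 0
            add(idx[k], par[k], -0.5 * alpha[k])
            add(par[k], idx[k], -0.5 * alpha[k])
            add(par[k], par[k], 0.25 * alpha[k])
        both = (self.sire >= 0) & (self.dam >= 0)
        add(self.sire[both], self.dam[both], 0.25 * alpha[both])
        add(self.dam[both], self.sire[both], 0.25 * alpha[both])
        ainv = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()
        ainv.sum_duplicates()
        return ainv

    def index_of(self, animals: np.ndarray) -> np.ndarray:
        """Positions of external ids within the pedigree order."""
        pos = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([pos[a] for a in animals], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc


def _topological_order(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Kahn ordering with cycle detection; stable within a generation."""
    n = sire.shape[0]
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                children[p].append(i)
                indeg[i] += 1
    from collections import deque

    queue = deque(int(i) for i in np.flatnonzero(indeg == 0))
    order = []
    while queue:
        i = queue.popleft()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
    return np.asarray(order, dtype=np.int64)


def trace_pedigree(
    pedigree: Pedigree, phenotyped: np.ndarray, generations: int = 5
) -> Pedigree:
    """Restrict a pedigree to phenotyped animals plus ``generations`` of ancestors.

    Ancestors further back than the requested number of generations are cut;
    animals whose parents fall outside the traced set keep those parents as
    unknown, i.e. they become founders of the traced pedigree.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    keep_depth: dict[int, int] = {}
    frontier = list(pedigree.index_of(np.asarray(phenotyped)))
    for i in frontier:
        keep_depth[i] = 0
    depth = 0
    while frontier and depth < generations:
        depth += 1
        nxt = []
        for i in frontier:
            for p in (pedigree.sire[i], pedigree.dam[i]):
                if p >= 0 and p not in keep_depth:
                    keep_depth[int(p)] = depth
                    nxt.append(int(p))
        frontier = nxt
    keep = np.array(sorted(keep_depth), dtype=np.int64)
    keep_set = set(int(k) for k in keep)
    remap = {int(old): new for new, old in enumerate(keep)}

    def par(arr: np.ndarray) -> np.ndarray:
        out = np.full(len(keep), -1, dtype=np.int64)
        for new, old in enumerate(keep):
            p = int(arr[old])
            if p in keep_set:
                out[new] = remap[p]
        return out

    return Pedigree(sire=par(pedigree.sire), dam=par(pedigree.dam), ids=pedigree.ids[keep])
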