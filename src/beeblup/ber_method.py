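"""The BER genetic-evaluation approximation (Bienefeld-Ehrhardt-Reinhardt).

The German Beebreed evaluation sidesteps the block-diagonal sampling
covariance by treating sires and worker groups as single individuals and
replacing the two distinct paternal relationships of workers (within a
colony vs. between colonies) by a single value, whose square root ``q``
becomes the path coefficient from sire to offspring:

``a_i = 1/2 a_dam + q a_sire + delta_i``.

``q`` derives from the asymptotic full-sib relationship ``a_FS`` (the
fixed point of the DPQ-relatedness recursion with inbreeding and
dam-sire relationship ignored) and the paternal half-sib relationship
``a_pHS``.  With the q-weighted parent matrix the sampling covariance is
*assumed* diagonal, which over-shrinks breeding values of aggregates --
the defining approximation of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .pedigree_core import Pedigree, PedigreeError
from .relmatrix import (
    ContributionModel,
    MatingBiology,
    build_Ainv,
    update_ass,
    _indices,
)

__all__ = [
    "BerConstants",
    "asymptotic_afs",
    "path_coefficient_q",
    "ber_D_diagonal",
    "build_M_ber",
    "BerTables",
    "ber_constants",
    "build_ber_tables",
]


@dataclass(frozen=True)
class BerConstants:
    """Asymptotic sib relationships and the sire-path coefficient.

    Attributes
    ----------
    a_FS:
        Asymptotic additive relationship between full-sibs.
    a_pFS:
        Its paternal component, ``a_FS - 1/4``.
    a_pHS:
        Paternal half-sib relationship ``(1 + (S-1) a_FS) / (4S)``.
    q:
        Sire-worker path coefficient, the square root of the mean of the
        two paternal relationships.
    """

    a_FS: float
    a_pFS: float
    a_pHS: float
    q: float


def asymptotic_afs(S: int, D: int, tol: float = 1e-12,
                   max_iter: int = 10_000, start: float = 0.0) -> float:
    """Asymptotic full-sib relationship for the BER contribution model.

    Fixed point of the DPQ-relatedness recursion under ``p1 = 1/D``,
    ``p2 = (S + D - 1)/(D S)`` with inbreeding and the dam-sire
    relationship set to zero.  The recursion is a contraction (slope
    ``(1 - p2)/4 < 1``), so the fixed point is unique and is approached
    within a few generations.
    """
    bio = MatingBiology(S=S, D=D, model=ContributionModel.BER)
    from .relmatrix import p1_same_drone, p2_same_dpq

    p1, p2 = p1_same_drone(bio), p2_same_dpq(bio)
    a = float(start)
    for _ in range(max_iter):
        a_next = update_ass(0.0, 0.0, p1, p2, a, 0.0)
        if abs(a_next - a) < tol:
            return a_next
        a = a_next
    raise RuntimeError("fixed-point iteration for a_FS did not converge")


def path_coefficient_q(a_FS: float, S: int) -> BerConstants:
    """Constants of the q-weighted model from the asymptotic a_FS."""
    a_pFS = a_FS - 0.25
    a_pHS = (1.0 + (S - 1.0) * a_FS) / (4.0 * S)
    mean = (a_pFS + a_pHS) / 2.0
    if mean < 0.0:
        raise ValueError(f"negative radicand for q (a_FS={a_FS}, S={S})")
    return BerConstants(a_FS=a_FS, a_pFS=a_pFS, a_pHS=a_pHS, q=float(np.sqrt(mean)))


def ber_constants(S: int, D: int) -> BerConstants:
    """Convenience: asymptotic a_FS and q for given mating sizes."""
    return path_coefficient_q(asymptotic_afs(S, D), S)


def ber_D_diagonal(q: float, a_ds: float, F_d: float, F_s: float) -> float:
    """Diagonal sampling term of the q-weighted model, both parents known.

    Includes both Mendelian sampling and the variance left over because
    the sire path carries ``q`` rather than 1/2.
    """
    d = 1.0 + (0.5 - q) * a_ds - 0.25 * (1.0 + F_d) - q * q * (1.0 + F_s)
    if d <= 0.0:
        raise ValueError(f"nonpositive sampling term ({d:.4g})")
    return d


def build_M_ber(pedigree: Pedigree, q: float) -> sp.csr_matrix:
    """Parent matrix with 1/2 on the dam path and q on the sire path."""
    _, dam, sire = _indices(pedigree)
    rows, cols, vals = [], [], []
    for i in range(len(pedigree)):
        if dam[i] >= 0:
            rows.append(i)
            cols.append(int(dam[i]))
            vals.append(0.5)
        if sire[i] >= 0:
            rows.append(i)
            cols.append(int(sire[i]))
            vals.append(q)
    n = len(pedigree)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


class BerTables:
    """Incremental q-weighted relationship tables (all records as singletons).

    Mirrors :class:`beeblup.relmatrix.TabularTables` but with the BER
    parent weights and a diagonal sampling matrix.  The dense relationship
    matrix is kept so that the dam-sire relationship feeding each new
    diagonal can be read off directly; its diagonal is ``1 + F`` with
    ``F = a_ds / 2`` exactly as in the plain animal model.
    """

    def __init__(self, S: int, D: int, capacity: int = 256,
                 dense_cap: int = 20_000,
                 constants: Optional[BerConstants] = None) -> None:
        self.constants = constants or ber_constants(S, D)
        self.q = self.constants.q
        self.dense_cap = dense_cap
        self.n = 0
        self._A = np.zeros((max(capacity, 16), max(capacity, 16)))
        self.dam: list[int] = []
        self.sire: list[int] = []
        self.F: list[float] = []
        self.Dii: list[float] = []

    def _grow(self) -> None:
        cap = self._A.shape[0]
        if self.n < cap:
            return
        new_cap = min(max(cap * 2, self.n + 1), max(self.dense_cap, self.n + 1))
        A = np.zeros((new_cap, new_cap))
        A[: self.n, : self.n] = self._A[: self.n, : self.n]
        self._A = A

    def add(self, category: int, dam: int = -1, sire: int = -1) -> int:
        if self.n >= self.dense_cap:
            raise MemoryError(
                f"dense relationship matrix capped at {self.dense_cap} records"
            )
        i = self.n
        if dam >= i or sire >= i:
            raise PedigreeError("parent appears after offspring")
        self._grow()
        A = self._A
        q = self.q

        row = np.zeros(i)
        if dam >= 0:
            row += 0.5 * A[dam, :i]
        if sire >= 0:
            row += q * A[sire, :i]

        if dam >= 0 and sire >= 0:
            a_ds = float(A[dam, sire])
            F_d = float(A[dam, dam]) - 1.0
            F_s = float(A[sire, sire]) - 1.0
            Dii = ber_D_diagonal(q, a_ds, F_d, F_s)
            F_rec = 0.5 * a_ds
            diag = (0.25 * float(A[dam, dam]) + q * q * float(A[sire, sire])
                    + q * a_ds + Dii)
        elif dam >= 0:
            Dii = 1.0 - 0.25 * float(A[dam, dam])
            F_rec = 0.0
            diag = 0.25 * float(A[dam, dam]) + Dii
        elif sire >= 0:
            Dii = 1.0 - q * q * float(A[sire, sire])
            F_rec = 0.0
            diag = q * q * float(A[sire, sire]) + Dii
        else:
            Dii, F_rec, diag = 1.0, 0.0, 1.0

        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = diag
        self.dam.append(dam)
        self.sire.append(sire)
        self.F.append(F_rec)
        self.Dii.append(Dii)
        self.n += 1
        return i

    @property
    def A(self) -> np.ndarray:
        return self._A[: self.n, : self.n]

    def M_sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i in range(self.n):
            if self.dam[i] >= 0:
                rows.append(i)
                cols.append(self.dam[i])
                vals.append(0.5)
            if self.sire[i] >= 0:
                rows.append(i)
                cols.append(self.sire[i])
                vals.append(self.q)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def Dinv_sparse(self) -> sp.csr_matrix:
        return sp.diags(1.0 / np.asarray(self.Dii), format="csr")

    def D_sparse(self) -> sp.csr_matrix:
        return sp.diags(np.asarray(self.Dii), format="csr")

    def Ainv_sparse(self) -> sp.csr_matrix:
        return build_Ainv(self.M_sparse(), self.Dinv_sparse())


def build_ber_tables(pedigree: Pedigree, S: int, D: int,
                     dense_cap: int = 20_000) -> BerTables:
    """Forward pass over an ordered pedigree with the q-weighted model."""
    cat, dam, sire = _indices(pedigree)
    tab = BerTables(S, D, capacity=len(pedigree) or 16, dense_cap=dense_cap)
    for i in range(len(pedigree)):
        tab.add(int(cat[i]), int(dam[i]), int(sire[i]))
    return tab
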