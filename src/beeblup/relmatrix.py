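"""Exact numerator relationship matrix for honey-bee pedigrees (BB method).

The breeding value of entity *i* decomposes as
``a_i = 1/2 a_dam + 1/2 a_sire + delta_i``; in matrix form ``a = M a + d``
so that ``A = (I - M)^-1 D (I - M)'^-1`` and
``A^-1 = (I - M)' D^-1 (I - M)``, where ``D = var(d)`` is the covariance
matrix of Mendelian sampling terms, expressed in units of the base-
population additive variance ``sigma_A^2``.

In honey bees ``D`` is not diagonal.  A drone is a flying gamete that
produces clonal sperm, and it mates a single queen, so two full-sibs may
carry an *identical* paternal gamete; moreover the contribution of the
``S`` drone-producing queens that constitute a pseudo-sire varies around
``1/S``.  Both effects correlate the sampling terms of the offspring of
one (queen x sire) mating, making ``D`` block diagonal with one block per
mating.  Within a block all off-diagonals equal ``cov(delta_FS)``, the
sampling covariance of full-sibs, which in turn equals the diagonal entry
of the worker group (the n -> infinity family mean).

Two probabilities summarise the mating biology:

* ``p1`` -- probability that two full-sibs descend from the same drone;
* ``p2`` -- probability that they descend from the same drone-producing
  queen (``p2 >= p1``).

They follow from the variance of contribution fractions; closed forms are
provided for empirical variances, for Poisson-distributed family sizes,
and for the equal-contribution partition used by the BER genetic
evaluation (see :mod:`beeblup.ber_method`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .pedigree_core import Category, Pedigree, PedigreeError

__all__ = [
    "ContributionModel",
    "MatingBiology",
    "RelationshipTables",
    "p1_same_drone",
    "p2_same_dpq",
    "cov_fullsib_sampling",
    "sampling_variance_queen",
    "sire_bv_variance",
    "sampling_variance_sire",
    "sampling_variance_workergroup",
    "update_ass",
    "inbreeding_from_asd",
    "build_M",
    "build_D",
    "invert_D_blocks",
    "build_A_and_tables",
    "build_Ainv",
    "TabularTables",
]

#: Smallest admissible eigenvalue of a Mendelian-sampling block.
PD_TOL = 1e-10


class ContributionModel(str, Enum):
    """How drone / drone-producing-queen contribution fractions vary."""

    POISSON = "poisson"      # Poisson family sizes: p1 = 1/T + 1/D, p2 = 1/D + 1/S
    BER = "ber"              # equal drone shares: p1 = 1/D, p2 = (S + D - 1)/(D S)
    EMPIRICAL = "empirical"  # user-supplied contribution variances


@dataclass(frozen=True)
class MatingBiology:
    """Mating-biology configuration.

    Parameters
    ----------
    S:
        Number of drone-producing queens (DPQs) constituting a sire.
    D:
        Number of drones mated to a queen.
    T:
        Total number of offspring of a queen; only the Poisson model uses
        it (through the 1/T term, negligible for realistic T).
    model:
        Distributional assumption for contribution fractions.
    var_cD, var_cS:
        Empirical variances of the drone and DPQ contribution fractions;
        used only under ``EMPIRICAL``.
    """

    S: int = 8
    D: int = 12
    T: float = 1e6
    model: ContributionModel = ContributionModel.POISSON
    var_cD: float = 0.0
    var_cS: float = 0.0

    def __post_init__(self) -> None:
        if self.S < 1 or self.D < 1:
            raise ValueError("S and D must be >= 1")
        if self.var_cD < 0 or self.var_cS < 0:
            raise ValueError("contribution variances must be >= 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def p1_same_drone(biology: MatingBiology) -> float:
    """Probability that two full-sibs descend from the same drone."""
    if biology.model is ContributionModel.EMPIRICAL:
        p1 = biology.D * biology.var_cD + 1.0 / biology.D
    elif biology.model is ContributionModel.POISSON:
        p1 = 1.0 / biology.T + 1.0 / biology.D
    else:  # BER: equal contribution of each drone
        p1 = 1.0 / biology.D
    if p1 > 1.0:
        raise ValueError(f"p1 = {p1:.4f} > 1; inconsistent var_cD")
    return p1


def p2_same_dpq(biology: MatingBiology) -> float:
    """Probability that two full-sibs descend from the same DPQ."""
    S, D = biology.S, biology.D
    if biology.model is ContributionModel.EMPIRICAL:
        p2 = S * biology.var_cS + 1.0 / S
    elif biology.model is ContributionModel.POISSON:
        p2 = 1.0 / D + 1.0 / S
    else:  # BER partition of 1 - 1/D into same/different DPQ
        p2 = (S + D - 1.0) / (D * S)
    if p2 > 1.0:
        raise ValueError(f"p2 = {p2:.4f} > 1; inconsistent var_cS")
    if p2 < p1_same_drone(biology):
        raise ValueError("p2 < p1; inconsistent empirical variances")
    return p2


def cov_fullsib_sampling(
    p1: float, p2: float, F_s: float, S: int, a_ss: float
) -> float:
    """Covariance of Mendelian sampling terms of full-sibs (per sigma_A^2).

    The first term comes from sibs sharing a drone father, the second from
    variation among DPQ contributions beyond the 1/S average already
    carried by the pedigree.
    """
    return (
        p1 * (1.0 - F_s) / 4.0
        + (p2 - 1.0 / S) * (1.0 + F_s - a_ss) / 4.0
    )


def sampling_variance_queen(F_d: float, F_s: float, S: int, a_ss: float) -> float:
    """Mendelian sampling variance of a queen with both parents known.

    Components: maternal gamete sampling, gamete sampling within one DPQ,
    and sampling among the S DPQs of the sire.
    """
    return (
        0.25 * (1.0 - F_d)
        + 0.25 * (1.0 - F_s)
        + 0.25 * (S - 1.0) / S * (1.0 + F_s - a_ss)
    )


def sire_bv_variance(S: int, F_s: float, a_ss: float) -> float:
    """Variance of the mean breeding value of the S DPQs of a sire."""
    return ((1.0 + F_s) + (S - 1.0) * a_ss) / S


def sampling_variance_sire(var_delta: float, cov_FS: float, S: int) -> float:
    """Sampling variance of a sire's mean breeding-value deviation."""
    return var_delta / S + (S - 1.0) / S * cov_FS


def sampling_variance_workergroup(cov_FS: float) -> float:
    """Worker-group sampling variance: the n -> infinity family-mean limit."""
    return cov_FS


def update_ass(
    F_d: float,
    F_s: float,
    p1: float,
    p2: float,
    a_ss_prev: float,
    a_sd: float,
) -> float:
    """Relatedness among the DPQs of a newly formed sire.

    Terms: shared dam; same drone (paternal relatedness 1/2); same DPQ but
    different drones (paternal relatedness (1+F_s)/4); different DPQs
    (paternal relatedness a_ss/4); and the dam-sire relationship.
    """
    return (
        (1.0 + F_d) / 4.0
        + 0.5 * p1
        + 0.25 * (p2 - p1) * (1.0 + F_s)
        + 0.25 * (1.0 - p2) * a_ss_prev
        + 0.5 * a_sd
    )


def inbreeding_from_asd(a_sd: float) -> float:
    """Inbreeding of an offspring from the dam-sire additive relationship."""
    return 0.5 * a_sd


# ---------------------------------------------------------------------------
# Tabular construction
# ---------------------------------------------------------------------------

_CAT_CODE = {Category.QUEEN: 0, Category.SIRE: 1, Category.WORKER_GROUP: 2}
QUEEN, SIRE, WORKER = 0, 1, 2


@dataclass
class _MatingStats:
    """Derived quantities of one (dam, sire) mating, fixed at first use."""

    a_sd: float
    F_off: float          # inbreeding of offspring of this mating
    cov_fs: float         # full-sib sampling covariance (per sigma_A^2)
    var_delta_q: float    # queen sampling variance
    var_delta_s: float    # sire-mean sampling variance
    ass_new: float        # DPQ relatedness of a sire bred from this mating
    members: list = field(default_factory=list)


class TabularTables:
    """Incremental tabular construction of A, D and the recursion tables.

    Records are appended in pedigree order (parents first).  A dense copy
    of ``A`` is maintained so that the dam-sire relationship ``a_sd`` of
    any new mating can be read off directly; inbreeding ``F``, the
    within-sire DPQ relatedness ``a_ss`` and the Mendelian-sampling
    blocks are updated in the same forward pass.

    The dense ``A`` limits this construction to moderate pedigrees
    (default cap 20 000 records, ~3.2 GB at the cap).
    """

    def __init__(self, biology: MatingBiology, capacity: int = 256,
                 dense_cap: int = 20_000) -> None:
        self.biology = biology
        self.p1 = p1_same_drone(biology)
        self.p2 = p2_same_dpq(biology)
        self.dense_cap = dense_cap
        self.n = 0
        self._A = np.zeros((max(capacity, 16), max(capacity, 16)))
        self.cat: list[int] = []
        self.dam: list[int] = []
        self.sire: list[int] = []
        self.F: list[float] = []      # sires: inbreeding of their member DPQs
        self.ass: list[float] = []    # meaningful for sires; 0.0 elsewhere
        self.Dii: list[float] = []
        self.mating: dict[tuple[int, int], _MatingStats] = {}
        self._singletons: list[int] = []
        self._has_offspring: list[bool] = []

    # -- construction ------------------------------------------------------

    def _grow(self) -> None:
        cap = self._A.shape[0]
        if self.n < cap:
            return
        new_cap = min(max(cap * 2, self.n + 1), max(self.dense_cap, self.n + 1))
        A = np.zeros((new_cap, new_cap))
        A[: self.n, : self.n] = self._A[: self.n, : self.n]
        self._A = A

    def mating_stats(self, d: int, s: int) -> _MatingStats:
        """Stats of mating (d, s); computed once when the mating first appears."""
        key = (d, s)
        st = self.mating.get(key)
        if st is None:
            a_sd = float(self._A[d, s])
            F_d, F_s, ass_s = self.F[d], self.F[s], self.ass[s]
            cov_fs = cov_fullsib_sampling(self.p1, self.p2, F_s,
                                          self.biology.S, ass_s)
            var_dq = sampling_variance_queen(F_d, F_s, self.biology.S, ass_s)
            st = _MatingStats(
                a_sd=a_sd,
                F_off=inbreeding_from_asd(a_sd),
                cov_fs=cov_fs,
                var_delta_q=var_dq,
                var_delta_s=sampling_variance_sire(var_dq, cov_fs,
                                                   self.biology.S),
                ass_new=update_ass(F_d, F_s, self.p1, self.p2, ass_s, a_sd),
            )
            self.mating[key] = st
        return st

    def add(self, category: int, dam: int = -1, sire: int = -1) -> int:
        """Append one record; returns its index."""
        if self.n >= self.dense_cap:
            raise MemoryError(
                f"tabular A capped at {self.dense_cap} records; "
                "raise dense_cap explicitly for larger pedigrees"
            )
        i = self.n
        if dam >= i or sire >= i:
            raise PedigreeError("parent appears after offspring")
        self._grow()
        A = self._A
        S = self.biology.S
        both = dam >= 0 and sire >= 0

        row = np.zeros(i)
        if dam >= 0:
            row += 0.5 * A[dam, :i]
        if sire >= 0:
            row += 0.5 * A[sire, :i]

        st: Optional[_MatingStats] = None
        if both:
            st = self.mating_stats(dam, sire)
            if st.members:
                # cov(delta_i, a_j): cov(delta_FS) for full sibs j, and half
                # of the parent's value for each of j's offspring -- the
                # sampling covariance propagates down descendants of sibs
                # that were recorded before this one.
                if any(self._has_offspring[m] for m in st.members):
                    c = np.zeros(i)
                    c[st.members] = st.cov_fs
                    for j in range(min(st.members) + 1, i):
                        dj, sj = self.dam[j], self.sire[j]
                        v = 0.0
                        if dj >= 0:
                            v += 0.5 * c[dj]
                        if sj >= 0:
                            v += 0.5 * c[sj]
                        if v:
                            c[j] += v
                    row += c
                else:
                    row[st.members] += st.cov_fs

        if category == QUEEN:
            if both:
                Dii = st.var_delta_q
                F_rec = st.F_off
            elif dam >= 0:
                Dii = 1.0 - 0.25 * float(A[dam, dam])
                F_rec = 0.0
            elif sire >= 0:
                Dii = 1.0 - 0.25 * float(A[sire, sire])
                F_rec = 0.0
            else:
                Dii, F_rec = 1.0, 0.0
            ass_rec = 0.0
        elif category == SIRE:
            if both:
                Dii = st.var_delta_s
                F_rec = st.F_off
                ass_rec = st.ass_new
            elif dam < 0 and sire < 0:
                F_rec, ass_rec = 0.0, 0.0
                Dii = sire_bv_variance(S, 0.0, 0.0)  # 1/S
            else:
                # one parent known: complete the group variance so that
                # the diagonal equals var(A-bar) of the new sire
                F_d = self.F[dam] if dam >= 0 else 0.0
                F_s = self.F[sire] if sire >= 0 else 0.0
                ass_s = self.ass[sire] if sire >= 0 else 0.0
                F_rec = 0.0
                ass_rec = update_ass(F_d, F_s, self.p1, self.p2, ass_s, 0.0)
                parent_var = 0.0
                if dam >= 0:
                    parent_var += 0.25 * float(A[dam, dam])
                if sire >= 0:
                    parent_var += 0.25 * float(A[sire, sire])
                Dii = sire_bv_variance(S, F_rec, ass_rec) - parent_var
        elif category == WORKER:
            if not both:
                raise PedigreeError("worker group requires both parents")
            Dii = sampling_variance_workergroup(st.cov_fs)
            F_rec = st.F_off
            ass_rec = 0.0
        else:
            raise ValueError(f"unknown category code {category}")

        if Dii < -PD_TOL:
            raise ValueError(f"negative sampling variance at record {i}")

        diag = Dii
        if dam >= 0:
            diag += 0.25 * float(A[dam, dam])
        if sire >= 0:
            diag += 0.25 * float(A[sire, sire])
        if both:
            diag += 0.5 * float(A[dam, sire])

        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = diag

        self.cat.append(category)
        self.dam.append(dam)
        self.sire.append(sire)
        self._has_offspring.append(False)
        if dam >= 0:
            self._has_offspring[dam] = True
        if sire >= 0:
            self._has_offspring[sire] = True
        self.F.append(F_rec)
        self.ass.append(ass_rec)
        self.Dii.append(Dii)
        if both:
            st.members.append(i)
        else:
            self._singletons.append(i)
        self.n += 1
        return i

    # -- assembled matrices ------------------------------------------------

    @property
    def A(self) -> np.ndarray:
        """Dense numerator relationship matrix (view, n x n)."""
        return self._A[: self.n, : self.n]

    def M_sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for i in range(self.n):
            for p in (self.dam[i], self.sire[i]):
                if p >= 0:
                    rows.append(i)
                    cols.append(p)
                    vals.append(0.5)
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def iter_blocks(self):
        """Yield (member_indices, dense_block) for every D block."""
        for i in self._singletons:
            yield [i], np.array([[self.Dii[i]]])
        for st in self.mating.values():
            if not st.members:
                continue
            m = len(st.members)
            blk = np.full((m, m), st.cov_fs)
            blk[np.diag_indices(m)] = [self.Dii[j] for j in st.members]
            yield st.members, blk

    def D_sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for members, blk in self.iter_blocks():
            idx = np.asarray(members)
            m = len(idx)
            rows.append(np.repeat(idx, m))
            cols.append(np.tile(idx, m))
            vals.append(blk.ravel())
        if not rows:
            return sp.csr_matrix((self.n, self.n))
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )

    def Dinv_sparse(self) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for members, blk in self.iter_blocks():
            idx = np.asarray(members)
            m = len(idx)
            if m == 1:
                v = blk[0, 0]
                if v <= PD_TOL:
                    raise np.linalg.LinAlgError(
                        f"singular sampling block at record {idx[0]}"
                    )
                inv = np.array([[1.0 / v]])
            else:
                w = np.linalg.eigvalsh(blk)
                if w[0] <= PD_TOL:
                    raise np.linalg.LinAlgError(
                        f"non-positive-definite sampling block "
                        f"(records {members}, min eig {w[0]:.3e})"
                    )
                inv = np.linalg.inv(blk)
            rows.append(np.repeat(idx, m))
            cols.append(np.tile(idx, m))
            vals.append(inv.ravel())
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )

    def Ainv_sparse(self) -> sp.csr_matrix:
        return build_Ainv(self.M_sparse(), self.Dinv_sparse())


# ---------------------------------------------------------------------------
# Public API over Pedigree objects
# ---------------------------------------------------------------------------


@dataclass
class RelationshipTables:
    """All relationship quantities of a pedigree under one biology model."""

    ids: list[str]
    F: np.ndarray          # per record; for sires: inbreeding of member DPQs
    a_ss: np.ndarray       # per record; meaningful for sires
    a_sd: dict             # (dam_id, sire_id) -> dam-sire additive relationship
    M: sp.csr_matrix
    Dmat: sp.csr_matrix
    Dinv: sp.csr_matrix
    A: np.ndarray
    Ainv: sp.csr_matrix


def _indices(pedigree: Pedigree):
    dam = np.full(len(pedigree), -1, dtype=np.int64)
    sire = np.full(len(pedigree), -1, dtype=np.int64)
    cat = np.zeros(len(pedigree), dtype=np.int64)
    for i, rec in enumerate(pedigree):
        cat[i] = _CAT_CODE[rec.category]
        if rec.dam_id is not None:
            dam[i] = pedigree.index_of(rec.dam_id)
        if rec.sire_id is not None:
            sire[i] = pedigree.index_of(rec.sire_id)
    return cat, dam, sire


def build_M(pedigree: Pedigree) -> sp.csr_matrix:
    """Parent-contribution matrix: 1/2 per known parent, zeros for base rows."""
    _, dam, sire = _indices(pedigree)
    rows, cols, vals = [], [], []
    for i in range(len(pedigree)):
        for p in (dam[i], sire[i]):
            if p >= 0:
                rows.append(i)
                cols.append(p)
                vals.append(0.5)
    n = len(pedigree)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_A_and_tables(
    pedigree: Pedigree,
    biology: MatingBiology,
    dense_cap: int = 20_000,
) -> RelationshipTables:
    """Single forward pass building A, D, D^-1, A^-1 and the recursions.

    The pedigree must be ordered (see
    :func:`beeblup.pedigree_core.validate_and_order`).
    """
    cat, dam, sire = _indices(pedigree)
    tab = TabularTables(biology, capacity=len(pedigree) or 16,
                        dense_cap=dense_cap)
    for i in range(len(pedigree)):
        tab.add(int(cat[i]), int(dam[i]), int(sire[i]))
    ids = [r.id for r in pedigree]
    a_sd = {
        (ids[d], ids[s]): st.a_sd for (d, s), st in tab.mating.items()
    }
    Dinv = tab.Dinv_sparse()
    M = tab.M_sparse()
    return RelationshipTables(
        ids=ids,
        F=np.asarray(tab.F),
        a_ss=np.asarray(tab.ass),
        a_sd=a_sd,
        M=M,
        Dmat=tab.D_sparse(),
        Dinv=Dinv,
        A=tab.A.copy(),
        Ainv=build_Ainv(M, Dinv),
    )


def build_D(pedigree: Pedigree, biology: MatingBiology,
            dense_cap: int = 20_000) -> sp.csr_matrix:
    """Block-diagonal Mendelian-sampling covariance matrix (per sigma_A^2)."""
    return build_A_and_tables(pedigree, biology, dense_cap=dense_cap).Dmat


def invert_D_blocks(Dmat: sp.spmatrix) -> sp.csr_matrix:
    """Block-wise numerical inverse of a block-diagonal matrix.

    Blocks are recovered as connected components of the sparsity pattern,
    so the input need not carry explicit block bookkeeping.
    """
    D = sp.csr_matrix(Dmat)
    n = D.shape[0]
    ncomp, labels = sp.csgraph.connected_components(D, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(ncomp + 1))
    rows, cols, vals = [], [], []
    for c in range(ncomp):
        idx = order[bounds[c]:bounds[c + 1]]
        blk = D[np.ix_(idx, idx)].toarray()
        m = len(idx)
        if m == 1:
            if blk[0, 0] <= PD_TOL:
                raise np.linalg.LinAlgError(
                    f"singular block at record {idx[0]}"
                )
            inv = 1.0 / blk
        else:
            w = np.linalg.eigvalsh(blk)
            if w[0] <= PD_TOL:
                raise np.linalg.LinAlgError(
                    f"non-positive-definite block (records {idx.tolist()})"
                )
            inv = np.linalg.inv(blk)
        rows.append(np.repeat(idx, m))
        cols.append(np.tile(idx, m))
        vals.append(inv.ravel())
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )


def build_Ainv(M: sp.spmatrix, Dinv: sp.spmatrix) -> sp.csr_matrix:
    """Inverse relationship matrix via (I - M)' D^-1 (I - M)."""
    n = M.shape[0]
    IM = sp.identity(n, format="csr") - sp.csr_matrix(M)
    Ainv = IM.T @ sp.csr_matrix(Dinv) @ IM
    Ainv = (Ainv + Ainv.T) * 0.5  # enforce exact symmetry
    return sp.csr_matrix(Ainv)
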