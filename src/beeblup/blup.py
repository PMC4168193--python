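"""Mixed-model equations for colony records with worker and queen effects.

A colony observation is modelled as ``y = Xb + Z_W a_W + Z_Q a_Q + e``
where ``a_W`` holds worker effects, ``a_Q`` queen effects, both with
covariance ``G (x) A sigma_... `` structured through the numerator
relationship matrix ``A`` and the 2x2 genetic (co)variance matrix of the
two effects.  The mixed-model equations add ``A^-1 alpha_k`` to the
genetic sub-blocks, with ``(alpha_1, alpha_2; alpha_2, alpha_3) =
sigma_e^2 G^-1``.

Each observation links exactly one worker group (worker effect) and its
queen (queen effect); residuals are independent between colonies because
a queen heads a single colony for life.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree_core import Pedigree

__all__ = [
    "GeneticParams",
    "MmeSystem",
    "alpha_matrix",
    "assemble_mme",
    "solve_mme",
    "selection_criterion",
    "solve_mme_arrays",
    "estimate_breeding_values",
]


@dataclass(frozen=True)
class GeneticParams:
    """Genetic parameters of the two-effect colony model.

    Defaults correspond to a trait with substantial queen contribution and
    the typical negative worker-queen genetic correlation.
    """

    var_AW: float = 1.0
    var_AQ: float = 0.5
    r_G: float = -0.5
    var_E: float = 2.0

    def __post_init__(self) -> None:
        if self.var_AW <= 0 or self.var_AQ <= 0 or self.var_E <= 0:
            raise ValueError("variances must be positive")
        if not abs(self.r_G) < 1:
            raise ValueError("|r_G| must be < 1 (G would be singular)")

    @property
    def G(self) -> np.ndarray:
        cov = self.r_G * np.sqrt(self.var_AW * self.var_AQ)
        return np.array([[self.var_AW, cov], [cov, self.var_AQ]])


def alpha_matrix(params: GeneticParams) -> tuple[float, float, float]:
    """Variance ratios (alpha1, alpha2, alpha3) = sigma_e^2 * G^-1 entries."""
    Ginv = np.linalg.inv(params.G)
    a = Ginv * params.var_E
    return float(a[0, 0]), float(a[0, 1]), float(a[1, 1])


@dataclass
class MmeSystem:
    """Assembled mixed-model equations, ordered (b | a_W | a_Q)."""

    coeff: sp.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    n_records: int

    def split_solution(self, x: np.ndarray):
        nf, n = self.n_fixed, self.n_records
        return x[:nf], x[nf:nf + n], x[nf + n:]


def _assemble(
    X: sp.csr_matrix,
    worker_idx: np.ndarray,
    queen_idx: np.ndarray,
    y: np.ndarray,
    Ainv: sp.spmatrix,
    alphas: tuple[float, float, float],
) -> MmeSystem:
    n = Ainv.shape[0]
    nobs = len(y)
    a1, a2, a3 = alphas
    ones = np.ones(nobs)
    ZW = sp.csr_matrix((ones, (np.arange(nobs), worker_idx)), shape=(nobs, n))
    ZQ = sp.csr_matrix((ones, (np.arange(nobs), queen_idx)), shape=(nobs, n))
    Ainv = sp.csr_matrix(Ainv)
    C = sp.bmat(
        [
            [X.T @ X, X.T @ ZW, X.T @ ZQ],
            [ZW.T @ X, ZW.T @ ZW + a1 * Ainv, ZW.T @ ZQ + a2 * Ainv],
            [ZQ.T @ X, ZQ.T @ ZW + a2 * Ainv, ZQ.T @ ZQ + a3 * Ainv],
        ],
        format="csc",
    )
    rhs = np.concatenate([X.T @ y, ZW.T @ y, ZQ.T @ y])
    return MmeSystem(coeff=C, rhs=rhs, n_fixed=X.shape[1], n_records=n)


def assemble_mme(
    phenotypes: pd.DataFrame,
    pedigree: Pedigree,
    Ainv: sp.spmatrix,
    alphas: tuple[float, float, float],
    fixed_effects: Sequence[str] = (),
) -> MmeSystem:
    """Assemble the mixed-model equations from a phenotype table.

    ``phenotypes`` must carry ``queen_id``, ``worker_group_id`` and
    ``trait_value``; columns named in ``fixed_effects`` are expanded as
    categorical effects next to the intercept.  All pedigree records are
    represented in the solution whether or not they have data.
    """
    for col in ("queen_id", "worker_group_id", "trait_value"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    for rid in pd.concat(
        [phenotypes["queen_id"], phenotypes["worker_group_id"]]
    ):
        if rid not in pedigree:
            raise KeyError(f"phenotype references id {rid!r} missing from pedigree")
    nobs = len(phenotypes)
    widx = np.array([pedigree.index_of(r) for r in phenotypes["worker_group_id"]])
    qidx = np.array([pedigree.index_of(r) for r in phenotypes["queen_id"]])
    y = phenotypes["trait_value"].to_numpy(dtype=float)
    X = sp.csr_matrix(np.ones((nobs, 1)))
    if fixed_effects:
        dummies = pd.get_dummies(
            phenotypes[list(fixed_effects)].astype(str), drop_first=True
        ).to_numpy(dtype=float)
        X = sp.hstack([X, sp.csr_matrix(dummies)], format="csr")
    return _assemble(X, widx, qidx, y, Ainv, alphas)


def solve_mme(system: MmeSystem, tol: float = 1e-10) -> dict[str, np.ndarray]:
    """Solve the equations; sparse direct factorization with CG fallback."""
    if system.rhs.size == 0 or not np.any(system.rhs):
        nf, n = system.n_fixed, system.n_records
        zero = np.zeros(n)
        return {"fixed": np.zeros(nf), "ebv_worker": zero,
                "ebv_queen": zero.copy()}
    try:
        x = spla.spsolve(system.coeff, system.rhs)
    except Exception:
        x, info = spla.cg(system.coeff, system.rhs, rtol=tol, maxiter=50_000)
        if info != 0:
            raise np.linalg.LinAlgError("MME solver did not converge")
    b, aW, aQ = system.split_solution(x)
    return {"fixed": b, "ebv_worker": aW, "ebv_queen": aQ}


def solve_mme_arrays(
    worker_idx: np.ndarray,
    queen_idx: np.ndarray,
    y: np.ndarray,
    Ainv: sp.spmatrix,
    alphas: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path used by the simulator: intercept-only model, index arrays.

    Returns (fixed, ebv_worker, ebv_queen).
    """
    nobs = len(y)
    if nobs == 0:
        n = Ainv.shape[0]
        return np.zeros(1), np.zeros(n), np.zeros(n)
    X = sp.csr_matrix(np.ones((nobs, 1)))
    system = _assemble(X, worker_idx, queen_idx, y, Ainv, alphas)
    sol = solve_mme(system)
    return sol["fixed"], sol["ebv_worker"], sol["ebv_queen"]


def selection_criterion(
    record_id: str,
    pedigree: Pedigree,
    ebv_worker: np.ndarray,
    ebv_queen: np.ndarray,
    method: str = "BB",
    q: Optional[float] = None,
    worker_of: Optional[dict[str, str]] = None,
    mate_of: Optional[dict[str, str]] = None,
) -> float:
    """Selection criterion of a mated queen.

    BB: the worker+queen effect EBV of the queen's own worker group (the
    average offspring of the mating).  BER: half the queen's own summed
    EBV plus ``q`` times the summed EBV of her mate.
    """
    if method.upper() == "BB":
        if worker_of is None or record_id not in worker_of:
            raise KeyError(f"no worker group recorded for queen {record_id!r}")
        w = pedigree.index_of(worker_of[record_id])
        return float(ebv_worker[w] + ebv_queen[w])
    if q is None:
        raise ValueError("BER criterion requires the path coefficient q")
    if mate_of is None or record_id not in mate_of:
        raise KeyError(f"no mate recorded for queen {record_id!r}")
    d = pedigree.index_of(record_id)
    s = pedigree.index_of(mate_of[record_id])
    return float(
        0.5 * (ebv_worker[d] + ebv_queen[d])
        + q * (ebv_worker[s] + ebv_queen[s])
    )


def estimate_breeding_values(
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    params: GeneticParams,
    Ainv: sp.spmatrix,
    fixed_effects: Sequence[str] = (),
) -> pd.DataFrame:
    """Convenience wrapper: assemble, solve, and tabulate EBVs per record."""
    alphas = alpha_matrix(params)
    system = assemble_mme(phenotypes, pedigree, Ainv, alphas, fixed_effects)
    sol = solve_mme(system)
    return pd.DataFrame(
        {
            "id": [r.id for r in pedigree],
            "category": [r.category.value for r in pedigree],
            "ebv_worker": sol["ebv_worker"],
            "ebv_queen": sol["ebv_queen"],
        }
    )
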