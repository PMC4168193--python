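"""Gene-dropping oracle for bee relationship matrices.

Independent Monte-Carlo estimate of the numerator relationship matrix by
explicit simulation of alleles: founder queens get unique allele labels,
a sire is S explicit drone-producing queens (DPQs), and each mating
realises D drones, every drone being a single gamete cloned from a random
allele of a random DPQ of the sire.  Offspring take one random maternal
allele from the dam and the allele of one random drone.  This matches the
equal-contribution (BER) drone model: two sibs pick the same drone with
probability 1/D, and two distinct drones come from the same DPQ with
probability 1/S.

Relationships are recovered from identity-by-descent: A_XY = 2 f_XY with
f the coancestry, averaging over group members (exactly over the S DPQs
of a sire; two independent random workers for a worker group, which are
distinct members with probability one).  Within-replicate averaging over
the four allele combinations is exact, so the only Monte-Carlo noise is
over replicate gene drops and worker draws.
"""

from __future__ import annotations

import numpy as np

from beeblup.pedigree_core import Category, Pedigree

__all__ = ["gene_drop_A"]


def _pair_equal_mean(x, y):
    """Mean IBD indicator over the 4 allele combinations, per replicate.

    x, y: (R, 2) allele-label arrays of two (possibly identical) diploids.
    """
    acc = 0.0
    for i in range(2):
        for j in range(2):
            acc = acc + (x[:, i] == y[:, j])
    return acc / 4.0


def gene_drop_A(pedigree: Pedigree, S: int, D: int, reps: int,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo relationship matrix and its standard errors.

    Returns (A_hat, se) with A_hat[i, j] = 2 * mean coancestry and ``se``
    the Monte-Carlo standard error of each entry.
    """
    n = len(pedigree)
    R = reps
    label = 0

    queen_alleles: dict[int, np.ndarray] = {}   # (R, 2)
    dpq_alleles: dict[int, np.ndarray] = {}     # (R, S, 2)
    drones: dict[tuple[int, int], np.ndarray] = {}  # mating -> (R, D)

    def mating_drones(d: int, s: int) -> np.ndarray:
        key = (d, s)
        if key not in drones:
            dpq = rng.integers(S, size=(R, D))
            al = rng.integers(2, size=(R, D))
            drones[key] = np.take_along_axis(
                dpq_alleles[s].reshape(R, 2 * S),
                dpq * 2 + al, axis=1)
        return drones[key]

    def offspring_queen(d: int, s: int) -> np.ndarray:
        mat = np.take_along_axis(queen_alleles[d],
                                 rng.integers(2, size=(R, 1)), axis=1)[:, 0]
        dr = mating_drones(d, s)
        pat = np.take_along_axis(dr, rng.integers(D, size=(R, 1)),
                                 axis=1)[:, 0]
        return np.stack([mat, pat], axis=1)

    idx = {r.id: i for i, r in enumerate(pedigree)}
    for i, rec in enumerate(pedigree):
        d = idx[rec.dam_id] if rec.dam_id is not None else -1
        s = idx[rec.sire_id] if rec.sire_id is not None else -1
        if rec.category is Category.QUEEN:
            if d < 0 or s < 0:
                # unknown parents: unrelated founder alleles
                queen_alleles[i] = np.tile([label, label + 1], (R, 1))
                label += 2
                if d >= 0 or s >= 0:
                    raise NotImplementedError(
                        "gene drop oracle covers fully known or base queens")
            else:
                queen_alleles[i] = offspring_queen(d, s)
        elif rec.category is Category.SIRE:
            if d < 0 and s < 0:
                dpq_alleles[i] = np.arange(
                    label, label + 2 * S).reshape(1, S, 2).repeat(R, axis=0)
                label += 2 * S
            else:
                members = [offspring_queen(d, s) for _ in range(S)]
                dpq_alleles[i] = np.stack(members, axis=1)
        # worker groups are sampled on demand from their mating

    def representation(i: int):
        """('queen', (R,2)) or ('sire', (R,S,2)) member alleles of record i.

        Worker groups are represented by a freshly sampled worker; two calls
        give two independent (hence distinct) members of the huge group.
        """
        rec = pedigree.records[i]
        if rec.category is Category.QUEEN:
            return "queen", queen_alleles[i]
        if rec.category is Category.SIRE:
            return "sire", dpq_alleles[i]
        return "queen", offspring_queen(idx[rec.dam_id], idx[rec.sire_id])

    A_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            is_worker = pedigree.records[i].category is Category.WORKER_GROUP
            ti, xi = representation(i)
            if i == j and not is_worker:
                tj, xj = ti, xi        # with-replacement member sampling
            else:
                tj, xj = representation(j)
            if ti == "sire" and tj == "sire":
                acc = 0.0
                for a in range(S):
                    for b in range(S):
                        acc = acc + _pair_equal_mean(xi[:, a], xj[:, b])
                f = acc / (S * S)
            elif ti == "sire" or tj == "sire":
                grp, single = (xi, xj) if ti == "sire" else (xj, xi)
                acc = 0.0
                for a in range(S):
                    acc = acc + _pair_equal_mean(grp[:, a], single)
                f = acc / S
            else:
                f = _pair_equal_mean(xi, xj)
            v = 2.0 * f
            A_hat[i, j] = A_hat[j, i] = v.mean()
            se[i, j] = se[j, i] = v.std(ddof=1) / np.sqrt(R)
    return A_hat, se
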