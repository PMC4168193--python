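import numpy as np
import pytest

from beeblup.pedigree_core import Category, IndividualRecord, Pedigree
from beeblup.relmatrix import ContributionModel, MatingBiology


@pytest.fixture
def poisson_biology():
    return MatingBiology(S=8, D=12, model=ContributionModel.POISSON)


@pytest.fixture
def ber_biology():
    return MatingBiology(S=8, D=12, model=ContributionModel.BER)


@pytest.fixture
def small_family():
    """Base dam and sire, two full-sib queens, a worker group and a sire."""
    R, C = IndividualRecord, Category
    return Pedigree([
        R("d", C.QUEEN),
        R("s", C.SIRE, group_size=8),
        R("q1", C.QUEEN, "d", "s"),
        R("q2", C.QUEEN, "d", "s"),
        R("w", C.WORKER_GROUP, "d", "s"),
        R("sn", C.SIRE, "d", "s", group_size=8),
    ])


@pytest.fixture
def fig1_fragment():
    """A queen whose sire descends from a recorded dam and sire."""
    R, C = IndividualRecord, Category
    return Pedigree([
        R("2a", C.QUEEN),
        R("1b", C.SIRE, "4a", "4b", group_size=8),
        R("1a", C.QUEEN, "2a", "1b"),
        R("4a", C.QUEEN),
        R("4b", C.SIRE, group_size=8),
    ])


def random_pedigree(rng: np.random.Generator, n_records: int = 60,
                    p_base: float = 0.15, p_single: float = 0.05) -> Pedigree:
    """Random structurally valid bee pedigree, parents before offspring.

    Queens are mated once (all their offspring entities share one sire);
    every mated queen gets at most one worker group; occasional
    single-parent queens and sires exercise the unknown-parent rules.
    """
    R, C = IndividualRecord, Category
    recs: list[IndividualRecord] = []
    queens: list[str] = []
    sires: list[str] = []
    mate: dict[str, str] = {}
    has_worker: set[str] = set()
    k = 0

    def base_queen():
        nonlocal k
        rid = f"q{k}"; k += 1
        recs.append(R(rid, C.QUEEN))
        queens.append(rid)
        return rid

    def base_sire():
        nonlocal k
        rid = f"s{k}"; k += 1
        recs.append(R(rid, C.SIRE, group_size=8))
        sires.append(rid)
        return rid

    def pick_mating():
        d = queens[rng.integers(len(queens))]
        if d not in mate:
            mate[d] = sires[rng.integers(len(sires))]
        return d, mate[d]

    base_queen()
    base_sire()
    while len(recs) < n_records:
        u = rng.random()
        if u < p_base:
            (base_queen if rng.random() < 0.5 else base_sire)()
            continue
        cat = rng.choice(["Q", "S", "W"], p=[0.45, 0.25, 0.30])
        nonlocal_k = f"{cat.lower()}{k}"; k += 1
        if cat == "W":
            free = [q for q in mate if q not in has_worker]
            if not free:
                d, s = pick_mating()
                if d in has_worker:
                    continue
            else:
                d = free[rng.integers(len(free))]
                s = mate[d]
            recs.append(R(nonlocal_k, C.WORKER_GROUP, d, s))
            has_worker.add(d)
            continue
        if rng.random() < p_single:
            if rng.random() < 0.5:
                d, s = queens[rng.integers(len(queens))], None
            else:
                d, s = None, sires[rng.integers(len(sires))]
        else:
            d, s = pick_mating()
        if cat == "Q":
            recs.append(R(nonlocal_k, C.QUEEN, d, s))
            queens.append(nonlocal_k)
        else:
            recs.append(R(nonlocal_k, C.SIRE, d, s, group_size=8))
            sires.append(nonlocal_k)
    return Pedigree(recs)


@pytest.fixture
def random_pedigree_factory():
    return random_pedigree
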