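"""Stochastic simulation of a honey-bee breeding scheme.

The simulated scheme mirrors a small closed breeding programme: every
year ``NSY`` sires and ``NQY = NSY * NFQ * NQ`` queens are born, the
queens in ``NSY * NFQ`` full-sib groups of ``NQ``.  Newborn queens are
mated immediately to the sires born the year before (each sire serves
``NFQ`` full-sib groups, every queen of a group to the same sire); each
mated queen heads one colony whose performance -- worker effect of the
worker group plus queen effect of the queen plus residual -- is recorded
when the queen is two years old.  From year 4 the dams of the next
generation are chosen among the two-year-old tested queens: the top
``NSY`` by the selection criterion breed one sire each and the top
``NSY * NFQ`` breed one full-sib group of queens each (random choice when
selection is off).

True breeding values (worker and queen effect, genetic correlation
``r_G``) are built from the parent average plus two Mendelian-sampling
components: one shared by all offspring entities of a mating -- the
full-sib sampling covariance -- and an individual residual.  The shared
and individual standard normal pairs are drawn from a bivariate normal
with correlation ``r_G``.  Sampling variances come from the exact
relationship recursion, by default with the equal-contribution (BER)
drone probabilities, so that the covariance structure generated is
exactly the one the BB estimator assumes.

Evaluation reproduces the standard diagnostics: within-replicate
regressions of true on estimated breeding values (slope 1 = unbiased
BLUP), the correlation between the selection criterion and the breeding
goal (the worker+queen total of a prospective virgin daughter), and the
cumulative genetic response under truncation selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ber_method import BerTables, ber_constants
from .blup import GeneticParams, alpha_matrix, solve_mme_arrays
from .pedigree_core import Category, IndividualRecord, Pedigree
from .relmatrix import (
    QUEEN,
    SIRE,
    WORKER,
    ContributionModel,
    MatingBiology,
    TabularTables,
)

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "draw_correlated_pair",
    "simulate_queen_bv",
    "simulate_sire_bv",
    "simulate_workergroup_bv",
    "simulate_phenotype",
    "simulate_goal_tbv",
    "run_scheme",
    "run_replicates",
    "regression_slopes",
    "criterion_values",
    "goal_tbv_values",
    "year_correlation",
    "cumulative_response",
    "evaluate_replicates",
]


@dataclass(frozen=True)
class SimConfig:
    """Breeding-scheme configuration.

    The defaults define a small programme: 5 sires per year, 25 full-sib
    queen groups of 3 (75 queens per year), sires of 8 drone-producing
    queens, 12 drones per mating, 20 years.
    """

    NSY: int = 5
    NFQ: int = 5
    NQ: int = 3
    years: int = 20
    replicates: int = 1000
    selection: bool = False
    method: str = "BB"           # estimator driving selection decisions
    seed: int = 0
    biology: MatingBiology = MatingBiology(model=ContributionModel.BER)
    params: GeneticParams = GeneticParams()

    def __post_init__(self) -> None:
        if self.years < 4:
            raise ValueError("scheme needs at least 4 years")
        if self.method.upper() not in ("BB", "BER"):
            raise ValueError("method must be BB or BER")

    @property
    def NQY(self) -> int:
        """Queens born per year: every sire serves NFQ groups of NQ."""
        return self.NSY * self.NFQ * self.NQ

    @property
    def n_groups(self) -> int:
        return self.NSY * self.NFQ

    @property
    def total_records(self) -> int:
        # base sires (3 years), base dams/sires + queens/workers (2 years),
        # then NSY sires + NQY queens + NQY worker groups per production year
        return (
            3 * self.NSY
            + 2 * (2 * self.n_groups + 2 * self.NQY)
            + (self.years - 3) * (self.NSY + 2 * self.NQY)
        )


# ---------------------------------------------------------------------------
# Elementary generators
# ---------------------------------------------------------------------------


def draw_correlated_pair(r_G: float, rng: np.random.Generator,
                         size: Optional[int] = None) -> np.ndarray:
    """Standard bivariate normal sample(s) with correlation ``r_G``."""
    m = 1 if size is None else size
    z = rng.standard_normal((m, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = r_G * z[:, 0] + math.sqrt(1.0 - r_G * r_G) * z[:, 1]
    return out[0] if size is None else out


def _scaled_sampling(shared_pair, own_pair, var_delta, cov_FS, var_A):
    """Shared + individual sampling terms per trait, scaled by sigma_A^2."""
    var_A = np.asarray(var_A, dtype=float)
    resid = var_delta - cov_FS
    if resid < -1e-12:
        raise ValueError("var(delta) < cov(delta_FS): negative radicand")
    resid = max(resid, 0.0)
    out = np.asarray(shared_pair) * np.sqrt(cov_FS * var_A)
    if own_pair is not None:
        out = out + np.asarray(own_pair) * np.sqrt(resid * var_A)
    return out


def simulate_queen_bv(dam_tbv, sire_tbv, shared_pair, own_pair,
                      var_delta: float, cov_FS: float,
                      var_A=(1.0, 1.0)) -> np.ndarray:
    """True breeding-value pair of a queen: parent average + shared +
    individual Mendelian sampling."""
    parent = 0.5 * (np.asarray(dam_tbv, float) + np.asarray(sire_tbv, float))
    return parent + _scaled_sampling(shared_pair, own_pair, var_delta,
                                     cov_FS, var_A)


def simulate_sire_bv(dam_tbv, sire_tbv, shared_pair, own_pair,
                     var_delta_bar: float, cov_FS: float,
                     var_A=(1.0, 1.0)) -> np.ndarray:
    """As for a queen but with the group-mean sampling variance."""
    return simulate_queen_bv(dam_tbv, sire_tbv, shared_pair, own_pair,
                             var_delta_bar, cov_FS, var_A)


def simulate_workergroup_bv(dam_tbv, sire_tbv, shared_pair, cov_FS,
                            var_A=(1.0, 1.0)) -> np.ndarray:
    """Worker-group pair: parent average + shared term only (the
    individual deviation averages out over the huge group)."""
    parent = 0.5 * (np.asarray(dam_tbv, float) + np.asarray(sire_tbv, float))
    return parent + _scaled_sampling(shared_pair, None, cov_FS, cov_FS, var_A)


def simulate_phenotype(worker_tbv_W: float, queen_tbv_Q: float,
                       var_E: float, rng: np.random.Generator) -> float:
    """Colony record: worker effect + queen effect + residual."""
    return worker_tbv_W + queen_tbv_Q + math.sqrt(var_E) * rng.standard_normal()


def simulate_goal_tbv(dam_tbv, sire_tbv, shared_pair, own_pair,
                      var_delta: float, cov_FS: float,
                      var_A=(1.0, 1.0)) -> float:
    """Breeding goal: worker+queen total of a virgin daughter of a mating."""
    return float(
        simulate_queen_bv(dam_tbv, sire_tbv, shared_pair, own_pair,
                          var_delta, cov_FS, var_A).sum()
    )


# ---------------------------------------------------------------------------
# Replicate container
# ---------------------------------------------------------------------------


@dataclass
class ReplicateResult:
    """Pedigree, true values, phenotypes and final EBVs of one replicate."""

    config: SimConfig
    cat: np.ndarray
    dam: np.ndarray
    sire: np.ndarray
    byear: np.ndarray
    tbv: np.ndarray                # (n, 2): worker, queen effect
    mate: np.ndarray               # sire index a queen was mated to, -1 else
    worker_of: np.ndarray          # worker-group index of a mated queen
    shared: np.ndarray             # (n, 2) shared sampling pair of her mating
    covfs_unit: np.ndarray         # cov(delta_FS)/sigma_A^2 of her mating
    vardq_unit: np.ndarray         # var(delta_queen)/sigma_A^2 of her mating
    phen_queen: np.ndarray
    phen_worker: np.ndarray
    phen_year: np.ndarray
    phen_value: np.ndarray
    ebv: dict[str, tuple[np.ndarray, np.ndarray]]
    q_ber: float

    @property
    def n(self) -> int:
        return len(self.cat)

    def to_pedigree(self) -> Pedigree:
        """Export as a :class:`~beeblup.pedigree_core.Pedigree`."""
        cats = {QUEEN: Category.QUEEN, SIRE: Category.SIRE,
                WORKER: Category.WORKER_GROUP}
        prefix = {QUEEN: "Q", SIRE: "S", WORKER: "W"}
        ids = [f"{prefix[int(c)]}{i}" for i, c in enumerate(self.cat)]
        recs = []
        for i in range(self.n):
            recs.append(IndividualRecord(
                id=ids[i],
                category=cats[int(self.cat[i])],
                dam_id=ids[self.dam[i]] if self.dam[i] >= 0 else None,
                sire_id=ids[self.sire[i]] if self.sire[i] >= 0 else None,
                birth_year=int(self.byear[i]),
                group_size=(1.0 if self.cat[i] == QUEEN
                            else float(self.config.biology.S)
                            if self.cat[i] == SIRE else math.inf),
            ))
        return Pedigree(recs)

    def phenotype_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "queen_idx": self.phen_queen,
            "worker_idx": self.phen_worker,
            "year": self.phen_year,
            "trait_value": self.phen_value,
        })


# ---------------------------------------------------------------------------
# Scheme runner
# ---------------------------------------------------------------------------


class _SchemeRunner:
    def __init__(self, config: SimConfig, rng: np.random.Generator,
                 methods: Sequence[str]):
        self.cfg = config
        self.rng = rng
        self.methods = [m.upper() for m in methods]
        need_ber = "BER" in self.methods or (
            config.selection and config.method.upper() == "BER")
        cap = config.total_records + 1
        self.gen = TabularTables(config.biology, capacity=cap,
                                 dense_cap=max(cap, 20_000))
        self.ber: Optional[BerTables] = (
            BerTables(config.biology.S, config.biology.D, capacity=cap,
                      dense_cap=max(cap, 20_000)) if need_ber else None
        )
        self.constants = (self.ber.constants if self.ber is not None
                          else ber_constants(config.biology.S, config.biology.D))
        self.alphas = alpha_matrix(config.params)
        self.sig2 = np.array([config.params.var_AW, config.params.var_AQ])
        # record arrays (lists while building)
        self.cat: list[int] = []
        self.byear: list[int] = []
        self.tbv: list[np.ndarray] = []
        self.mate: list[int] = []
        self.worker_of: list[int] = []
        self.shared: list[np.ndarray] = []
        self.covfs_unit: list[float] = []
        self.vardq_unit: list[float] = []
        self.phen_queen: list[int] = []
        self.phen_worker: list[int] = []
        self.phen_year: list[int] = []
        self.phen_value: list[float] = []

    # -- record plumbing ---------------------------------------------------

    def _add(self, cat: int, dam: int, sire: int, byear: int,
             tbv: np.ndarray) -> int:
        i = self.gen.add(cat, dam, sire)
        if self.ber is not None:
            self.ber.add(cat, dam, sire)
        self.cat.append(cat)
        self.byear.append(byear)
        self.tbv.append(tbv)
        self.mate.append(-1)
        self.worker_of.append(-1)
        self.shared.append(np.full(2, np.nan))
        self.covfs_unit.append(np.nan)
        self.vardq_unit.append(np.nan)
        return i

    def _pair(self, size: Optional[int] = None) -> np.ndarray:
        return draw_correlated_pair(self.cfg.params.r_G, self.rng, size)

    def _mate_queen(self, q: int, s: int) -> None:
        """Mate queen q to sire s: shared pair, worker group, colony record."""
        cfg = self.cfg
        self.mate[q] = s
        self.shared[q] = self._pair()
        st = self.gen.mating_stats(q, s)
        self.covfs_unit[q] = st.cov_fs
        self.vardq_unit[q] = st.var_delta_q
        tbv_w = simulate_workergroup_bv(self.tbv[q], self.tbv[s],
                                        self.shared[q], st.cov_fs, self.sig2)
        w = self._add(WORKER, q, s, self.byear[q], tbv_w)
        self.worker_of[q] = w
        p = simulate_phenotype(tbv_w[0], self.tbv[q][1],
                               cfg.params.var_E, self.rng)
        self.phen_queen.append(q)
        self.phen_worker.append(w)
        self.phen_year.append(self.byear[q] + 2)
        self.phen_value.append(p)

    def _make_sire(self, dam_q: int, year: int) -> int:
        s_mate = self.mate[dam_q]
        st = self.gen.mating_stats(dam_q, s_mate)
        tbv = simulate_sire_bv(self.tbv[dam_q], self.tbv[s_mate],
                               self.shared[dam_q], self._pair(),
                               st.var_delta_s, st.cov_fs, self.sig2)
        return self._add(SIRE, dam_q, s_mate, year, tbv)

    def _make_queen_group(self, dam_q: int, year: int) -> list[int]:
        s_mate = self.mate[dam_q]
        st = self.gen.mating_stats(dam_q, s_mate)
        out = []
        for _ in range(self.cfg.NQ):
            tbv = simulate_queen_bv(self.tbv[dam_q], self.tbv[s_mate],
                                    self.shared[dam_q], self._pair(),
                                    st.var_delta_q, st.cov_fs, self.sig2)
            out.append(self._add(QUEEN, dam_q, s_mate, year, tbv))
        return out

    def _base_sire(self, year: int) -> int:
        S = self.cfg.biology.S
        tbv = self._pair() * np.sqrt(self.sig2 / S)
        return self._add(SIRE, -1, -1, year, tbv)

    def _base_queen_group(self, year: int) -> list[int]:
        """Base full-sib group: offspring of a recorded base mating.

        The shared base dam and sire enter the pedigree (without a colony
        record), so the estimators see the same full-sib covariance the
        generator draws -- base full-sibs are related through their base
        mating exactly as later cohorts are.
        """
        dam = self._add(QUEEN, -1, -1, year - 2,
                        self._pair() * np.sqrt(self.sig2))
        sire = self._base_sire(year - 2)
        self.mate[dam] = sire
        self.shared[dam] = self._pair()
        st = self.gen.mating_stats(dam, sire)
        self.covfs_unit[dam] = st.cov_fs
        self.vardq_unit[dam] = st.var_delta_q
        return self._make_queen_group(dam, year)

    # -- estimation --------------------------------------------------------

    def _solve(self, method: str, year_limit: Optional[int] = None):
        py = np.asarray(self.phen_year)
        mask = slice(None) if year_limit is None else py <= year_limit
        widx = np.asarray(self.phen_worker)[mask]
        qidx = np.asarray(self.phen_queen)[mask]
        yv = np.asarray(self.phen_value)[mask]
        if method == "BB":
            Ainv = self.gen.Ainv_sparse()
        else:
            assert self.ber is not None
            Ainv = self.ber.Ainv_sparse()
        _, ebvW, ebvQ = solve_mme_arrays(widx, qidx, yv, Ainv, self.alphas)
        return ebvW, ebvQ

    def _criteria(self, cand: np.ndarray, ebvW: np.ndarray,
                  ebvQ: np.ndarray, method: str) -> np.ndarray:
        if method == "BB":
            w = np.asarray([self.worker_of[c] for c in cand])
            return ebvW[w] + ebvQ[w]
        q = self.constants.q
        m = np.asarray([self.mate[c] for c in cand])
        return (0.5 * (ebvW[cand] + ebvQ[cand])
                + q * (ebvW[m] + ebvQ[m]))

    # -- main loop ---------------------------------------------------------

    def run(self) -> ReplicateResult:
        cfg = self.cfg
        rng = self.rng
        sires_by_year: dict[int, list[int]] = {}
        queens_by_year: dict[int, list[int]] = {}

        for y in (1, 2, 3):
            sires_by_year[y] = [self._base_sire(y) for _ in range(cfg.NSY)]
        for y in (2, 3):
            queens: list[int] = []
            groups = [self._base_queen_group(y) for _ in range(cfg.n_groups)]
            self._allocate_mates(groups, sires_by_year[y - 1])
            for g in groups:
                queens.extend(g)
            queens_by_year[y] = queens

        for y in range(4, cfg.years + 1):
            cand = np.asarray(queens_by_year[y - 2])
            if cfg.selection:
                ebvW, ebvQ = self._solve(cfg.method.upper(), year_limit=y)
                crit = self._criteria(cand, ebvW, ebvQ, cfg.method.upper())
                order = np.argsort(-crit, kind="stable")
                sire_dams = cand[order[: cfg.NSY]]
                queen_dams = cand[order[: cfg.n_groups]]
            else:
                sire_dams = rng.choice(cand, cfg.NSY, replace=False)
                queen_dams = rng.choice(cand, cfg.n_groups, replace=False)
            sires_by_year[y] = [self._make_sire(d, y) for d in sire_dams]
            groups = [self._make_queen_group(d, y) for d in queen_dams]
            self._allocate_mates(groups, sires_by_year[y - 1])
            queens_by_year[y] = [q for g in groups for q in g]

        ebv = {m: self._solve(m) for m in self.methods}
        return ReplicateResult(
            config=cfg,
            cat=np.asarray(self.cat, dtype=np.int8),
            dam=np.asarray(self.gen.dam, dtype=np.int32),
            sire=np.asarray(self.gen.sire, dtype=np.int32),
            byear=np.asarray(self.byear, dtype=np.int16),
            tbv=np.asarray(self.tbv),
            mate=np.asarray(self.mate, dtype=np.int32),
            worker_of=np.asarray(self.worker_of, dtype=np.int32),
            shared=np.asarray(self.shared),
            covfs_unit=np.asarray(self.covfs_unit),
            vardq_unit=np.asarray(self.vardq_unit),
            phen_queen=np.asarray(self.phen_queen, dtype=np.int32),
            phen_worker=np.asarray(self.phen_worker, dtype=np.int32),
            phen_year=np.asarray(self.phen_year, dtype=np.int16),
            phen_value=np.asarray(self.phen_value),
            ebv=ebv,
            q_ber=self.constants.q,
        )

    def _allocate_mates(self, groups: list[list[int]],
                        sires: list[int]) -> None:
        """Randomly assign full-sib groups to sires, NFQ groups per sire;
        every queen of a group is mated to the same sire."""
        cfg = self.cfg
        assignment = np.repeat(sires, cfg.NFQ)
        perm = self.rng.permutation(len(groups))
        for gi, slot in zip(perm, range(len(assignment))):
            s = int(assignment[slot])
            for q in groups[gi]:
                self._mate_queen(q, s)


def run_scheme(config: SimConfig, replicate: int = 0,
               methods: Sequence[str] = ("BB", "BER")) -> ReplicateResult:
    """Run one replicate of the scheme; fully determined by config + index."""
    seed = np.random.SeedSequence([config.seed, replicate])
    rng = np.random.default_rng(seed)
    return _SchemeRunner(config, rng, methods).run()


def run_replicates(config: SimConfig,
                   methods: Sequence[str] = ("BB", "BER"),
                   replicates: Optional[int] = None,
                   progress: bool = False) -> list[ReplicateResult]:
    """Run ``config.replicates`` independent replicates."""
    n = config.replicates if replicates is None else replicates
    out = []
    for r in range(n):
        out.append(run_scheme(config, replicate=r, methods=methods))
        if progress and (r + 1) % 25 == 0:
            print(f"  replicate {r + 1}/{n}", flush=True)
    return out


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

_CATEGORY_NAMES = {QUEEN: "queens", SIRE: "sires", WORKER: "colonies"}
_EFFECTS = {"worker": 0, "queen": 1}


def regression_slopes(rep: ReplicateResult, method: str,
                      year: int) -> dict[tuple[str, str], float]:
    """Within-replicate slopes of TBV on EBV per category and effect.

    Cells with (near-)degenerate EBV variance yield NaN.
    """
    ebvW, ebvQ = rep.ebv[method.upper()]
    ebv = {"worker": ebvW, "queen": ebvQ}
    out: dict[tuple[str, str], float] = {}
    for code, cname in _CATEGORY_NAMES.items():
        idx = np.flatnonzero((rep.cat == code) & (rep.byear == year))
        for ename, col in _EFFECTS.items():
            if len(idx) < 2:
                out[(cname, ename)] = np.nan
                continue
            x = ebv[ename][idx]
            t = rep.tbv[idx, col]
            xc = x - x.mean()
            sxx = float(xc @ xc)
            out[(cname, ename)] = (
                float(xc @ (t - t.mean()) / sxx) if sxx > 1e-12 else np.nan
            )
    return out


def criterion_values(rep: ReplicateResult, method: str,
                     queens: np.ndarray) -> np.ndarray:
    """Selection criterion of mated queens under a method's final EBVs."""
    ebvW, ebvQ = rep.ebv[method.upper()]
    if method.upper() == "BB":
        w = rep.worker_of[queens]
        return ebvW[w] + ebvQ[w]
    m = rep.mate[queens]
    return (0.5 * (ebvW[queens] + ebvQ[queens])
            + rep.q_ber * (ebvW[m] + ebvQ[m]))


def goal_tbv_values(rep: ReplicateResult, queens: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Breeding-goal TBVs: one virgin daughter per mated queen.

    Reuses the mating's shared sampling pair and draws a fresh individual
    residual, so goals correlate with the colony's worker group exactly as
    real daughters would.
    """
    cfg = rep.config
    sig2 = np.array([cfg.params.var_AW, cfg.params.var_AQ])
    out = np.empty(len(queens))
    for k, qi in enumerate(queens):
        si = rep.mate[qi]
        own = draw_correlated_pair(cfg.params.r_G, rng)
        out[k] = simulate_goal_tbv(
            rep.tbv[qi], rep.tbv[si], rep.shared[qi], own,
            rep.vardq_unit[qi], rep.covfs_unit[qi], sig2,
        )
    return out


def year_correlation(rep: ReplicateResult, method: str, year: int,
                     rng: np.random.Generator) -> float:
    """Correlation between criterion EBV and goal TBV over the matings of
    one year (the mated queens born that year)."""
    queens = np.flatnonzero((rep.cat == QUEEN) & (rep.byear == year)
                            & (rep.mate >= 0))
    crit = criterion_values(rep, method, queens)
    goal = goal_tbv_values(rep, queens, rng)
    if crit.std() < 1e-12 or goal.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(crit, goal)[0, 1])


def cumulative_response(rep: ReplicateResult) -> pd.Series:
    """Mean worker+queen TBV total of the queens born in each year."""
    total = rep.tbv.sum(axis=1)
    years = sorted(set(int(y) for y in rep.byear[rep.cat == QUEEN]))
    vals = {}
    for y in years:
        idx = (rep.cat == QUEEN) & (rep.byear == y)
        vals[y] = float(total[idx].mean())
    return pd.Series(vals, name="response")


def evaluate_replicates(
    results: Iterable[ReplicateResult],
    year: int = 20,
    methods: Sequence[str] = ("BB", "BER"),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Aggregate diagnostics over replicates.

    Returns a dict with:

    * ``slopes`` -- mean within-replicate regression slope of TBV on EBV
      with its standard error, per method, category and effect;
    * ``correlations`` -- mean correlation between criterion EBV and goal
      TBV among the matings of ``year``;
    * ``response`` -- mean cumulative response per birth year (only
      meaningful for selection runs).
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    methods = [m.upper() for m in methods if m.upper() in results[0].ebv]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 797]))

    slope_rows = []
    corr_rows = []
    slope_acc: dict = {}
    corr_acc: dict = {m: [] for m in methods}
    resp_acc: list[pd.Series] = []
    for rep in results:
        # one goal-TBV draw per replicate, shared across methods
        queens = np.flatnonzero((rep.cat == QUEEN) & (rep.byear == year)
                                & (rep.mate >= 0))
        goal = goal_tbv_values(rep, queens, rng)
        for m in methods:
            for key, v in regression_slopes(rep, m, year).items():
                slope_acc.setdefault((m,) + key, []).append(v)
            crit = criterion_values(rep, m, queens)
            if crit.std() > 1e-12 and goal.std() > 1e-12:
                corr_acc[m].append(float(np.corrcoef(crit, goal)[0, 1]))
        resp_acc.append(cumulative_response(rep))

    for (m, cname, ename), vals in slope_acc.items():
        v = np.asarray(vals)
        v = v[np.isfinite(v)]
        slope_rows.append({
            "method": m, "category": cname, "effect": ename,
            "slope": v.mean(), "se": v.std(ddof=1) / math.sqrt(len(v)),
            "n_reps": len(v),
        })
    for m in methods:
        v = np.asarray(corr_acc[m])
        corr_rows.append({
            "method": m, "correlation": v.mean(),
            "se": v.std(ddof=1) / math.sqrt(len(v)), "n_reps": len(v),
        })
    resp = pd.concat(resp_acc, axis=1)
    response = pd.DataFrame({
        "year": resp.index,
        "response": resp.mean(axis=1),
        "se": resp.std(axis=1, ddof=1) / math.sqrt(resp.shape[1]),
    }).reset_index(drop=True)
    return {
        "slopes": pd.DataFrame(slope_rows),
        "correlations": pd.DataFrame(corr_rows),
        "response": response,
    }
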