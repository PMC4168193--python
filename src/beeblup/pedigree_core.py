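"""Pedigree data model for honey-bee breeding populations.

A honey-bee pedigree contains three kinds of entities:

* **queens** -- single diploid individuals, the selection candidates;
* **sires** (pseudo-sires) -- groups of ``S`` drone-producing queens whose
  drones collectively fathered the offspring of a mated queen, treated as
  one pedigree "individual";
* **worker groups** -- the ~10^4 workers of one colony, treated as one
  entity with an averaged breeding value.

Every entity has at most one dam (a queen) and one sire (a pseudo-sire).
Because a queen is mated once, all offspring entities of one
(dam, sire) pair -- the worker group of the dam's colony plus any progeny
queens and progeny sires -- form a full-sib family.  These families are
the *mating blocks*: the units on which the Mendelian-sampling covariance
matrix is block diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "Category",
    "IndividualRecord",
    "Pedigree",
    "MatingBlock",
    "PedigreeError",
    "validate_and_order",
    "find_mating_blocks",
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
]


class PedigreeError(ValueError):
    """Raised for structural problems in a pedigree (cycles, bad links)."""


class Category(str, Enum):
    """Entity type of a pedigree record."""

    QUEEN = "Q"
    SIRE = "S"
    WORKER_GROUP = "W"


#: Sentinel group size for worker groups; all formulas use the n -> inf limit.
INFINITE_GROUP = math.inf


@dataclass(frozen=True)
class IndividualRecord:
    """One pedigree node: a queen, a pseudo-sire or a worker group.

    Parameters
    ----------
    id:
        Unique token identifying the record.
    category:
        Entity type; determines which sampling-variance formula applies.
    dam_id, sire_id:
        Parent links.  The dam must be a queen, the sire a pseudo-sire.
        ``None`` marks an unknown parent (base individuals).
    birth_year:
        Integer year of birth; used by the breeding-scheme simulator and
        for cohort-wise summaries.
    group_size:
        Number of individuals aggregated in the record: 1 for a queen,
        ``S`` drone-producing queens for a sire, ``math.inf`` for a
        worker group.
    """

    id: str
    category: Category
    dam_id: Optional[str] = None
    sire_id: Optional[str] = None
    birth_year: int = 0
    group_size: float = 1.0

    def __post_init__(self) -> None:
        if self.category is Category.WORKER_GROUP and self.group_size == 1.0:
            object.__setattr__(self, "group_size", INFINITE_GROUP)

    @property
    def is_base(self) -> bool:
        return self.dam_id is None and self.sire_id is None


class Pedigree:
    """Ordered collection of :class:`IndividualRecord` with id lookup."""

    def __init__(self, records: Iterable[IndividualRecord] = ()) -> None:
        self.records: list[IndividualRecord] = list(records)
        self._index = {r.id: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.id in seen:
                    raise PedigreeError(f"duplicate id {r.id!r}")
                seen.add(r.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[IndividualRecord]:
        return iter(self.records)

    def __getitem__(self, rid: str) -> IndividualRecord:
        return self.records[self._index[rid]]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def index_of(self, rid: str) -> int:
        return self._index[rid]


@dataclass
class MatingBlock:
    """All offspring entities of one (dam queen x pseudo-sire) mating.

    Base records (any record missing a parent) form singleton blocks.
    A full block holds the dam's worker group plus any progeny queens and
    progeny sires; its size is 1 + #queens + #sires.
    """

    dam_id: Optional[str]
    sire_id: Optional[str]
    member_ids: list[str] = field(default_factory=list)

    @property
    def is_singleton(self) -> bool:
        return len(self.member_ids) == 1


def _check_parent_links(ped: Pedigree) -> None:
    for rec in ped:
        for pid, want, label in (
            (rec.dam_id, Category.QUEEN, "dam"),
            (rec.sire_id, Category.SIRE, "sire"),
        ):
            if pid is None:
                continue
            if pid not in ped:
                raise PedigreeError(f"{rec.id}: unknown {label} id {pid!r}")
            if ped[pid].category is not want:
                raise PedigreeError(
                    f"{rec.id}: {label} {pid!r} is a "
                    f"{ped[pid].category.name}, expected {want.name}"
                )
        if rec.category is Category.WORKER_GROUP and (
            rec.dam_id is None or rec.sire_id is None
        ):
            raise PedigreeError(
                f"worker group {rec.id} must have both parents known"
            )


def validate_and_order(pedigree: Pedigree) -> Pedigree:
    """Validate parent links and return a topologically ordered pedigree.

    Parents precede offspring in the result.  The original relative order
    is preserved among records whose parents are already placed (stable
    Kahn ordering), so an already-ordered pedigree is returned unchanged.

    Raises
    ------
    PedigreeError
        If ids are duplicated, a parent link dangles, a dam is not a
        queen, a sire is not a pseudo-sire, or the parent graph contains
        a cycle.
    """
    _check_parent_links(pedigree)
    n = len(pedigree)
    placed = [False] * n
    out: list[IndividualRecord] = []
    remaining = list(range(n))
    while remaining:
        progressed = False
        next_round: list[int] = []
        for i in remaining:
            rec = pedigree.records[i]
            ok = True
            for pid in (rec.dam_id, rec.sire_id):
                if pid is not None and not placed[pedigree.index_of(pid)]:
                    ok = False
                    break
            if ok:
                out.append(rec)
                placed[i] = True
                progressed = True
            else:
                next_round.append(i)
        if not progressed:
            cyc = ", ".join(pedigree.records[i].id for i in next_round[:5])
            raise PedigreeError(f"cycle detected in pedigree (involving {cyc})")
        remaining = next_round
    return Pedigree(out)


def find_mating_blocks(pedigree: Pedigree) -> list[MatingBlock]:
    """Partition an ordered pedigree into full-sib mating blocks.

    Records with both parents known are grouped by (dam_id, sire_id);
    records with any unknown parent become singleton blocks.  Together
    the blocks partition the record set.
    """
    blocks: dict[tuple[str, str], MatingBlock] = {}
    out: list[MatingBlock] = []
    for rec in pedigree:
        if rec.dam_id is not None and rec.sire_id is not None:
            key = (rec.dam_id, rec.sire_id)
            blk = blocks.get(key)
            if blk is None:
                blk = MatingBlock(rec.dam_id, rec.sire_id)
                blocks[key] = blk
                out.append(blk)
            blk.member_ids.append(rec.id)
        else:
            out.append(MatingBlock(rec.dam_id, rec.sire_id, [rec.id]))
    return out


_PED_COLUMNS = ["id", "category", "dam_id", "sire_id", "birth_year", "group_size"]


def read_pedigree_csv(path) -> Pedigree:
    """Read a pedigree from CSV.

    Expected columns: ``id,category,dam_id,sire_id,birth_year,group_size``
    with category in {Q, S, W} and empty string for unknown parents.
    """
    df = pd.read_csv(path, dtype={"id": str, "dam_id": str, "sire_id": str},
                     keep_default_na=False)
    missing = [c for c in _PED_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        try:
            cat = Category(row.category)
        except ValueError:
            raise PedigreeError(f"bad category token {row.category!r}") from None
        gs = float(row.group_size)
        records.append(
            IndividualRecord(
                id=str(row.id),
                category=cat,
                dam_id=str(row.dam_id) or None,
                sire_id=str(row.sire_id) or None,
                birth_year=int(row.birth_year),
                group_size=math.inf if cat is Category.WORKER_GROUP else gs,
            )
        )
    ped = Pedigree(records)
    _check_parent_links(ped)
    return ped


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    """Write a pedigree to CSV (inverse of :func:`read_pedigree_csv`)."""
    rows = []
    for r in pedigree:
        rows.append(
            {
                "id": r.id,
                "category": r.category.value,
                "dam_id": r.dam_id or "",
                "sire_id": r.sire_id or "",
                "birth_year": r.birth_year,
                "group_size": "inf" if math.isinf(r.group_size)
                else f"{r.group_size:g}",
            }
        )
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(path, index=False)


_PHEN_COLUMNS = ["colony_id", "queen_id", "worker_group_id", "year", "trait_value"]


def read_phenotype_csv(path) -> pd.DataFrame:
    """Read colony phenotypes.

    Required columns: ``colony_id,queen_id,worker_group_id,year,trait_value``;
    any further columns are treated as categorical fixed effects.
    """
    df = pd.read_csv(
        path,
        dtype={"colony_id": str, "queen_id": str, "worker_group_id": str},
        keep_default_na=False,
    )
    missing = [c for c in _PHEN_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"phenotype file missing columns: {missing}")
    df["year"] = df["year"].astype(int)
    df["trait_value"] = df["trait_value"].astype(float)
    return df


def write_phenotype_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
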