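"""Pedigree ingestion, validation, ordering and ancestry classification.

A pedigree is a directed acyclic graph of individuals with at most one sire
and one dam each.  Individuals are identified by opaque strings on disk and
by dense integer indices internally; all downstream matrices are
index-addressed, with index order equal to a topological (oldest-first)
order so that iterating ``range(n)`` always visits parents before their
offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

UNKNOWN = -1
#: The six relationship categories used to stratify imputation accuracy by
#: the pattern of high-density genotyped ancestors.
CATEGORIES = ("BothParents", "SireMGS", "DamPGS", "Sire", "Dam", "Other")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass
class Pedigree:
    """An ordered pedigree.

    Attributes
    ----------
    ids
        Individual identifiers in topological (oldest-first) order.
    sire, dam
        Integer index of each individual's sire/dam, ``UNKNOWN`` (-1) if
        the parent is not recorded.
    generation_rank
        0 for base animals, otherwise ``max(rank(parents)) + 1``.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    generation_rank: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {v: i for i, v in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        i = self.index[individual]
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    def is_base(self) -> np.ndarray:
        """Boolean mask of base animals (both parents unknown)."""
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def offspring_lists(self) -> list[list[int]]:
        """For each individual, the indices of its offspring."""
        out: list[list[int]] = [[] for _ in range(self.n)]
        for c in range(self.n):
            if self.sire[c] >= 0:
                out[self.sire[c]].append(c)
            if self.dam[c] >= 0 and self.dam[c] != self.sire[c]:
                out[self.dam[c]].append(c)
        return out

    def ancestor_matrix(self) -> np.ndarray:
        """Boolean matrix ``A[i, j]`` = j is i or an ancestor of i.

        Computed in one topological pass; O(n^2 / 8) memory.
        """
        n = self.n
        A = np.zeros((n, n), dtype=bool)
        for i in range(n):
            A[i, i] = True
            if self.sire[i] >= 0:
                A[i] |= A[self.sire[i]]
            if self.dam[i] >= 0:
                A[i] |= A[self.dam[i]]
        return A


def from_records(
    records: Iterable[tuple[str, str, str]], unknown: str = "0"
) -> Pedigree:
    """Build a validated, topologically ordered Pedigree from (id, sire, dam)
    triples.  Parents referenced but never listed are appended as base
    animals.  Raises :class:`PedigreeError` on duplicate ids or cycles.
    """
    rows = [(str(a), str(s), str(d)) for a, s, d in records]
    seen: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for ind, s, d in rows:
        if ind in seen:
            raise PedigreeError(f"duplicate individual id: {ind!r}")
        seen[ind] = (s, d)
        order.append(ind)
    # implicit founders
    for ind, (s, d) in list(seen.items()):
        for p in (s, d):
            if p != unknown and p not in seen:
                seen[p] = (unknown, unknown)
                order.append(p)

    # Kahn topological sort, deterministic (input order as tie-break)
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    n_pending = np.zeros(n, dtype=np.int32)
    children: list[list[int]] = [[] for _ in range(n)]
    for ind in order:
        i = idx[ind]
        s, d = seen[ind]
        for p in {s, d} - {unknown}:
            n_pending[i] += 1
            children[idx[p]].append(i)
    queue = [i for i in range(n) if n_pending[i] == 0]
    topo: list[int] = []
    head = 0
    while head < len(queue):
        i = queue[head]
        head += 1
        topo.append(i)
        for c in children[i]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                queue.append(c)
    if len(topo) != n:
        on_cycle = [order[i] for i in range(n) if n_pending[i] > 0]
        raise PedigreeError(
            f"pedigree contains a cycle through individual {on_cycle[0]!r}"
        )

    ids = [order[i] for i in topo]
    new_idx = {v: i for i, v in enumerate(ids)}
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    rank = np.zeros(n, dtype=np.int64)
    for i, ind in enumerate(ids):
        s, d = seen[ind]
        if s != unknown:
            sire[i] = new_idx[s]
        if d != unknown:
            dam[i] = new_idx[d]
        pr = [rank[p] for p in (sire[i], dam[i]) if p >= 0]
        rank[i] = max(pr) + 1 if pr else 0
    return Pedigree(ids=ids, sire=sire, dam=dam, generation_rank=rank, index=new_idx)


def load_pedigree(
    path: str | Path, unknown: str = "0", skip_header: bool = False
) -> Pedigree:
    """Read a whitespace-delimited pedigree file (id, sire, dam, ...).

    Extra columns are ignored.  ``unknown`` (default "0") marks a missing
    parent.
    """
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if skip_header and ln == 0:
                continue
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise PedigreeError(
                    f"{path}: line {ln + 1}: expected at least 3 columns"
                )
            records.append((parts[0], parts[1], parts[2]))
    return from_records(records, unknown=unknown)


def identify_base_animals(ped: Pedigree) -> set[str]:
    """All individuals with both parents unknown."""
    mask = ped.is_base()
    return {ped.ids[i] for i in np.nonzero(mask)[0]}


def classify_ancestry(
    ped: Pedigree, hd_set: set[str] | frozenset[str], individual: str
) -> str:
    """Classify an individual by which of its recent ancestors are
    high-density genotyped.

    The labels, in precedence order, are: BothParents (sire and dam HD),
    SireMGS (sire and maternal grandsire HD), DamPGS (dam and paternal
    grandsire HD), Sire, Dam, and Other.
    """
    if individual not in ped.index:
        raise KeyError(f"unknown individual: {individual!r}")
    i = ped.index[individual]

    def _id(j: int) -> str | None:
        return ped.ids[j] if j >= 0 else None

    s, d = ped.sire[i], ped.dam[i]
    sire_id, dam_id = _id(s), _id(d)
    pgs_id = _id(ped.sire[s]) if s >= 0 else None  # paternal grandsire
    mgs_id = _id(ped.sire[d]) if d >= 0 else None  # maternal grandsire
    sire_hd = sire_id in hd_set if sire_id else False
    dam_hd = dam_id in hd_set if dam_id else False
    pgs_hd = pgs_id in hd_set if pgs_id else False
    mgs_hd = mgs_id in hd_set if mgs_id else False
    if sire_hd and dam_hd:
        return "BothParents"
    if sire_hd and mgs_hd:
        return "SireMGS"
    if dam_hd and pgs_hd:
        return "DamPGS"
    if sire_hd:
        return "Sire"
    if dam_hd:
        return "Dam"
    return "Other"


def classify_all(ped: Pedigree, hd_set: set[str], individuals: Sequence[str]) -> list[str]:
    return [classify_ancestry(ped, hd_set, ind) for ind in individuals]
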