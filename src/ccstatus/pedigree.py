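"""Line pedigrees and obligate-ancestor determination.

A pedigree is the directed acyclic ancestry structure of one recombinant
inbred line: a set of parentless founders at the top (eight for a full
funnel), mixing crosses, and then brother-sister matings.  The central
query is the set of *obligate ancestor* mating pairs for a chosen set of
extant animals: matings (sire, dam) such that every extant animal descends
from both members and every ancestry path from any extant animal back to
the founders passes through one of the pair's offspring.  The genomes of
the most recent such pair bound everything that can still segregate in
the line, so they are the animals worth genotyping.

Funnel founders are never reported as obligate ancestors: they are
ancestors of everything by construction and carry no information about
residual heterozygosity.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Individual",
    "MatingPair",
    "Pedigree",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "descendants",
    "obligate_ancestor_pairs",
    "obligate_individuals",
    "most_recent_obligate_ancestors",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or bad queries."""


_SEX_ALIASES = {
    "male": "male",
    "m": "male",
    "female": "female",
    "f": "female",
}


def _norm_sex(raw: str) -> str:
    try:
        return _SEX_ALIASES[raw.strip().lower()]
    except KeyError:
        raise PedigreeError(f"unrecognized sex value {raw!r}") from None


@dataclass(frozen=True)
class Individual:
    """One animal: id, parents (both or neither), sex, generation, line."""

    id: str
    sire: str | None
    dam: str | None
    sex: str  # "male" | "female"
    generation: int
    line: str

    def __post_init__(self) -> None:
        if (self.sire is None) != (self.dam is None):
            raise PedigreeError(
                f"individual {self.id!r}: sire and dam must both be present "
                "or both absent"
            )
        if self.sex not in ("male", "female"):
            raise PedigreeError(f"individual {self.id!r}: bad sex {self.sex!r}")
        if self.generation < 0:
            raise PedigreeError(
                f"individual {self.id!r}: negative generation {self.generation}"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire is None


@dataclass(frozen=True, order=True)
class MatingPair:
    """A sire-dam mating with at least one recorded offspring."""

    generation: int
    sire_id: str = field(compare=True)
    dam_id: str = field(compare=True)


class Pedigree:
    """Validated ancestry graph for a single line.

    Parameters
    ----------
    individuals
        Iterable of :class:`Individual`.  Ids must be unique, every
        referenced parent must be present with the correct sex, and the
        ancestry graph must be acyclic.
    line_id
        Identifier of the line; defaults to the (unique) ``line`` value
        of the individuals.
    """

    def __init__(self, individuals: Iterable[Individual], line_id: str | None = None):
        self._by_id: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._by_id:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        if not self._by_id:
            raise PedigreeError("empty pedigree")
        if line_id is None:
            lines = {ind.line for ind in self._by_id.values()}
            line_id = sorted(lines)[0] if len(lines) == 1 else "+".join(sorted(lines))
        self.line_id = line_id
        self._children: dict[str, list[str]] = {i: [] for i in self._by_id}
        self._validate()

    def _validate(self) -> None:
        for ind in self._by_id.values():
            for parent_id, role, want_sex in (
                (ind.sire, "sire", "male"),
                (ind.dam, "dam", "female"),
            ):
                if parent_id is None:
                    continue
                parent = self._by_id.get(parent_id)
                if parent is None:
                    raise PedigreeError(
                        f"individual {ind.id!r} references missing {role} "
                        f"{parent_id!r}"
                    )
                if parent.sex != want_sex:
                    raise PedigreeError(
                        f"{role} {parent_id!r} of {ind.id!r} is not {want_sex}"
                    )
                self._children[parent_id].append(ind.id)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative DFS over child->parent edges with an explicit stack so a
        # cycle can be reported as the offending id chain
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._by_id}
        for root in self._by_id:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(root, 0)]
            chain: list[str] = []
            while stack:
                node, pi = stack[-1]
                if pi == 0:
                    color[node] = GRAY
                    chain.append(node)
                parents = [
                    p
                    for p in (self._by_id[node].sire, self._by_id[node].dam)
                    if p is not None
                ]
                if pi < len(parents):
                    stack[-1] = (node, pi + 1)
                    nxt = parents[pi]
                    if color[nxt] == GRAY:
                        cycle = chain[chain.index(nxt):] + [nxt]
                        raise PedigreeError(
                            "ancestry cycle detected: " + " -> ".join(cycle)
                        )
                    if color[nxt] == WHITE:
                        stack.append((nxt, 0))
                else:
                    color[node] = BLACK
                    chain.pop()
                    stack.pop()

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._by_id

    def __getitem__(self, animal_id: str) -> Individual:
        try:
            return self._by_id[animal_id]
        except KeyError:
            raise PedigreeError(f"unknown individual id {animal_id!r}") from None

    def __iter__(self):
        return iter(self._by_id.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pedigree):
            return NotImplemented
        return self.line_id == other.line_id and self._by_id == other._by_id

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def founders(self) -> list[Individual]:
        """Parentless individuals, i.e. the funnel founders."""
        return [ind for ind in self._by_id.values() if ind.is_founder]

    def children_of(self, animal_id: str) -> list[str]:
        self[animal_id]
        return list(self._children[animal_id])

    def max_generation(self) -> int:
        return max(ind.generation for ind in self._by_id.values())

    def matings(self) -> dict[tuple[str, str], list[str]]:
        """All (sire_id, dam_id) pairs with their recorded offspring."""
        out: dict[tuple[str, str], list[str]] = {}
        for ind in self._by_id.values():
            if ind.sire is not None:
                out.setdefault((ind.sire, ind.dam), []).append(ind.id)
        return out

    def sex_of(self, animal_id: str) -> str:
        return self[animal_id].sex


# -- file dialect --------------------------------------------------------

_HEADER = ["id", "sire", "dam", "sex", "generation", "line"]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (``id,sire,dam,sex,generation,line``).

    Empty sire/dam fields mean no parent (founder).  All structural
    invariants are checked; violations raise :class:`PedigreeError`.
    """
    path = Path(path)
    individuals = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _HEADER:
            raise PedigreeError(
                f"{path}: expected header {','.join(_HEADER)!r}, "
                f"got {reader.fieldnames!r}"
            )
        for row in reader:
            individuals.append(
                Individual(
                    id=row["id"].strip(),
                    sire=row["sire"].strip() or None,
                    dam=row["dam"].strip() or None,
                    sex=_norm_sex(row["sex"]),
                    generation=int(row["generation"]),
                    line=row["line"].strip(),
                )
            )
    return Pedigree(individuals)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    """Write a pedigree in the CSV dialect accepted by :func:`read_pedigree`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for ind in pedigree:
            writer.writerow(
                [ind.id, ind.sire or "", ind.dam or "", ind.sex, ind.generation, ind.line]
            )


# -- queries -------------------------------------------------------------


def descendants(pedigree: Pedigree, ids: set[str]) -> set[str]:
    """All individuals reachable from ``ids`` via parent->child edges.

    The query ids themselves are excluded.
    """
    for i in ids:
        pedigree[i]
    seen: set[str] = set()
    frontier = list(ids)
    while frontier:
        node = frontier.pop()
        for child in pedigree.children_of(node):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen - set(ids)


def _check_extant(pedigree: Pedigree, extant: set[str]) -> None:
    if not extant:
        raise PedigreeError("extant set is empty")
    lines = {pedigree[i].line for i in extant}
    if len(lines) > 1:
        raise PedigreeError(
            f"extant animals span multiple lines: {sorted(lines)}"
        )


def _covered_by_cut(pedigree: Pedigree, extant: set[str], cut: set[str]) -> bool:
    """True iff every ancestry path from extant to a founder meets ``cut``."""
    blocked = set(cut)
    seen: set[str] = set()
    frontier = [e for e in extant if e not in blocked]
    while frontier:
        node = frontier.pop()
        ind = pedigree[node]
        if ind.is_founder:
            return False
        for parent in (ind.sire, ind.dam):
            if parent in blocked or parent in seen:
                continue
            seen.add(parent)
            frontier.append(parent)
    return True


def obligate_ancestor_pairs(pedigree: Pedigree, extant: set[str]) -> list[MatingPair]:
    """Every mating through which all ancestry of ``extant`` must pass.

    A mating (sire, dam) qualifies when every extant animal is a
    descendant of both members and removing the mating's offspring
    disconnects the extant set from the founders.  Matings involving a
    funnel founder are excluded.  Pairs are returned ordered by
    generation ascending (ties by sire then dam id).
    """
    extant = set(extant)
    _check_extant(pedigree, extant)
    result = []
    for (sire_id, dam_id), offspring in pedigree.matings().items():
        sire = pedigree[sire_id]
        dam = pedigree[dam_id]
        if sire.is_founder or dam.is_founder:
            continue
        desc_sire = descendants(pedigree, {sire_id})
        desc_dam = descendants(pedigree, {dam_id})
        if not extant <= desc_sire or not extant <= desc_dam:
            continue
        if _covered_by_cut(pedigree, extant, set(offspring)):
            result.append(
                MatingPair(
                    generation=max(sire.generation, dam.generation),
                    sire_id=sire_id,
                    dam_id=dam_id,
                )
            )
    return sorted(result)


def obligate_individuals(pedigree: Pedigree, extant: set[str]) -> list[str]:
    """Single non-founder individuals through which all ancestry passes.

    Informational only: line classification uses mating pairs, whose four
    haplotypes bound the line genome.
    """
    extant = set(extant)
    _check_extant(pedigree, extant)
    out = []
    for ind in pedigree:
        if ind.is_founder:
            continue
        desc = descendants(pedigree, {ind.id})
        if not extant <= (desc | {ind.id}):
            continue
        if _covered_by_cut(pedigree, extant, {ind.id}):
            out.append(ind.id)
    return sorted(out, key=lambda i: (pedigree[i].generation, i))


def most_recent_obligate_ancestors(pedigree: Pedigree, extant: set[str]) -> MatingPair:
    """The obligate ancestor pair of maximal generation.

    Ties are broken toward the lexicographically smallest (sire, dam)
    ids and reported as a warning.
    """
    pairs = obligate_ancestor_pairs(pedigree, extant)
    if not pairs:
        raise PedigreeError(
            "no obligate ancestor pair exists for the given extant set "
            "(does it include a funnel founder?)"
        )
    top_gen = pairs[-1].generation
    tied = [p for p in pairs if p.generation == top_gen]
    if len(tied) > 1:
        warnings.warn(
            f"{len(tied)} obligate pairs tie at generation {top_gen}; "
            "breaking tie lexicographically",
            stacklevel=2,
        )
    return min(tied, key=lambda p: (p.sire_id, p.dam_id))
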