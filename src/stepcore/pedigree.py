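"""Pedigrees and pedigree-based additive relationship matrices.

A pedigree is a directed acyclic parent->offspring structure with
unknown-parent support.  The additive (numerator) relationship matrix is
computed by the tabular recursion; the directional ancestor matrix and
the per-genotype completeness score are derived from it.
"""

from __future__ import annotations

import csv
import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .matrix import RelationshipMatrix

#: Accepted encodings of an unknown parent in input records.
UNKNOWN_SENTINELS = {"", "0", "na", "nan", "none", "-", "unknown"}


def _normalize_parent(value) -> str | None:
    if value is None:
        return None
    value = str(value).strip()
    return None if value.lower() in UNKNOWN_SENTINELS else value


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Canonically ordered pedigree: every parent precedes its offspring.

    ``mother_of``/``father_of`` are partial maps; absence means unknown.
    """

    individuals: list[str]
    mother_of: dict[str, str]
    father_of: dict[str, str]
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = {ind: k for k, ind in enumerate(self.individuals)}
        if len(pos) != len(self.individuals):
            raise PedigreeError("duplicate individuals in pedigree")
        for child, parent in list(self.mother_of.items()) + list(self.father_of.items()):
            if parent not in pos:
                raise PedigreeError(f"parent {parent!r} of {child!r} not an individual")
            if pos[parent] >= pos[child]:
                raise PedigreeError(f"parent {parent!r} does not precede {child!r}")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.mother_of.get(ind), self.father_of.get(ind)

    def is_founder(self, ind: str) -> bool:
        return ind not in self.mother_of and ind not in self.father_of

    def founders(self) -> list[str]:
        return [i for i in self.individuals if self.is_founder(i)]

    def ancestors(self, ind: str) -> set[str]:
        """All individuals reachable from ``ind`` through parent links."""
        out: set[str] = set()
        stack = [p for p in self.parents(ind) if p is not None]
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(q for q in self.parents(p) if q is not None)
        return out

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            has_groups = bool(self.group_of)
            writer.writerow(["id", "mother", "father"] + (["group"] if has_groups else []))
            for ind in self.individuals:
                row = [ind, self.mother_of.get(ind, ""), self.father_of.get(ind, "")]
                if has_groups:
                    row.append(self.group_of.get(ind, ""))
                writer.writerow(row)


def build_pedigree(records, groups: dict[str, str] | None = None) -> Pedigree:
    """Build a canonically ordered :class:`Pedigree` from raw records.

    Parameters
    ----------
    records
        Iterable of ``(individual, mother, father)`` triples.  Unknown
        parents are encoded by an empty field or ``"0"`` (and a few
        other common sentinels, see :data:`UNKNOWN_SENTINELS`).
    groups
        Optional free-form group label per individual.

    Parents that are named but never listed as individuals are appended
    as founders.  Duplicate rows with conflicting parents and
    parent-offspring cycles raise :class:`PedigreeError`.
    """
    mother_of: dict[str, str] = {}
    father_of: dict[str, str] = {}
    order: list[str] = []
    seen: dict[str, tuple[str | None, str | None]] = {}

    for rec in records:
        ind, mother, father = str(rec[0]).strip(), rec[1], rec[2]
        if not ind or ind.lower() in UNKNOWN_SENTINELS:
            raise PedigreeError(f"invalid individual identifier {rec[0]!r}")
        mother = _normalize_parent(mother)
        father = _normalize_parent(father)
        if ind in seen:
            if seen[ind] != (mother, father):
                raise PedigreeError(
                    f"conflicting parent records for individual {ind!r}: "
                    f"{seen[ind]} vs {(mother, father)}"
                )
            continue
        seen[ind] = (mother, father)
        order.append(ind)
        if mother is not None:
            mother_of[ind] = mother
        if father is not None:
            father_of[ind] = father
        if ind in (mother, father):
            raise PedigreeError(f"individual {ind!r} is its own parent")

    # register parents that never appear as individuals as founders
    for parent in list(mother_of.values()) + list(father_of.values()):
        if parent not in seen:
            seen[parent] = (None, None)
            order.append(parent)

    ordered = _topological_order(order, mother_of, father_of)
    group_of = {}
    if groups:
        group_of = {str(k): str(v) for k, v in groups.items() if str(k) in seen}
    return Pedigree(ordered, mother_of, father_of, group_of)


def _topological_order(order, mother_of, father_of) -> list[str]:
    """Topological sort (parents first), ties broken by input order."""
    pos = {ind: k for k, ind in enumerate(order)}
    children: dict[str, list[str]] = {ind: [] for ind in order}
    n_parents = {ind: 0 for ind in order}
    for child, parent in list(mother_of.items()) + list(father_of.items()):
        children[parent].append(child)
        n_parents[child] += 1

    ready = [pos[i] for i in order if n_parents[i] == 0]
    heapq.heapify(ready)
    out: list[str] = []
    remaining = dict(n_parents)
    while ready:
        ind = order[heapq.heappop(ready)]
        out.append(ind)
        for child in children[ind]:
            remaining[child] -= 1
            if remaining[child] == 0:
                heapq.heappush(ready, pos[child])
    if len(out) < len(order):
        cycle = _find_cycle(
            [i for i in order if i not in set(out)], mother_of, father_of
        )
        raise PedigreeError(
            "parent-offspring cycle detected: " + " -> ".join(cycle)
        )
    return out


def _find_cycle(candidates, mother_of, father_of) -> list[str]:
    cand = set(candidates)
    node = candidates[0]
    path, where = [], {}
    while node not in where:
        where[node] = len(path)
        path.append(node)
        node = next(
            p for p in (mother_of.get(node), father_of.get(node)) if p in cand
        )
    return path[where[node]:] + [node]


def read_pedigree_csv(path: str | Path) -> Pedigree:
    """Read a header CSV ``id,mother,father[,group]`` (unknown = empty or 0)."""
    records, groups = [], {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "mother", "father"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise PedigreeError(f"{path}: expected header columns id,mother,father")
        for row in reader:
            records.append((row["id"], row["mother"], row["father"]))
            if row.get("group"):
                groups[row["id"]] = row["group"]
    return build_pedigree(records, groups or None)


def amatrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular recursion.

    Founders are unrelated and non-inbred.  For individual ``i`` with
    parents ``s``, ``d`` (unknown contributes zero)::

        a(i, j) = 0.5 * (a(j, s) + a(j, d))   for j before i
        a(i, i) = 1 + 0.5 * a(s, d)

    The diagonal is ``1 + F`` with ``F`` the inbreeding coefficient.
    """
    n = ped.n
    pos = {ind: k for k, ind in enumerate(ped.individuals)}
    a = np.zeros((n, n))
    for i, ind in enumerate(ped.individuals):
        mother, father = ped.parents(ind)
        mi = pos[mother] if mother is not None else None
        fi = pos[father] if father is not None else None
        row = np.zeros(i)
        if mi is not None:
            row += 0.5 * a[mi, :i]
        if fi is not None:
            row += 0.5 * a[fi, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[mi, fi] if mi is not None and fi is not None else 0.0)
    return RelationshipMatrix(list(ped.individuals), a, "A")


def ancestor_matrix(ped: Pedigree, A: RelationshipMatrix) -> RelationshipMatrix:
    """Directional matrix keeping only relationships to one's own ancestors.

    Row ``i`` retains ``A(i, j)`` when ``j`` is an ancestor of ``i``
    (any depth through parent links); everything else, including the
    diagonal, is zeroed.
    """
    if list(A.ids) != list(ped.individuals):
        raise ValueError("pedigree and A matrix ids differ")
    pos = {ind: k for k, ind in enumerate(ped.individuals)}
    out = np.zeros_like(A.values)
    for i, ind in enumerate(ped.individuals):
        anc = ped.ancestors(ind)
        if anc:
            idx = [pos[a] for a in anc]
            out[i, idx] = A.values[i, idx]
    return RelationshipMatrix(list(ped.individuals), out, "Astar")


def completeness(ped: Pedigree, A: RelationshipMatrix | None = None) -> dict[str, float]:
    """Pedigree completeness: sum of relationships to recorded ancestors.

    In a non-inbred, fully recorded pedigree this equals 1 per known
    ancestral generation (2 x 0.5 for parents, 4 x 0.25 for
    grandparents, ...); founders score 0.
    """
    if A is None:
        A = amatrix(ped)
    astar = ancestor_matrix(ped, A)
    sums = astar.values.sum(axis=1)
    return {ind: float(s) for ind, s in zip(ped.individuals, sums)}
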