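"""Stepwise core-collection selection.

Mandatory entries come from breeder rules (recent crossing-parent
frequency, trait "must-haves", previously sequenced genotypes); the
remaining slots minimize the accession-to-nearest-entry criterion
(A-NE): the mean, over the whole collection, of each genotype's
distance to its closest core entry.  The optimizer is a seeded
best-improvement swap descent with random restarts; because single runs
are stochastic, a multi-run consensus picks the most frequently
selected candidates, with documented tie-breaking.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .matrix import RelationshipMatrix


class SelectionError(ValueError):
    pass


class CrossingRecord(NamedTuple):
    mother: str
    father: str
    year: int


def read_crossings_csv(path: str | Path) -> list[CrossingRecord]:
    """Read a header CSV ``mother,father,year``."""
    out = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(CrossingRecord(row["mother"].strip(), row["father"].strip(),
                                      int(row["year"])))
    return out


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def select_recent_parents(crossings: Sequence[CrossingRecord], min_uses: int = 4,
                          window_years: int = 3, reference_year: int | None = None,
                          ) -> set[str]:
    """Parents used at least ``min_uses`` times in the last ``window_years`` years.

    Each crossing contributes one use to its mother and one to its
    father (a self-cross therefore counts twice).  The window is the
    ``window_years`` calendar years ending at ``reference_year``.
    """
    if reference_year is None:
        raise SelectionError("reference_year is required")
    if min_uses < 1:
        raise SelectionError("min_uses must be >= 1")
    if not crossings:
        warnings.warn("empty crossing list; no recent parents selected")
        return set()
    first_year = reference_year - window_years + 1
    counts: dict[str, int] = {}
    for rec in crossings:
        if first_year <= rec.year <= reference_year:
            counts[rec.mother] = counts.get(rec.mother, 0) + 1
            counts[rec.father] = counts.get(rec.father, 0) + 1
    return {p for p, c in counts.items() if c >= min_uses}


def ane(D: RelationshipMatrix, core, collection) -> float:
    """Accession-to-nearest-entry criterion.

    Mean, over every genotype in ``collection``, of its minimum
    distance to any entry in ``core``.  Core entries contribute 0
    (their nearest entry is themselves).
    """
    core = list(core)
    if not core:
        raise SelectionError("core is empty")
    coll = list(collection)
    if not set(core) <= set(coll):
        raise SelectionError("core must be a subset of the collection")
    sub = D.values[np.ix_(D.indices(coll), D.indices(core))]
    mins = sub.min(axis=1)
    # entries themselves are at distance D(i,i)=0 from the core
    return float(mins.mean())


@dataclass
class SearchParams:
    """Stopping/restart knobs for :func:`optimize_core`."""

    restarts: int = 10
    max_sweeps: int = 200  # best-improvement sweeps per restart


@dataclass
class CoreSelection:
    fixed: list[str]
    free: list[str]
    criterion: float
    frequencies: dict[str, float] = field(default_factory=dict)
    always_selected: int | None = None
    seeds: list[int] = field(default_factory=list)

    @property
    def entries(self) -> list[str]:
        return list(self.fixed) + list(self.free)

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed,
            "free": self.free,
            "criterion": self.criterion,
            "frequencies": self.frequencies,
            "always_selected": self.always_selected,
            "seeds": [int(s) for s in self.seeds],
        }


def optimize_core(D: RelationshipMatrix, size: int, fixed=(), collection=None,
                  seed: int = 0, search: SearchParams | None = None,
                  _init_free=None) -> CoreSelection:
    """Single seeded run of the A-NE minimizer.

    Free slots are filled at random, then improved by best-improvement
    swap moves (one free entry against one non-entry) until no swap
    improves the criterion, with random restarts keeping the best run.
    Fixed entries are never swapped out.
    """
    search = search or SearchParams()
    if search.restarts < 1 or search.max_sweeps < 1:
        raise SelectionError("search budget must be positive")
    fixed = [str(g) for g in fixed]
    coll = [str(g) for g in (collection if collection is not None else D.ids)]
    if not set(fixed) <= set(coll):
        raise SelectionError("fixed entries must belong to the collection")
    if size < len(fixed):
        raise SelectionError(f"size {size} < {len(fixed)} fixed entries")
    if size > len(coll):
        raise SelectionError(f"size {size} > collection of {len(coll)}")

    cidx = D.indices(coll)
    sub = D.values[np.ix_(cidx, cidx)]  # collection-local distances
    pos = {g: k for k, g in enumerate(coll)}
    fixed_idx = np.array(sorted(pos[g] for g in fixed), dtype=int)
    candidates = np.array(
        sorted(k for k in range(len(coll)) if coll[k] not in set(fixed)), dtype=int
    )
    n_free = size - len(fixed)

    rng = np.random.default_rng(seed)
    best_free, best_val = None, np.inf
    for restart in range(search.restarts):
        if restart == 0 and _init_free is not None:
            free = np.array(sorted(pos[g] for g in _init_free), dtype=int)
        elif n_free:
            free = rng.choice(candidates, size=n_free, replace=False)
        else:
            free = np.array([], dtype=int)
        free, val = _swap_descent(sub, fixed_idx, free, candidates,
                                  search.max_sweeps)
        if val < best_val - 1e-15:
            best_val, best_free = val, free
    free_ids = sorted(coll[k] for k in best_free)
    result = CoreSelection(fixed=sorted(fixed), free=free_ids,
                           criterion=float(best_val), seeds=[int(seed)])
    return result


def _swap_descent(sub, fixed_idx, free, candidates, max_sweeps):
    """Best-improvement swap descent on the collection-local distance matrix."""
    core = np.concatenate([fixed_idx, free]).astype(int)
    n = sub.shape[0]
    if core.size == 0:
        raise SelectionError("core is empty")
    val = sub[:, core].min(axis=1).mean()
    free = list(free)
    in_core = np.zeros(n, dtype=bool)
    in_core[core] = True
    for _ in range(max_sweeps):
        best = (0.0, None, None)
        outside = candidates[~in_core[candidates]]
        for fi, f in enumerate(free):
            others = np.array([x for x in np.concatenate([fixed_idx, free]) if x != f],
                              dtype=int)
            if others.size:
                base = sub[:, others].min(axis=1)
            else:
                base = np.full(n, np.inf)
            for c in outside:
                new_val = np.minimum(base, sub[:, c]).mean()
                gain = val - new_val
                if gain > best[0] + 1e-15:
                    best = (gain, fi, c)
        if best[1] is None:
            break
        _, fi, c = best
        in_core[free[fi]] = False
        in_core[c] = True
        free[fi] = c
        core = np.concatenate([fixed_idx, free]).astype(int)
        val = sub[:, core].min(axis=1).mean()
    return np.array(sorted(free), dtype=int), float(val)


def consensus_core(D: RelationshipMatrix, size: int, fixed=(), collection=None,
                   n_iter: int = 3000, base_seed: int = 0,
                   preference: Sequence[str] | None = None,
                   search: SearchParams | None = None,
                   tie_tol: float = 0.15) -> CoreSelection:
    """Multi-run consensus over ``n_iter`` seeded optimizer runs.

    Per-candidate selection frequency is the fraction of runs in which
    the candidate occupied a free slot.  The final free set takes the
    top-frequency candidates.  Candidates whose frequencies are within
    ``tie_tol`` of each other (chained into maximal groups) count as
    interchangeable alternatives for a slot: within such a group the
    breeder ``preference`` order decides first, then raw frequency,
    then lexicographic id — so a near-50/50 split defers to preference
    while a clear majority wins regardless.  ``always_selected``
    reports how many chosen free entries had frequency 1.0.
    """
    if n_iter < 1:
        raise SelectionError("n_iter must be >= 1")
    fixed = [str(g) for g in fixed]
    coll = [str(g) for g in (collection if collection is not None else D.ids)]
    n_free = size - len(fixed)
    counts: dict[str, int] = {}
    seeds = list(range(int(base_seed), int(base_seed) + n_iter))
    for s in seeds:
        run = optimize_core(D, size, fixed, coll, seed=s, search=search)
        for g in run.free:
            counts[g] = counts.get(g, 0) + 1
    freqs = {g: c / n_iter for g, c in counts.items()}

    pref_rank = {g: k for k, g in enumerate(preference)} if preference else {}
    by_freq = sorted(freqs, key=lambda g: (-freqs[g], g))
    ranked: list[str] = []
    k = 0
    while k < len(by_freq):
        group = [by_freq[k]]
        while (k + len(group) < len(by_freq)
               and freqs[group[-1]] - freqs[by_freq[k + len(group)]] <= tie_tol):
            group.append(by_freq[k + len(group)])
        group.sort(key=lambda g: (pref_rank.get(g, len(pref_rank)),
                                  -freqs[g], g))
        ranked.extend(group)
        k += len(group)
    free = sorted(ranked[:n_free])
    crit = ane(D, set(free) | set(fixed), coll) if (free or fixed) else 0.0
    always = sum(1 for g in free if counts.get(g, 0) == n_iter)
    return CoreSelection(fixed=sorted(fixed), free=free, criterion=float(crit),
                         frequencies=freqs, always_selected=always, seeds=seeds)


def ane_curve(D: RelationshipMatrix, sizes: Sequence[int], fixed=(),
              collection=None, seed: int = 0, random_reps: int = 20,
              search: SearchParams | None = None) -> list[tuple[int, float, float]]:
    """Optimized and random-baseline A-NE for a range of core sizes.

    The optimized series is non-increasing in size: each size's search
    is warm-started from the previous best core plus a greedy addition.
    The baseline draws the free slots uniformly, averaged over
    ``random_reps`` seeded replicates.
    """
    fixed = [str(g) for g in fixed]
    coll = [str(g) for g in (collection if collection is not None else D.ids)]
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[0] < max(len(fixed), 1):
        raise SelectionError("sizes must be >= number of fixed entries (and >= 1)")
    rng = np.random.default_rng(seed)
    out: list[tuple[int, float, float]] = []
    prev_free: list[str] | None = None
    others = [g for g in coll if g not in set(fixed)]
    for size in sizes:
        init = None
        if prev_free is not None:
            init = _greedy_extend(D, prev_free, fixed, coll, size - len(fixed))
        run = optimize_core(D, size, fixed, coll, seed=int(rng.integers(2**31)),
                            search=search, _init_free=init)
        prev_free = run.free
        rand_vals = []
        for _ in range(random_reps):
            pick = list(rng.choice(others, size=size - len(fixed), replace=False))
            rand_vals.append(ane(D, set(pick) | set(fixed), coll))
        out.append((size, run.criterion, float(np.mean(rand_vals))))
    return out


def _greedy_extend(D, free, fixed, coll, n_free):
    """Extend a free set greedily (or truncate) to exactly n_free entries."""
    free = list(free)[:n_free]
    chosen = set(free) | set(fixed)
    while len(free) < n_free:
        remaining = [g for g in coll if g not in chosen]
        best = min(remaining, key=lambda g: ane(D, chosen | {g}, coll))
        free.append(best)
        chosen.add(best)
    return free
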