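"""Breeding-program-like synthetic fixtures and the realized-IBD oracle.

Simulates multi-generation pedigrees over weakly connected
sub-populations, drops uniquely labeled founder alleles through the
pedigree (gene dropping) so realized identity-by-descent is known
exactly, and degrades the outputs (missing pedigree links, missing
dosage calls, sample swaps) the way real breeding records are degraded.
Loci are unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import DosageMatrix
from .pedigree import Pedigree, build_pedigree


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Knobs for the pedigree/genotype simulator.  ``seed`` is mandatory."""

    seed: int
    n_subpops: int = 3
    n_founders: int = 8  # per sub-population
    generations: int = 4
    crosses_per_generation: int = 6  # per sub-population
    offspring_per_cross: int = 2
    migration_rate: float = 0.05  # chance a cross takes one parent elsewhere
    n_markers: int = 1000
    freq_range: tuple[float, float] = (0.05, 0.5)  # founder allele frequencies
    fraction_genotyped: float = 1.0
    link_missing_rate: float = 0.0  # per parent link, in the observed pedigree
    n_swaps: int = 0
    missing_rate: float = 0.0  # dosage-level missingness

    def __post_init__(self) -> None:
        for name in ("migration_rate", "fraction_genotyped",
                     "link_missing_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_subpops", "n_founders", "offspring_per_cross",
                     "crosses_per_generation"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.generations < 0 or self.n_markers < 0 or self.n_swaps < 0:
            raise SimulationError("counts must be non-negative")
        if not 0 < self.freq_range[0] <= self.freq_range[1] < 1:
            raise SimulationError("freq_range must satisfy 0 < low <= high < 1")


def simulate_pedigree(cfg: SimConfig) -> tuple[Pedigree, Pedigree]:
    """Simulate a pedigree; returns ``(true, observed)``.

    Founders are unrelated.  Each generation draws crosses within each
    sub-population, except that with probability ``migration_rate`` one
    parent comes from another sub-population.  The observed pedigree is
    the true pedigree with each parent link independently deleted at
    ``link_missing_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[tuple[str, str, str]] = []
    groups: dict[str, str] = {}
    pools: list[list[str]] = []  # current parent pool per subpop
    for sp in range(cfg.n_subpops):
        pool = []
        for f in range(cfg.n_founders):
            name = f"P{sp}_F{f}"
            records.append((name, "", ""))
            groups[name] = f"pop{sp}"
            pool.append(name)
        pools.append(pool)

    for gen in range(1, cfg.generations + 1):
        new_pools: list[list[str]] = [[] for _ in range(cfg.n_subpops)]
        for sp in range(cfg.n_subpops):
            for cross in range(cfg.crosses_per_generation):
                mother = pools[sp][rng.integers(len(pools[sp]))]
                father_pool = sp
                if cfg.n_subpops > 1 and rng.random() < cfg.migration_rate:
                    father_pool = int(rng.choice(
                        [k for k in range(cfg.n_subpops) if k != sp]
                    ))
                father = pools[father_pool][rng.integers(len(pools[father_pool]))]
                if father == mother and len(pools[sp]) > 1:
                    father = next(p for p in pools[sp] if p != mother)
                for off in range(cfg.offspring_per_cross):
                    name = f"P{sp}_G{gen}_C{cross}_{off}"
                    records.append((name, mother, father))
                    groups[name] = f"pop{sp}"
                    new_pools[sp].append(name)
        pools = new_pools

    true_ped = build_pedigree(records, groups)
    obs_records = []
    for ind in true_ped.individuals:
        mother, father = true_ped.parents(ind)
        if mother is not None and rng.random() < cfg.link_missing_rate:
            mother = None
        if father is not None and rng.random() < cfg.link_missing_rate:
            father = None
        obs_records.append((ind, mother or "", father or ""))
    observed = build_pedigree(obs_records, groups)
    return true_ped, observed


@dataclass
class GeneDropResult:
    """Gene-dropped genotypes with exact realized IBD.

    ``allele_labels`` has shape (individuals, loci, 2) and holds
    founder-allele identities; ``dosages`` counts "1"-state alleles.
    ``realized_ibd[i, j]`` is the per-locus mean of half the number of
    label matches among the four allele pairings; ``ibd_se`` is its
    Monte-Carlo standard error over loci.
    """

    pedigree: Pedigree
    dosages: DosageMatrix
    allele_labels: np.ndarray
    founder_freqs: np.ndarray
    realized_ibd: np.ndarray | None = None
    ibd_se: np.ndarray | None = None


def gene_drop(ped: Pedigree, n_markers: int, freq_range=(0.05, 0.5),
              seed: int = 0, compute_ibd: bool = True) -> GeneDropResult:
    """Drop uniquely labeled founder alleles through the pedigree.

    Every founder allele copy gets a unique label; its allelic state at
    each locus is Bernoulli with the locus's founder frequency (drawn
    uniformly from ``freq_range``).  Each non-founder inherits one
    uniformly random allele per parent per locus, independently across
    loci.  An unknown parent contributes a fresh founder allele.
    """
    rng = np.random.default_rng(seed)
    n, L = ped.n, int(n_markers)
    pos = {ind: k for k, ind in enumerate(ped.individuals)}

    n_slots = sum(
        (ped.mother_of.get(i) is None) + (ped.father_of.get(i) is None)
        for i in ped.individuals
    )
    freqs = rng.uniform(*freq_range, size=L)
    states = (rng.random((n_slots, L)) < freqs).astype(np.int8)

    labels = np.zeros((n, L, 2), dtype=np.int32)
    next_label = 0
    for i, ind in enumerate(ped.individuals):
        for side, parent in enumerate(ped.parents(ind)):
            if parent is None:
                labels[i, :, side] = next_label
                next_label += 1
            else:
                p = pos[parent]
                choice = rng.integers(2, size=L)
                labels[i, :, side] = labels[p, np.arange(L), choice]
    assert next_label == n_slots

    dosages = states[labels[:, :, 0], np.arange(L)] + states[labels[:, :, 1], np.arange(L)]
    d = DosageMatrix(list(ped.individuals), [f"m{k}" for k in range(L)],
                     dosages.astype(float))
    ibd = se = None
    if compute_ibd:
        ibd, se = _realized_ibd(labels)
    return GeneDropResult(ped, d, labels, freqs, ibd, se)


def _realized_ibd(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, L, _ = labels.shape
    ibd = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        a1, a2 = labels[i, :, 0], labels[i, :, 1]
        for j in range(i, n):
            b1, b2 = labels[j, :, 0], labels[j, :, 1]
            per_locus = 0.5 * (
                (a1 == b1).astype(float) + (a1 == b2) + (a2 == b1) + (a2 == b2)
            )
            m = per_locus.mean()
            ibd[i, j] = ibd[j, i] = m
            se[i, j] = se[j, i] = per_locus.std(ddof=1) / np.sqrt(L)
    return ibd, se


def degrade(d: DosageMatrix, missing_rate: float = 0.0, n_swaps: int = 0,
            seed: int = 0, pairs=None) -> tuple[DosageMatrix, list[tuple[str, str]]]:
    """Degrade a dosage matrix: random missing cells plus sample swaps.

    ``n_swaps`` genotype-row pairs are exchanged (labels keep their
    place, data moves — the classic sample swap); the returned ledger
    lists the swapped id pairs.  Explicit ``pairs`` override the random
    choice.
    """
    if not 0 <= missing_rate <= 1:
        raise SimulationError(f"missing_rate must be in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    out = d.dosages.copy()
    n = d.n_genotypes
    if pairs is None:
        if n_swaps > n // 2:
            raise SimulationError(f"n_swaps {n_swaps} > floor(n/2) = {n // 2}")
        chosen = rng.choice(n, size=2 * n_swaps, replace=False)
        pairs_idx = [(int(chosen[2 * k]), int(chosen[2 * k + 1]))
                     for k in range(n_swaps)]
    else:
        gidx = {g: k for k, g in enumerate(d.genotype_ids)}
        pairs_idx = [(gidx[str(a)], gidx[str(b)]) for a, b in pairs]
        if len({k for p in pairs_idx for k in p}) != 2 * len(pairs_idx):
            raise SimulationError("swap pairs must be disjoint")
    ledger = []
    for i, j in pairs_idx:
        out[[i, j], :] = out[[j, i], :]
        ledger.append((d.genotype_ids[i], d.genotype_ids[j]))
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out[mask] = np.nan
    return (
        DosageMatrix(list(d.genotype_ids), list(d.marker_ids), out,
                     d.marker_meta, d.imputed),
        ledger,
    )


@dataclass
class SwapScenario:
    """Default sample-swap fixture for outlier-recovery diagnostics."""

    pedigree: Pedigree
    genotyped: list[str]
    dosages: DosageMatrix  # degraded (swapped) dosages of the genotyped set
    swapped_ids: set[str]
    ledger: list[tuple[str, str]] = field(default_factory=list)


def swap_scenario(seed: int = 0, n_swaps: int = 5, n_markers: int = 1200,
                  generations: int = 6) -> SwapScenario:
    """Build the default swap-recovery fixture.

    A deep multi-sub-population pedigree is simulated with complete
    records (so late-generation completeness exceeds the outlier
    threshold), the last two generations are genotyped by gene drop,
    and ``n_swaps`` cross-sub-population pairs from the final
    generation are swapped.
    """
    cfg = SimConfig(seed=seed, n_subpops=3, n_founders=6,
                    generations=generations, crosses_per_generation=4,
                    offspring_per_cross=2, migration_rate=0.03,
                    n_markers=n_markers)
    ped, _ = simulate_pedigree(cfg)
    drop = gene_drop(ped, n_markers, cfg.freq_range, seed=seed + 1,
                     compute_ibd=False)

    last_two = [i for i in ped.individuals
                if f"_G{generations}_" in i or f"_G{generations - 1}_" in i]
    final_gen = [i for i in ped.individuals if f"_G{generations}_" in i]
    rng = np.random.default_rng(seed + 2)
    by_pop: dict[str, list[str]] = {}
    for ind in final_gen:
        by_pop.setdefault(ped.group_of[ind], []).append(ind)
    pops = sorted(by_pop)
    pairs = []
    used: set[str] = set()
    for k in range(n_swaps):
        pa, pb = pops[k % len(pops)], pops[(k + 1) % len(pops)]
        a = next(x for x in rng.permutation(by_pop[pa]) if x not in used)
        b = next(x for x in rng.permutation(by_pop[pb]) if x not in used)
        used.update((a, b))
        pairs.append((a, b))

    geno = drop.dosages.select_genotypes(last_two)
    degraded, ledger = degrade(geno, n_swaps=len(pairs), seed=seed + 3, pairs=pairs)
    swapped = {g for pair in ledger for g in pair}
    return SwapScenario(ped, last_two, degraded, swapped, ledger)
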