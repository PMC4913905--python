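"""Forward-in-time haploid random-mating simulator.

Simulates a population of haploid individuals on a single chromosome,
started from a biparental cross of two completely divergent founder
lines and evolved by random mating at constant size with discrete,
non-overlapping generations.  Recombination follows Haldane's model
(crossovers form a Poisson process of rate 1 per Morgan, no
interference); there is no mutation and no selection.  This mimics
evolving recombinant-inbred-line / doubled-haploid material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneticMap",
    "HaploidPopulation",
    "make_founders",
    "meiosis",
    "evolve",
    "make_full_sibs",
    "filter_markers",
    "branch_tst",
]


@dataclass(frozen=True)
class GeneticMap:
    """Locus positions (Morgans) on one chromosome.

    ``chrom_length`` is the total genome length L and ``avg_chrom_length``
    the average chromosome length l; both equal 1 for the single
    1-Morgan chromosome used throughout the simulation study, but they
    enter the effective-segment-number formulas separately.
    """

    positions: np.ndarray
    chrom_length: float = 1.0
    avg_chrom_length: float | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if pos.size == 0:
            raise ValueError("map must contain at least one locus")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted non-decreasing")
        if pos[0] < 0 or pos[-1] > self.chrom_length:
            raise ValueError("positions must lie within [0, chrom_length]")
        if self.avg_chrom_length is None:
            object.__setattr__(self, "avg_chrom_length", self.chrom_length)

    @property
    def n_loci(self) -> int:
        return self.positions.size

    @classmethod
    def equally_spaced(cls, n_loci: int, length: float = 1.0) -> "GeneticMap":
        """Grid of ``n_loci`` positions at spacing length/n_loci starting at 0.

        On a 1-Morgan chromosome this makes every whole-centimorgan
        point an exact marker position for the 100/1,000/5,000/10,000
        panels, so centimorgan-placed QTLs coincide with markers.
        """
        if n_loci < 2:
            raise ValueError("need at least 2 loci for an equally spaced map")
        return cls(np.arange(n_loci) * (length / n_loci), chrom_length=length)

    def nearest_locus(self, position: float) -> int:
        """Index of the locus closest to ``position`` (ties to the left locus)."""
        return int(np.argmin(np.abs(self.positions - position)))


@dataclass
class HaploidPopulation:
    """A set of haploid genomes: 0/1 allele matrix (individuals x loci)."""

    alleles: np.ndarray
    map: GeneticMap
    generation: int = 0

    def __post_init__(self):
        alleles = np.asarray(self.alleles, dtype=np.int8)
        if alleles.ndim != 2 or alleles.shape[1] != self.map.n_loci:
            raise ValueError("allele matrix must be individuals x map loci")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1")
        self.alleles = alleles

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    def subset(self, rows) -> "HaploidPopulation":
        return HaploidPopulation(self.alleles[rows], self.map, self.generation)


def make_founders(map: GeneticMap) -> HaploidPopulation:
    """Two completely divergent founder lines: all-0 and all-1 haplotypes."""
    alleles = np.vstack([
        np.zeros(map.n_loci, dtype=np.int8),
        np.ones(map.n_loci, dtype=np.int8),
    ])
    return HaploidPopulation(alleles, map, generation=0)


def meiosis(parent_a: np.ndarray, parent_b: np.ndarray, map: GeneticMap,
            rng: np.random.Generator) -> np.ndarray:
    """One gamete of two haploid parents under Haldane recombination.

    Crossover count ~ Poisson(chromosome length); crossover locations
    uniform on [0, L]; the copied parent alternates between consecutive
    crossovers, starting from either parent with probability 1/2.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    if parent_a.shape != (map.n_loci,) or parent_b.shape != (map.n_loci,):
        raise ValueError("parent haplotype length must match the map")
    n_cross = rng.poisson(map.chrom_length)
    start = rng.integers(2)
    if n_cross == 0:
        return (parent_a if start == 0 else parent_b).copy()
    cross = np.sort(rng.uniform(0.0, map.chrom_length, size=n_cross))
    parity = (np.searchsorted(cross, map.positions, side="right") + start) % 2
    return np.where(parity == 0, parent_a, parent_b)


def _random_offspring(pop: HaploidPopulation, n_offspring: int,
                      rng: np.random.Generator) -> np.ndarray:
    """``n_offspring`` gametes, each from two distinct random parents."""
    n = pop.n_individuals
    if n < 2:
        raise ValueError("need at least 2 parents for random mating")
    out = np.empty((n_offspring, pop.map.n_loci), dtype=np.int8)
    for i in range(n_offspring):
        a, b = rng.choice(n, size=2, replace=False)
        out[i] = meiosis(pop.alleles[a], pop.alleles[b], pop.map, rng)
    return out


def evolve(pop: HaploidPopulation, n_generations: int, pop_size: int,
           rng: np.random.Generator) -> HaploidPopulation:
    """Random mating at constant ``pop_size`` for ``n_generations`` steps.

    Each offspring is one meiotic gamete of two distinct parents drawn
    uniformly at random (no selfing); generations do not overlap.
    """
    if n_generations == 0:
        return pop
    if pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    current = pop
    for _ in range(n_generations):
        offspring = _random_offspring(current, pop_size, rng)
        current = HaploidPopulation(offspring, pop.map, current.generation + 1)
    return current


def make_full_sibs(pop: HaploidPopulation, n_sibs: int,
                   rng: np.random.Generator) -> HaploidPopulation:
    """Full-sib family: ``n_sibs`` gametes of one randomly chosen parent pair."""
    if pop.n_individuals < 2:
        raise ValueError("need at least 2 individuals to pick a parent pair")
    if n_sibs < 1:
        raise ValueError("n_sibs must be at least 1")
    a, b = rng.choice(pop.n_individuals, size=2, replace=False)
    sibs = np.empty((n_sibs, pop.map.n_loci), dtype=np.int8)
    for i in range(n_sibs):
        sibs[i] = meiosis(pop.alleles[a], pop.alleles[b], pop.map, rng)
    return HaploidPopulation(sibs, pop.map, pop.generation + 1)


def filter_markers(genotypes: np.ndarray) -> np.ndarray:
    """Indices of polymorphic, first-occurrence marker columns.

    Drops monomorphic columns and, among groups of identical columns,
    keeps only the left-most (smallest position). Returns ascending
    column indices into the input matrix.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    poly = (genotypes.min(axis=0) != genotypes.max(axis=0))
    seen: set[bytes] = set()
    kept = []
    for j in np.nonzero(poly)[0]:
        key = genotypes[:, j].astype(np.int8).tobytes()
        if key not in seen:
            seen.add(key)
            kept.append(j)
    return np.asarray(kept, dtype=int)


def branch_tst(pop_at_checkpoint: HaploidPopulation, extra_generations: int,
               n_tst: int, rng: np.random.Generator) -> HaploidPopulation:
    """Test individuals branched off a checkpoint population.

    The checkpoint is the penultimate generation of the training
    population.  It keeps evolving by random mating for
    ``extra_generations`` further generations at its own size, after
    which ``n_tst`` offspring are produced; with ``extra_generations=0``
    the test individuals are ordinary members of the final generation
    (same layout as the standard training/test split, without ever
    duplicating training rows).
    """
    if extra_generations < 0:
        raise ValueError("extra_generations must be >= 0")
    if n_tst > pop_at_checkpoint.n_individuals:
        raise ValueError("n_tst exceeds population size")
    current = evolve(pop_at_checkpoint, extra_generations,
                     pop_at_checkpoint.n_individuals, rng)
    tst = _random_offspring(current, n_tst, rng)
    return HaploidPopulation(tst, pop_at_checkpoint.map, current.generation + 1)
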