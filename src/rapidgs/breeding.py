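"""Meiosis, crossing, selfing, diallel mating, and doubled-haploid induction.

The crossover model is Haldane's: crossover counts per chromosome are
Poisson(length_cM / 100), positions uniform, no interference.  Haplotypes are
0/1 vectors over the map's flat marker order; genotypes are alternate-allele
counts (0/1/2), so DH individuals only ever carry 0 or 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "Individual",
    "Population",
    "gamete",
    "cross",
    "self_pollinate",
    "make_dh",
    "diallel",
]


@dataclass
class Individual:
    """A diploid, phased individual with pedigree labels."""

    id: str
    haplotypes: np.ndarray  # (2, n_markers) int8
    mother_id: str | None = None
    father_id: str | None = None
    stage: str = "S0"  # S0 | S1 | F1 | DH
    population: str = ""
    family: str | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_markers)")

    @property
    def genotype(self) -> np.ndarray:
        """Alternate-allele counts, shape (n_markers,)."""
        return self.haplotypes.sum(axis=0)

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None


@dataclass
class Population:
    """An ordered collection of individuals sharing one genetic map."""

    name: str
    individuals: list[Individual]
    _geno: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, i: int) -> Individual:
        return self.individuals[i]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def genotypes(self) -> np.ndarray:
        """(n, m) matrix of 0/1/2 alternate-allele counts (cached)."""
        if self._geno is None:
            self._geno = np.stack([ind.genotype for ind in self.individuals]).astype(np.int8)
        return self._geno

    def allele_freqs(self) -> np.ndarray:
        """Per-marker alternate-allele frequency."""
        return self.genotypes().mean(axis=0) / 2.0

    def subset(self, indices, name: str | None = None) -> "Population":
        return Population(name or self.name, [self.individuals[i] for i in indices])


def gamete(parent: Individual, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One recombinant haplotype from a phased parent (Haldane model)."""
    hap = np.empty(gmap.n_markers, dtype=np.int8)
    for c in range(gmap.n_chrom):
        sl = gmap.chrom_slice(c)
        length = gmap.chrom_lengths[c]
        n_xo = rng.poisson(length / 100.0)
        start = rng.integers(2)
        pos = gmap.positions_cm[sl]
        if n_xo == 0:
            phase = np.full(pos.shape, start)
        else:
            xo = np.sort(rng.uniform(0.0, length, size=n_xo))
            phase = (start + np.searchsorted(xo, pos)) % 2
        h = parent.haplotypes[:, sl]
        hap[sl] = np.where(phase == 0, h[0], h[1])
    return hap


def cross(
    mother: Individual,
    father: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    *,
    id: str,
    stage: str = "S0",
    population: str = "",
    family: str | None = None,
) -> Individual:
    """Offspring from one gamete of each parent; pedigree recorded."""
    haps = np.stack([gamete(mother, gmap, rng), gamete(father, gmap, rng)])
    return Individual(
        id=id,
        haplotypes=haps,
        mother_id=mother.id,
        father_id=father.id,
        stage=stage,
        population=population,
        family=family,
    )


def self_pollinate(
    parent: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    *,
    id: str,
    stage: str = "S1",
    population: str = "",
    family: str | None = None,
) -> Individual:
    """Selfing: two independent gametes from the same parent."""
    return cross(
        parent, parent, gmap, rng, id=id, stage=stage, population=population, family=family
    )


def make_dh(
    parent: Individual,
    gmap: GeneticMap,
    rng: np.random.Generator,
    *,
    id: str,
    population: str = "",
) -> Individual:
    """Doubled haploid: one gamete drawn and doubled; homozygous everywhere."""
    g = gamete(parent, gmap, rng)
    return Individual(
        id=id,
        haplotypes=np.stack([g, g.copy()]),
        mother_id=parent.id,
        father_id=parent.id,
        stage="DH",
        population=population,
        family=parent.family,
    )


def diallel(
    founders: list[Individual],
    total_offspring: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    *,
    population: str = "S1",
    id_prefix: str = "S1",
) -> Population:
    """Half-diallel (no selfs, no reciprocals), each F1 selfed once.

    ``total_offspring`` S1 plants are allocated as evenly as possible across
    the C(n, 2) families; family label = the founder pair.
    """
    if len(founders) < 2:
        raise ValueError("diallel requires at least 2 founders")
    pairs = list(itertools.combinations(range(len(founders)), 2))
    n_fam = len(pairs)
    base, extra = divmod(total_offspring, n_fam)
    offspring: list[Individual] = []
    counter = 0
    for k, (i, j) in enumerate(pairs):
        fam_size = base + (1 if k < extra else 0)
        if fam_size == 0:
            continue
        a, b = founders[i], founders[j]
        fam = f"{a.id}x{b.id}"
        f1 = cross(a, b, gmap, rng, id=f"{id_prefix}_F1_{fam}", stage="F1", family=fam)
        for _ in range(fam_size):
            counter += 1
            offspring.append(
                self_pollinate(
                    f1,
                    gmap,
                    rng,
                    id=f"{id_prefix}_{counter:05d}",
                    stage="S1",
                    population=population,
                    family=fam,
                )
            )
    return Population(population, offspring)


def pedigree_frame(individuals: list[Individual]) -> pd.DataFrame:
    """Pedigree export: id, mother, father, stage, population, family."""
    return pd.DataFrame(
        {
            "id": [i.id for i in individuals],
            "mother": [i.mother_id for i in individuals],
            "father": [i.father_id for i in individuals],
            "stage": [i.stage for i in individuals],
            "population": [i.population for i in individuals],
            "family": [i.family for i in individuals],
        }
    )


__all__.append("pedigree_frame")
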