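"""Synthetic landrace founders, polygenic trait architectures, and
plot-level multi-environment phenotypes.

Founders are heterozygous S0 plants drawn under linkage equilibrium: a
per-marker alternate-allele frequency comes from a truncated Beta
distribution and haplotype alleles are independent Bernoulli draws.
Linkage disequilibrium then arises downstream through selection and mating.
Trait genetics are strictly additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import as_rng
from .breeding import Individual, Population
from .genmap import GeneticMap

__all__ = [
    "TraitArchitecture",
    "TrialDesign",
    "VarianceConfig",
    "simulate_founders",
    "assign_architecture",
    "true_breeding_values",
    "simulate_trial",
    "DEFAULT_TRAITS",
]

DEFAULT_TRAITS = ("PH_V4", "PH_V6", "PH", "FF")

FREQ_TRUNCATION = (0.05, 0.95)


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL positions and per-trait additive allele-substitution effects."""

    trait_names: tuple[str, ...]
    qtl_indices: np.ndarray  # flat marker indices into the map
    qtl_marker_ids: tuple[str, ...]
    effects: np.ndarray  # (n_qtl, n_traits), trait units per alternate allele
    target_genetic_corr: np.ndarray  # (n_traits, n_traits)

    def __post_init__(self) -> None:
        if self.effects.shape != (len(self.qtl_indices), len(self.trait_names)):
            raise ValueError("effects shape must be (n_qtl, n_traits)")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")
        c = self.target_genetic_corr
        if c.shape != (len(self.trait_names),) * 2 or not np.allclose(c, c.T):
            raise ValueError("target_genetic_corr must be symmetric n_traits x n_traits")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("target_genetic_corr must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-8:
            raise ValueError("target_genetic_corr must be positive semi-definite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass(frozen=True)
class TrialDesign:
    """Multi-environment alpha-lattice-like layout.

    Each environment is a (location, year) label; every listed entry is grown
    in every environment in ``n_reps`` complete replications, randomized into
    incomplete blocks of ``block_size`` plots.
    """

    environments: tuple[str, ...]
    n_reps: int
    entries: tuple[str, ...]
    block_size: int = 10

    def __post_init__(self) -> None:
        if not self.environments or not self.entries:
            raise ValueError("design needs at least one environment and one entry")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate entry ids in design")


@dataclass(frozen=True)
class VarianceConfig:
    """Variance components used to generate plot values, per trait.

    ``env``, ``gxe``, ``error`` map trait name -> variance; ``rep`` and
    ``block`` are shared across traits.
    """

    env: dict
    gxe: dict
    error: dict
    rep: float = 0.0
    block: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.env, self.gxe, self.error):
            if any(v < 0 for v in d.values()):
                raise ValueError("variance components must be >= 0")
        if self.rep < 0 or self.block < 0:
            raise ValueError("variance components must be >= 0")


def simulate_founders(
    gmap: GeneticMap,
    n: int,
    maf_beta: tuple[float, float] = (1.0, 1.0),
    seed: int | np.random.Generator | None = None,
    *,
    population: str = "S0",
    id_prefix: str = "S0",
) -> Population:
    """Draw ``n`` heterozygous S0 plants under linkage equilibrium.

    Per-marker alternate-allele frequencies are Beta(a, b) truncated to
    [0.05, 0.95] (rejection sampling); haplotype alleles are independent
    Bernoulli(p) draws, so individuals are phased diploids.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    a, b = maf_beta
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    rng = as_rng(seed)
    m = gmap.n_markers
    lo, hi = FREQ_TRUNCATION
    freqs = rng.beta(a, b, size=m)
    bad = (freqs < lo) | (freqs > hi)
    while np.any(bad):  # rejection sampling onto the truncated support
        freqs[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (freqs < lo) | (freqs > hi)
    haps = (rng.random(size=(n, 2, m)) < freqs).astype(np.int8)
    individuals = [
        Individual(
            id=f"{id_prefix}_{i + 1:04d}",
            haplotypes=haps[i],
            stage="S0",
            population=population,
        )
        for i in range(n)
    ]
    return Population(population, individuals)


def assign_architecture(
    gmap: GeneticMap,
    founders: Population,
    n_qtl: int,
    target_genetic_corr: np.ndarray,
    trait_sds: np.ndarray,
    seed: int | np.random.Generator | None = None,
    trait_names: tuple[str, ...] = DEFAULT_TRAITS,
) -> TraitArchitecture:
    """Sample QTL and correlated additive effects.

    QTL are sampled without replacement from the map markers.  Effect rows
    are multivariate normal with covariance proportional to
    ``target_genetic_corr``; columns are then rescaled so the realized
    true-breeding-value standard deviations in ``founders`` equal
    ``trait_sds`` exactly.
    """
    target_genetic_corr = np.asarray(target_genetic_corr, dtype=float)
    trait_sds = np.asarray(trait_sds, dtype=float)
    if n_qtl > gmap.n_markers:
        raise ValueError("n_qtl exceeds number of markers")
    if np.min(np.linalg.eigvalsh(target_genetic_corr)) < -1e-8:
        raise ValueError("target_genetic_corr must be positive semi-definite")
    rng = as_rng(seed)
    qtl = np.sort(rng.choice(gmap.n_markers, size=n_qtl, replace=False))
    # sqrt factor tolerates PSD-but-singular targets
    w, v = np.linalg.eigh(target_genetic_corr)
    factor = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    effects = rng.standard_normal(size=(n_qtl, len(trait_names))) @ factor.T
    geno = founders.genotypes()[:, qtl].astype(float)
    tbv = geno @ effects
    sd = tbv.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate architecture: zero TBV variance in founders")
    effects = effects * (trait_sds / sd)
    return TraitArchitecture(
        trait_names=tuple(trait_names),
        qtl_indices=qtl,
        qtl_marker_ids=tuple(gmap.marker_ids[i] for i in qtl),
        effects=effects,
        target_genetic_corr=target_genetic_corr,
    )


def true_breeding_values(
    population: Population | np.ndarray,
    arch: TraitArchitecture,
) -> np.ndarray:
    """Additive TBVs: genotype dosage at each QTL times its effect, summed.

    Accepts a Population (QTL columns taken from the full genotype matrix)
    or a pre-sliced (n, n_qtl) dosage matrix.
    """
    if isinstance(population, Population):
        geno = population.genotypes()[:, arch.qtl_indices]
    else:
        geno = np.asarray(population)
        if geno.ndim != 2 or geno.shape[1] != len(arch.qtl_indices):
            raise ValueError("genotype matrix must be (n, n_qtl)")
    if np.any(pd.isna(geno)):
        raise ValueError("missing QTL genotypes")
    return geno.astype(float) @ arch.effects


def simulate_trial(
    populations: dict[str, Population],
    arch: TraitArchitecture,
    design: TrialDesign,
    variances: VarianceConfig,
    outlier_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    *,
    population_means: dict[str, np.ndarray] | None = None,
    sowing_kernels: int = 20,
    survival_p: float = 0.9,
) -> pd.DataFrame:
    """Generate plot-level records for a multi-environment trial.

    Plot value = population mean + TBV + environment + GxE + replication +
    block + residual.  A fraction ``outlier_rate`` of residuals is inflated
    tenfold; a per-plot plant count ~ Binomial(sowing_kernels, survival_p)
    makes the minimum-plant-stand filter exercisable downstream.
    """
    if not populations:
        raise ValueError("empty design: no populations supplied")
    rng = as_rng(seed)
    traits = arch.trait_names

    id_to_pop: dict[str, str] = {}
    id_to_tbv: dict[str, np.ndarray] = {}
    for pname, pop in populations.items():
        tbv = true_breeding_values(pop, arch)
        shift = np.zeros(len(traits))
        if population_means and pname in population_means:
            shift = np.asarray(population_means[pname], dtype=float)
        for i, ind in enumerate(pop):
            id_to_pop[ind.id] = pname
            id_to_tbv[ind.id] = tbv[i] + shift
    missing = [e for e in design.entries if e not in id_to_pop]
    if missing:
        raise ValueError(f"design entries without genotypes: {missing[:5]}")

    env_eff = {
        env: np.array([rng.normal(0.0, np.sqrt(variances.env[t])) for t in traits])
        for env in design.environments
    }
    gxe_eff = {
        (g, env): np.array([rng.normal(0.0, np.sqrt(variances.gxe[t])) for t in traits])
        for env in design.environments
        for g in design.entries
    }

    err_sd = np.array([np.sqrt(variances.error[t]) for t in traits])
    rows = []
    n_entries = len(design.entries)
    for env in design.environments:
        for rep in range(1, design.n_reps + 1):
            rep_eff = rng.normal(0.0, np.sqrt(variances.rep)) if variances.rep > 0 else 0.0
            order = rng.permutation(n_entries)
            n_blocks = int(np.ceil(n_entries / design.block_size))
            block_eff = (
                rng.normal(0.0, np.sqrt(variances.block), size=n_blocks)
                if variances.block > 0
                else np.zeros(n_blocks)
            )
            for plot_i, entry_i in enumerate(order):
                g = design.entries[entry_i]
                block = plot_i // design.block_size
                resid = rng.normal(0.0, 1.0, size=len(traits)) * err_sd
                if outlier_rate > 0 and rng.random() < outlier_rate:
                    resid = resid * 10.0
                value = id_to_tbv[g] + env_eff[env] + gxe_eff[(g, env)] + rep_eff
                value = value + block_eff[block] + resid
                rows.append(
                    {
                        "genotype": g,
                        "population": id_to_pop[g],
                        "environment": env,
                        "replication": f"{env}_r{rep}",
                        "block": f"{env}_r{rep}_b{block + 1}",
                        "plant_count": int(rng.binomial(sowing_kernels, survival_p)),
                        **{t: value[k] for k, t in enumerate(traits)},
                    }
                )
    return pd.DataFrame(rows)
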