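"""Multi-trait selection criterion, truncation selection with founder
contribution caps, MRD-maximizing mate allocation, and the three-cycle,
two-replication scheme orchestrator.

The criterion combines standardized GEBVs of the two early-height traits
(directional) with a transformed final-height GEBV (stabilizing):
``SC_i = V4_i + V6_i + 2 * PH_trans_i`` where
``PH_trans_i = max_j(scaled PH_j) - |scaled PH_i|`` over the current
candidate set.  Standardization is always over the candidate set of the
current cycle; the prediction model is never refit between cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .breeding import (
    Individual,
    Population,
    cross,
    diallel,
    make_dh,
    pedigree_frame,
)
from .genmap import GeneticMap, make_genetic_map
from .gblup import GblupFit, fit_gblup, fit_gblup_multitrait
from .landrace import (
    DEFAULT_TRAITS,
    TraitArchitecture,
    assign_architecture,
    simulate_founders,
    true_breeding_values,
)
from .relatedness import cross_grm, greedy_mrd_pairs, mrd_matrix, vanraden_grm

__all__ = [
    "scale_gebvs",
    "ph_trans",
    "selection_criterion",
    "rank_by_criterion",
    "select_top",
    "split_even_odd",
    "MatingPlan",
    "pair_by_mrd",
    "exhaustive_mrd_pairs",
    "SchemeConfig",
    "SchemeResult",
    "run_scheme",
]


# ------------------------------------------------------------- criterion


def scale_gebvs(values: np.ndarray, trait: str = "trait") -> np.ndarray:
    """Center and scale to mean 0, SD 1 (population SD, divisor n)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError(f"cannot scale trait {trait!r}: zero standard deviation")
    return (values - values.mean()) / sd


def ph_trans(scaled_ph: np.ndarray, use_abs_max: bool = False) -> np.ndarray:
    """Stabilizing transform: distance of |scaled value| below the set maximum.

    ``use_abs_max`` switches the additive constant from max(scaled) to
    max(|scaled|); the choice shifts all values equally and cannot change
    the ranking of the criterion.
    """
    scaled_ph = np.asarray(scaled_ph, dtype=float)
    if scaled_ph.size == 0:
        raise ValueError("empty candidate set")
    top = np.abs(scaled_ph).max() if use_abs_max else scaled_ph.max()
    return top - np.abs(scaled_ph)


def selection_criterion(
    scaled_v4: np.ndarray,
    scaled_v6: np.ndarray,
    ph_trans_vals: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 2.0),
) -> np.ndarray:
    """Linear combination of the three criterion components."""
    w4, w6, wt = weights
    return (
        w4 * np.asarray(scaled_v4, dtype=float)
        + w6 * np.asarray(scaled_v6, dtype=float)
        + wt * np.asarray(ph_trans_vals, dtype=float)
    )


def rank_by_criterion(sc: np.ndarray, ids: list[str]) -> list[int]:
    """Indices sorted by decreasing criterion; ties broken by candidate id."""
    return sorted(range(len(ids)), key=lambda i: (-sc[i], ids[i]))


def select_top(
    ranked_ids: list[str],
    n_select: int,
    lineages: dict[str, frozenset] | None = None,
    cap: int | None = None,
) -> list[str]:
    """Greedy truncation selection respecting a per-founder progeny cap.

    Walks down the ranking; a candidate is skipped when selecting it would
    push any of its founder ancestors above ``cap`` selected descendants.
    A shortfall (candidates exhausted) is returned as-is.
    """
    if n_select > len(ranked_ids):
        raise ValueError("n_select exceeds the number of candidates")
    if cap is None or lineages is None:
        return list(ranked_ids[:n_select])
    founders = set().union(*lineages.values()) if lineages else set()
    if cap * max(len(founders), 1) < n_select:
        raise ValueError(
            f"infeasible: cap {cap} x {len(founders)} founders < n_select {n_select}"
        )
    counts: dict[str, int] = {}
    chosen: list[str] = []
    for cid in ranked_ids:
        if len(chosen) == n_select:
            break
        lin = lineages.get(cid, frozenset())
        if any(counts.get(f, 0) + 1 > cap for f in lin):
            continue
        chosen.append(cid)
        for f in lin:
            counts[f] = counts.get(f, 0) + 1
    return chosen


def split_even_odd(ranked_selected: list[str]) -> tuple[list[str], list[str]]:
    """Odd ranks (1st, 3rd, ...) seed replication 1; even ranks seed R2."""
    return list(ranked_selected[0::2]), list(ranked_selected[1::2])


# ---------------------------------------------------------------- mating


@dataclass(frozen=True)
class MatingPlan:
    pairs: tuple[tuple[str, str, int], ...]  # (parent_a, parent_b, n_offspring)
    total_mrd: float
    contributions: dict = field(default_factory=dict)


def pair_by_mrd(
    individuals: list[Individual],
    n_pairs: int,
    total_offspring: int | None = None,
) -> MatingPlan:
    """Greedy MRD-maximizing pairing; each individual used at most once.

    Individual frequency vectors are genotype / 2 (values 0, 0.5, 1).
    Offspring are allocated as evenly as possible when ``total_offspring``
    is given.
    """
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals to form pairs")
    ids = [ind.id for ind in individuals]
    freqs = np.stack([ind.genotype for ind in individuals]) / 2.0
    dist = mrd_matrix(freqs)
    idx_pairs = greedy_mrd_pairs(dist, ids, n_pairs)
    total = float(sum(dist[i, j] for i, j in idx_pairs))
    if total_offspring is None:
        sizes = [0] * len(idx_pairs)
    else:
        base, extra = divmod(total_offspring, len(idx_pairs))
        sizes = [base + (1 if k < extra else 0) for k in range(len(idx_pairs))]
    pairs = tuple(
        (ids[i], ids[j], sizes[k]) for k, (i, j) in enumerate(idx_pairs)
    )
    return MatingPlan(pairs=pairs, total_mrd=total)


def exhaustive_mrd_pairs(dist: np.ndarray, n_pairs: int) -> tuple[list[tuple[int, int]], float]:
    """Best perfect matching by enumeration; oracle for small candidate sets."""
    n = dist.shape[0]
    if n > 12:
        raise ValueError("exhaustive matching limited to <= 12 candidates")

    best: tuple[float, list[tuple[int, int]]] = (-np.inf, [])

    def recurse(avail: list[int], chosen: list[tuple[int, int]], score: float) -> None:
        nonlocal best
        if len(chosen) == n_pairs:
            if score > best[0]:
                best = (score, list(chosen))
            return
        first = avail[0]
        for j in avail[1:]:
            rest = [a for a in avail if a not in (first, j)]
            recurse(rest, chosen + [(first, j)], score + dist[first, j])
        if len(avail) - 1 >= 2 * (n_pairs - len(chosen)):
            recurse(avail[1:], chosen, score)  # leave `first` unused

    recurse(list(range(n)), [], 0.0)
    return best[1], best[0]


# ------------------------------------------------------------- the scheme


@dataclass(frozen=True)
class SchemeConfig:
    """Counts, caps, weights and genetics settings for the full scheme."""

    n_chrom: int = 10
    markers_per_chrom: int = 200
    chrom_length_cm: float = 160.0
    maf_beta: tuple[float, float] = (2.0, 2.0)
    n_qtl: int = 400
    trait_names: tuple[str, ...] = DEFAULT_TRAITS
    trait_sds: tuple[float, ...] = (5.0, 8.0, 15.0, 3.0)
    genetic_corr: tuple[tuple[float, ...], ...] = (
        (1.0, 0.8, 0.4, 0.0),
        (0.8, 1.0, 0.4, 0.0),
        (0.4, 0.4, 1.0, 0.0),
        (0.0, 0.0, 0.0, 1.0),
    )
    h2: float = 0.7  # entry-mean heritability of training phenotypes

    n_c0: int = 402
    n_c0r: int = 105
    n_select_c0: int = 20
    n_founders_r2: int = 10  # set 8 to mirror the replication that lost two founders
    s1_size: int = 1000
    n_select_s1: int = 40
    founder_cap: int = 15
    n_pairs_c2: int = 20
    s0_size: int = 1000
    n_select_s0: int = 30
    n_pairs_c3: int = 15
    c3_size: int = 1000
    dh_per_cycle: int = 100

    sc_weights: tuple[float, float, float] = (1.0, 1.0, 2.0)
    criterion: str = "sc"  # "sc" (stabilizing) | "truncation_early"
    ph_trans_abs_max: bool = False

    @staticmethod
    def scaled() -> "SchemeConfig":
        """Desk-scale configuration for stochastic property checks."""
        return SchemeConfig(
            markers_per_chrom=100,
            n_chrom=6,
            n_qtl=200,
            n_c0=200,
            n_c0r=60,
            s1_size=200,
            s0_size=200,
            c3_size=200,
            dh_per_cycle=40,
        )


@dataclass
class SchemeResult:
    config: SchemeConfig
    seed: int
    gmap: GeneticMap
    arch: TraitArchitecture
    populations: dict[str, Population]
    gebvs: pd.DataFrame  # id, population, replication, cycle, one column per trait
    tbvs: pd.DataFrame
    fit: GblupFit
    fit_ff: GblupFit
    selections: dict[str, list[str]]
    mating_plans: dict[str, MatingPlan]
    c0_gebv_sd: dict[str, float]
    ref_freqs: np.ndarray

    def pedigree(self) -> pd.DataFrame:
        seen: dict[str, Individual] = {}
        for pop in self.populations.values():
            for ind in pop:
                seen.setdefault(ind.id, ind)
        return pedigree_frame(list(seen.values()))

    def population_means(self, kind: str = "gebv") -> pd.DataFrame:
        df = self.gebvs if kind == "gebv" else self.tbvs
        traits = list(self.config.trait_names)
        return df.groupby("population")[traits].mean()


def _founder_lineages(pop: Population, founder_ids: set[str],
                      parents: dict[str, tuple[str | None, str | None]]) -> dict[str, frozenset]:
    """Set of C0sel founder ancestors per individual, from the pedigree."""
    cache: dict[str, frozenset] = {}

    def lineage(iid: str) -> frozenset:
        if iid in cache:
            return cache[iid]
        if iid in founder_ids:
            cache[iid] = frozenset([iid])
            return cache[iid]
        mother, father = parents.get(iid, (None, None))
        out: frozenset = frozenset()
        for p in (mother, father):
            if p is not None:
                out |= lineage(p)
        cache[iid] = out
        return out

    return {ind.id: lineage(ind.id) for ind in pop}


def run_scheme(config: SchemeConfig, seed: int) -> SchemeResult:
    """Execute the full scheme: train, select C0sel, split, and per
    replication run diallel -> C1-S1 -> select/pair -> C2-S0 -> select/pair
    -> C3-S0, extracting DH sets per cycle and a random C0r sample."""
    cfg = config
    traits = list(cfg.trait_names)
    sel_traits = traits[:3]
    ff_trait = traits[3] if len(traits) > 3 else None

    gmap = make_genetic_map(cfg.n_chrom, cfg.markers_per_chrom, cfg.chrom_length_cm,
                            stage_rng(seed, "map"))
    s0 = simulate_founders(gmap, cfg.n_c0, cfg.maf_beta, stage_rng(seed, "founders"),
                           population="PE-S0", id_prefix="PE")
    rng_dh0 = stage_rng(seed, "dh_c0")
    c0 = Population(
        "C0",
        [make_dh(plant, gmap, rng_dh0, id=f"C0_{i + 1:04d}", population="C0")
         for i, plant in enumerate(s0)],
    )
    if len(c0) == 0:
        raise RuntimeError("stage C0: zero survivors")
    arch = assign_architecture(gmap, c0, cfg.n_qtl, np.array(cfg.genetic_corr),
                               np.array(cfg.trait_sds), stage_rng(seed, "arch"),
                               trait_names=cfg.trait_names)
    tbv_c0 = true_breeding_values(c0, arch)
    rng_noise = stage_rng(seed, "train_noise")
    noise_sd = tbv_c0.std(axis=0) * np.sqrt((1.0 - cfg.h2) / cfg.h2)
    y_train = tbv_c0 + rng_noise.standard_normal(tbv_c0.shape) * noise_sd

    ref_freqs = c0.allele_freqs()
    grm = vanraden_grm(c0.genotypes(), ref_freqs, ids=c0.ids)
    fit = fit_gblup_multitrait(y_train[:, :3], None, grm, trait_names=sel_traits)
    fit_ff = (fit_gblup(y_train[:, 3], None, grm, trait_name=ff_trait)
              if ff_trait else None)

    c0_geno = c0.genotypes()

    def gebvs_for(pop: Population) -> np.ndarray:
        kx = cross_grm(c0_geno, pop.genotypes(), ref_freqs)
        out = kx.T @ fit.alpha
        if fit_ff is not None:
            out = np.hstack([out, kx.T @ fit_ff.alpha])
        return out

    def sc_rank(pop: Population, gebv: np.ndarray) -> tuple[np.ndarray, list[int]]:
        v4 = scale_gebvs(gebv[:, 0], traits[0])
        v6 = scale_gebvs(gebv[:, 1], traits[1])
        if cfg.criterion == "truncation_early":
            sc = v4 + v6
        else:
            ph = scale_gebvs(gebv[:, 2], traits[2])
            sc = selection_criterion(v4, v6, ph_trans(ph, cfg.ph_trans_abs_max),
                                     cfg.sc_weights)
        return sc, rank_by_criterion(sc, pop.ids)

    populations: dict[str, Population] = {"C0": c0}
    selections: dict[str, list[str]] = {}
    mating_plans: dict[str, MatingPlan] = {}

    gebv_c0 = gebvs_for(c0)
    sc0, rank0 = sc_rank(c0, gebv_c0)
    c0sel_ids = select_top([c0.ids[i] for i in rank0], cfg.n_select_c0)
    selections["C0sel"] = c0sel_ids
    r1_ids, r2_ids = split_even_odd(c0sel_ids)
    r2_ids = r2_ids[: cfg.n_founders_r2]
    by_id = {ind.id: ind for ind in c0}
    populations["C0sel-R1"] = Population("C0sel-R1", [by_id[i] for i in r1_ids])
    populations["C0sel-R2"] = Population("C0sel-R2", [by_id[i] for i in r2_ids])
    selections["C0sel-R1"], selections["C0sel-R2"] = r1_ids, r2_ids

    rng_c0r = stage_rng(seed, "c0r")
    c0r_idx = rng_c0r.choice(len(c0), size=cfg.n_c0r, replace=False)
    populations["C0r"] = Population("C0r", [c0[i] for i in sorted(c0r_idx)])

    for rep, founder_ids in (("R1", r1_ids), ("R2", r2_ids)):
        founders = [by_id[i] for i in founder_ids]
        rng_rep = stage_rng(seed, f"{rep}_diallel")
        s1 = diallel(founders, cfg.s1_size, gmap, rng_rep,
                     population=f"C1-S1-{rep}", id_prefix=f"{rep}_S1")
        if len(s1) == 0:
            raise RuntimeError(f"stage C1-S1-{rep}: zero survivors")
        populations[f"C1-S1-{rep}"] = s1
        parents = {ind.id: (ind.mother_id, ind.father_id) for ind in s1}
        for ind in s1:
            fam = ind.family
            if fam:
                a, b = fam.split("x")
                parents[ind.mother_id] = (a, b)  # route S1 through its F1
        gebv_s1 = gebvs_for(s1)
        sc1, rank1 = sc_rank(s1, gebv_s1)
        lineages = _founder_lineages(s1, set(founder_ids), parents)
        sel1 = select_top([s1.ids[i] for i in rank1], cfg.n_select_s1,
                          lineages, cfg.founder_cap)
        if len(sel1) < 2 * cfg.n_pairs_c2:
            raise RuntimeError(f"stage C1-sel-{rep}: not enough selected plants")
        selections[f"C1-S1sel-{rep}"] = sel1
        s1_by_id = {ind.id: ind for ind in s1}
        plan2 = pair_by_mrd([s1_by_id[i] for i in sel1], cfg.n_pairs_c2, cfg.s0_size)
        mating_plans[f"C2-{rep}"] = plan2

        rng_c2 = stage_rng(seed, f"{rep}_c2")
        c2_inds: list[Individual] = []
        for a, b, size in plan2.pairs:
            fam = f"{a}x{b}"
            for _ in range(size):
                c2_inds.append(cross(s1_by_id[a], s1_by_id[b], gmap, rng_c2,
                                     id=f"{rep}_S0_{len(c2_inds) + 1:05d}", stage="S0",
                                     population=f"C2-S0-{rep}", family=fam))
        c2 = Population(f"C2-S0-{rep}", c2_inds)
        if len(c2) == 0:
            raise RuntimeError(f"stage C2-S0-{rep}: zero survivors")
        populations[f"C2-S0-{rep}"] = c2
        gebv_c2 = gebvs_for(c2)
        sc2, rank2 = sc_rank(c2, gebv_c2)
        sel2 = select_top([c2.ids[i] for i in rank2], cfg.n_select_s0)
        selections[f"C2-S0sel-{rep}"] = sel2
        c2_by_id = {ind.id: ind for ind in c2}
        plan3 = pair_by_mrd([c2_by_id[i] for i in sel2], cfg.n_pairs_c3, cfg.c3_size)
        mating_plans[f"C3-{rep}"] = plan3

        rng_c3 = stage_rng(seed, f"{rep}_c3")
        c3_inds: list[Individual] = []
        for a, b, size in plan3.pairs:
            fam = f"{a}x{b}"
            for _ in range(size):
                c3_inds.append(cross(c2_by_id[a], c2_by_id[b], gmap, rng_c3,
                                     id=f"{rep}_C3S0_{len(c3_inds) + 1:05d}", stage="S0",
                                     population=f"C3-S0-{rep}", family=fam))
        c3 = Population(f"C3-S0-{rep}", c3_inds)
        if len(c3) == 0:
            raise RuntimeError(f"stage C3-S0-{rep}: zero survivors")
        populations[f"C3-S0-{rep}"] = c3

        for cycle, src in (("C1", s1), ("C2", c2), ("C3", c3)):
            rng_dh = stage_rng(seed, f"{rep}_{cycle}_dh")
            picks = rng_dh.choice(len(src), size=min(cfg.dh_per_cycle, len(src)),
                                  replace=False)
            dh = Population(
                f"{cycle}-DH-{rep}",
                [make_dh(src[i], gmap, rng_dh,
                         id=f"{rep}_{cycle}DH_{k + 1:04d}",
                         population=f"{cycle}-DH-{rep}")
                 for k, i in enumerate(sorted(picks))],
            )
            populations[f"{cycle}-DH-{rep}"] = dh

    report_pops = [
        "C0", "C0r", "C0sel-R1", "C0sel-R2",
        "C1-S1-R1", "C1-S1-R2", "C2-S0-R1", "C2-S0-R2",
        "C1-DH-R1", "C1-DH-R2", "C2-DH-R1", "C2-DH-R2", "C3-DH-R1", "C3-DH-R2",
    ]
    gebv_rows, tbv_rows = [], []
    for pname in report_pops:
        pop = populations[pname]
        g = gebvs_for(pop)
        t = true_breeding_values(pop, arch)
        rep = pname.rsplit("-", 1)[1] if pname.endswith(("R1", "R2")) else None
        cycle = _cycle_of(pname)
        for i, iid in enumerate(pop.ids):
            base = {"id": iid, "population": pname, "replication": rep, "cycle": cycle}
            gebv_rows.append({**base, **{tr: g[i, k] for k, tr in enumerate(traits)}})
            tbv_rows.append({**base, **{tr: t[i, k] for k, tr in enumerate(traits)}})
    gebvs = pd.DataFrame(gebv_rows)
    tbvs = pd.DataFrame(tbv_rows)
    c0_sd = {tr: float(gebvs.loc[gebvs["population"] == "C0", tr].std())
             for tr in traits}

    return SchemeResult(
        config=cfg, seed=seed, gmap=gmap, arch=arch, populations=populations,
        gebvs=gebvs, tbvs=tbvs, fit=fit, fit_ff=fit_ff, selections=selections,
        mating_plans=mating_plans, c0_gebv_sd=c0_sd, ref_freqs=ref_freqs,
    )


def _cycle_of(pname: str) -> int | None:
    if pname.startswith("C0"):
        return 0
    for c in (1, 2, 3):
        if pname.startswith(f"C{c}-"):
            return c
    return None
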