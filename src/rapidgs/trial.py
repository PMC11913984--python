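"""Multi-environment trial analysis: plot filters, adjusted entry means,
population-heterogeneous variance components, heritability, and population
comparisons.

The plot-level model has a fixed population mean, genotype effects nested in
population (random with a separate variance per population, or fixed when
adjusted means are requested), random environment, genotype-by-environment
nested in population (heterogeneous variances), replication within
environment, and incomplete block within replication.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .mixedmodel import MixedModelFit, RandomTerm, reml

__all__ = [
    "plot_filter",
    "grubbs_flags",
    "grubbs_filter",
    "AdjustedMeans",
    "VarianceComponents",
    "fit_trial_model",
    "heritability",
    "compare_populations",
    "lrt_variance_heterogeneity",
]


# ---------------------------------------------------------------- filtering


def plot_filter(records: pd.DataFrame, min_plants: int = 5) -> pd.DataFrame:
    """Drop plots with fewer than ``min_plants`` plants; log removals."""
    keep = records["plant_count"] >= min_plants
    removed = records.loc[~keep]
    if len(removed):
        per_env = removed.groupby("environment").size().to_dict()
        warnings.warn(f"plot filter removed {len(removed)} plots: {per_env}", stacklevel=2)
    return records.loc[keep].reset_index(drop=True)


def grubbs_flags(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; returns a boolean outlier mask.

    At each pass the most extreme value is tested with
    G = max|x - mean| / sd against the t-based critical value; if rejected it
    is removed and the test repeats.  Degenerate inputs (n < 3 or zero SD)
    are passed through unflagged.
    """
    x = np.asarray(values, dtype=float)
    flags = np.zeros(x.shape, dtype=bool)
    active = np.isfinite(x)
    while True:
        idx = np.flatnonzero(active)
        n = idx.size
        if n < 3:
            break
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        g = dev.max() / sd
        t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        if g <= g_crit:
            break
        worst = idx[int(np.argmax(dev))]
        flags[worst] = True
        active[worst] = False
    return flags


def grubbs_filter(
    records: pd.DataFrame,
    traits: list[str],
    alpha: float = 0.05,
    by: tuple[str, ...] = ("environment",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the Grubbs test per trait within each stratum (default: per
    environment); flagged values are set to NaN.  Returns (filtered records,
    flag summary)."""
    out = records.copy()
    rows = []
    for key, grp in records.groupby(list(by)):
        for trait in traits:
            flags = grubbs_flags(grp[trait].to_numpy(), alpha=alpha)
            if flags.any():
                out.loc[grp.index[flags], trait] = np.nan
            rows.append(
                {
                    **dict(zip(by, key if isinstance(key, tuple) else (key,))),
                    "trait": trait,
                    "n_flagged": int(flags.sum()),
                }
            )
    return out, pd.DataFrame(rows)


# ----------------------------------------------------------- model fitting


@dataclass
class AdjustedMeans:
    """BLUEs per genotype for one trait."""

    trait: str
    table: pd.DataFrame  # columns: genotype, population, mean, se
    fit: MixedModelFit


@dataclass
class VarianceComponents:
    """REML variance components with per-population genetic and GxE terms."""

    trait: str
    populations: tuple[str, ...]
    sigma2_g: dict
    sigma2_gl: dict
    sigma2_env: float
    sigma2_rep: float
    sigma2_block: float
    sigma2_e: float
    loglik: float
    fit: MixedModelFit


def _dummies(codes: np.ndarray, n_levels: int) -> sparse.csc_matrix:
    n = codes.shape[0]
    return sparse.csc_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _check_connected(df: pd.DataFrame) -> None:
    g_codes, g_levels = pd.factorize(df["genotype"])
    e_codes, e_levels = pd.factorize(df["environment"])
    n_g, n_e = len(g_levels), len(e_levels)
    adj = sparse.csr_matrix(
        (np.ones(len(df)), (g_codes, e_codes)), shape=(n_g, n_e)
    )
    graph = sparse.bmat(
        [[None, adj], [adj.T, None]], format="csr"
    )
    n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
    if n_comp > 1:
        groups = [
            [str(g_levels[i]) for i in np.flatnonzero(labels[:n_g] == c)][:5]
            for c in range(n_comp)
        ]
        raise ValueError(f"disconnected trial design; isolated genotype groups: {groups}")


def _trial_terms(
    df: pd.DataFrame,
    pop_levels: list[str],
    *,
    genetic_pops: list[str],
    pooled_g: bool = False,
) -> list[RandomTerm]:
    terms: list[RandomTerm] = []
    if pooled_g and genetic_pops:
        mask = df["population"].isin(genetic_pops).to_numpy()
        codes, levels = pd.factorize(df.loc[mask, "genotype"])
        z = sparse.lil_matrix((len(df), len(levels)))
        z[np.flatnonzero(mask), :] = _dummies(codes, len(levels))
        terms.append(RandomTerm("g(pooled)", z.tocsc(), tuple(map(str, levels))))
    else:
        for p in genetic_pops:
            mask = (df["population"] == p).to_numpy()
            codes, levels = pd.factorize(df.loc[mask, "genotype"])
            z = sparse.lil_matrix((len(df), len(levels)))
            z[np.flatnonzero(mask), :] = _dummies(codes, len(levels))
            terms.append(RandomTerm(f"g({p})", z.tocsc(), tuple(map(str, levels))))
    for p in pop_levels:
        mask = (df["population"] == p).to_numpy()
        key = df.loc[mask, "genotype"].astype(str) + "@" + df.loc[mask, "environment"].astype(str)
        codes, levels = pd.factorize(key)
        z = sparse.lil_matrix((len(df), len(levels)))
        z[np.flatnonzero(mask), :] = _dummies(codes, len(levels))
        terms.append(RandomTerm(f"gl({p})", z.tocsc(), tuple(map(str, levels))))
    for name, col in (("env", "environment"), ("rep", "replication"), ("block", "block")):
        codes, levels = pd.factorize(df[col])
        terms.append(RandomTerm(name, _dummies(codes, len(levels)), tuple(map(str, levels))))
    return terms


def fit_trial_model(
    records: pd.DataFrame,
    trait: str,
    mode: str = "means",
    fixed_populations: tuple[str, ...] = (),
    pooled_g: bool = False,
    max_iter: int = 100,
):
    """REML fit of the plot-level trial model for one trait.

    ``mode='means'`` treats every genotype as fixed and returns BLUEs
    (:class:`AdjustedMeans`); ``mode='varcomp'`` treats genotypes in
    non-fixed populations as random with population-specific variances and
    returns :class:`VarianceComponents`.
    """
    df = records.dropna(subset=[trait]).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no observations for trait {trait}")
    _check_connected(df)
    y = df[trait].to_numpy(dtype=float)
    pop_levels = list(pd.unique(df["population"]))

    if mode == "means":
        g_codes, g_levels = pd.factorize(df["genotype"])
        x = _dummies(g_codes, len(g_levels)).toarray()
        terms = _trial_terms(df, pop_levels, genetic_pops=[])
        fit = reml(y, x, terms, max_iter=max_iter)
        geno_pop = df.groupby("genotype")["population"].first()
        table = pd.DataFrame(
            {
                "genotype": list(map(str, g_levels)),
                "population": [geno_pop[g] for g in g_levels],
                "mean": fit.beta,
                "se": np.sqrt(np.diag(fit.beta_cov)),
            }
        )
        return AdjustedMeans(trait=trait, table=table, fit=fit)

    if mode != "varcomp":
        raise ValueError("mode must be 'means' or 'varcomp'")

    random_pops = [p for p in pop_levels if p not in fixed_populations]
    # fixed part: population intercepts for random pops, genotype dummies for
    # fixed (check) populations
    p_codes = df["population"].to_numpy()
    cols = []
    names = []
    for p in random_pops:
        cols.append((p_codes == p).astype(float))
        names.append(f"pop:{p}")
    for p in fixed_populations:
        if p not in pop_levels:
            continue
        mask = p_codes == p
        for g in pd.unique(df.loc[mask, "genotype"]):
            cols.append(((df["genotype"] == g) & mask).to_numpy(dtype=float))
            names.append(f"check:{g}")
    x = np.column_stack(cols)
    terms = _trial_terms(df, pop_levels, genetic_pops=random_pops, pooled_g=pooled_g)
    fit = reml(y, x, terms, max_iter=max_iter)
    name_idx = {nm: i for i, nm in enumerate(fit.term_names)}
    if pooled_g:
        s2g = {p: float(fit.theta[name_idx["g(pooled)"]]) for p in random_pops}
    else:
        s2g = {p: float(fit.theta[name_idx[f"g({p})"]]) for p in random_pops}
    s2gl = {p: float(fit.theta[name_idx[f"gl({p})"]]) for p in pop_levels}
    return VarianceComponents(
        trait=trait,
        populations=tuple(random_pops),
        sigma2_g=s2g,
        sigma2_gl=s2gl,
        sigma2_env=fit.variance("env"),
        sigma2_rep=fit.variance("rep"),
        sigma2_block=fit.variance("block"),
        sigma2_e=fit.sigma2_e,
        loglik=fit.loglik,
        fit=fit,
    )


# --------------------------------------------------------------- summaries


def heritability(
    sigma2_g: float,
    sigma2_gl: float,
    sigma2_e: float,
    n_env: int,
    n_rep: int,
    n_genotypes: int | None = None,
    alpha: float = 0.05,
):
    """Entry-mean heritability with an F-quantile confidence interval.

    h2 = s2_g / (s2_g + s2_gl / E + s2_e / (E R)).  The CI uses the
    balanced-design approximation: F_obs = 1 / (1 - h2) with
    df1 = n_g - 1 and df2 = (n_g - 1)(E - 1); bounds are
    1 - F_quantile / F_obs, truncated to [0, 1].
    """
    denom = sigma2_g + sigma2_gl / n_env + sigma2_e / (n_env * n_rep)
    if denom <= 0:
        return 0.0, (0.0, 0.0)
    h2 = float(np.clip(sigma2_g / denom, 0.0, 1.0))
    if n_genotypes is None or h2 >= 1.0 or n_env < 2:
        return h2, None
    f_obs = 1.0 / (1.0 - h2) if h2 < 1.0 else np.inf
    df1 = n_genotypes - 1
    df2 = (n_genotypes - 1) * (n_env - 1)
    lo = 1.0 - stats.f.ppf(1.0 - alpha / 2.0, df1, df2) / f_obs
    hi = 1.0 - stats.f.ppf(alpha / 2.0, df1, df2) / f_obs
    return h2, (float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


def _letter_display(levels: list[str], different: set[tuple[str, str]]) -> dict:
    """Compact letter display: populations not proven different share letters."""
    letters: list[set[str]] = []
    for lev in levels:
        placed = False
        for grp in letters:
            if all((lev, other) not in different and (other, lev) not in different for other in grp):
                grp.add(lev)
                placed = True
        if not placed:
            letters.append({lev})
    out = {lev: "" for lev in levels}
    for i, grp in enumerate(letters):
        for lev in grp:
            out[lev] += string.ascii_lowercase[i % 26]
    return out


def compare_populations(
    adjusted_means: pd.DataFrame,
    value_col: str = "mean",
    alpha: float = 0.05,
):
    """Global Wald test on population means plus Welch pairwise t-tests.

    Expects one row per genotype with columns ``population`` and
    ``value_col``.  Pairwise p-values are Bonferroni-Holm adjusted; a letter
    display is derived from the adjusted decisions.  With a single
    population the global test is skipped.
    """
    pops = list(pd.unique(adjusted_means["population"]))
    groups = {
        p: adjusted_means.loc[adjusted_means["population"] == p, value_col].to_numpy()
        for p in pops
    }
    if len(pops) < 2:
        return {
            "global_stat": None,
            "global_p": None,
            "message": "single population: global test skipped",
            "pairwise": pd.DataFrame(),
            "letters": {pops[0]: "a"} if pops else {},
        }
    w = np.array([len(groups[p]) / max(groups[p].var(ddof=1), 1e-12) for p in pops])
    m = np.array([groups[p].mean() for p in pops])
    grand = float(np.sum(w * m) / np.sum(w))
    wald = float(np.sum(w * (m - grand) ** 2))
    global_p = float(stats.chi2.sf(wald, len(pops) - 1))

    rows = []
    for a, b in itertools.combinations(pops, 2):
        t_stat, p_val = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append({"pop_a": a, "pop_b": b, "t": float(t_stat), "p": float(p_val)})
    pair = pd.DataFrame(rows)
    pair["p_holm"] = _holm(pair["p"].to_numpy())
    different = {
        (r.pop_a, r.pop_b) for r in pair.itertuples() if r.p_holm < alpha
    } if global_p < alpha else set()
    return {
        "global_stat": wald,
        "global_p": global_p,
        "message": None,
        "pairwise": pair,
        "letters": _letter_display(pops, different),
    }


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def lrt_variance_heterogeneity(
    records: pd.DataFrame,
    trait: str,
    pop_a: str,
    pop_b: str,
    fixed_populations: tuple[str, ...] = (),
    max_iter: int = 100,
):
    """LRT of separate vs pooled genetic variance for a population pair.

    Both models share fixed effects, so the REML likelihoods are comparable;
    the statistic 2 * (ll_het - ll_pooled) is referred to chi-square(1).
    """
    sub = records[records["population"].isin([pop_a, pop_b])].reset_index(drop=True)
    het = fit_trial_model(sub, trait, mode="varcomp",
                          fixed_populations=fixed_populations, max_iter=max_iter)
    pooled = fit_trial_model(sub, trait, mode="varcomp", pooled_g=True,
                             fixed_populations=fixed_populations, max_iter=max_iter)
    stat = max(0.0, 2.0 * (het.loglik - pooled.loglik))
    p = float(stats.chi2.sf(stat, 1))
    return {"statistic": stat, "p": p, "het": het, "pooled": pooled}
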