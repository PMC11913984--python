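"""Selection-response regressions, C0-anchored reporting, prediction
ability/accuracy, training-set retraining across eras, bootstrap
comparisons of abilities, and per-population trait correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionFit",
    "response_regression",
    "response_regression_from_means",
    "standardize_to_c0",
    "AccuracyReport",
    "prediction_accuracy",
    "retrain",
    "BootstrapResult",
    "bootstrap_compare",
    "trait_correlations",
    "report_tables",
    "holm_adjust",
]


# ------------------------------------------------------------- regression


@dataclass
class RegressionFit:
    """Per-replication cycle regressions plus the common-slope LRT."""

    per_rep: pd.DataFrame  # replication, n, intercept, slope, se, p_one_sided
    lrt_stat: float | None
    lrt_p: float | None

    def slope(self, rep) -> float:
        row = self.per_rep.loc[self.per_rep["replication"] == rep]
        return float(row["slope"].iloc[0])


def _ols_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise ValueError("regression needs at least 2 distinct cycles")
    slope = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - intercept - slope * x
    rss = float(np.sum(w * resid**2))
    n = int(sw) if w is not None else len(x)
    df = n - 2
    se = float(np.sqrt(rss / df / sxx)) if df > 0 else np.nan
    return intercept, slope, se, rss, n, df


def response_regression(
    values: np.ndarray,
    cycles: np.ndarray,
    replications: np.ndarray | None = None,
    one_sided: bool = True,
) -> RegressionFit:
    """OLS of individual values on cycle index with replication-specific
    intercepts and slopes, plus an LRT of a common slope across
    replications (chi-square, df = n_reps - 1)."""
    values = np.asarray(values, dtype=float)
    cycles = np.asarray(cycles, dtype=float)
    if replications is None:
        replications = np.zeros(len(values), dtype=int)
    replications = np.asarray(replications)
    reps = list(pd.unique(replications))

    rows = []
    rss_full = 0.0
    n_total = len(values)
    for r in reps:
        mask = replications == r
        if len(np.unique(cycles[mask])) < 2:
            raise ValueError(f"replication {r!r} has fewer than 2 distinct cycles")
        intercept, slope, se, rss, n, df = _ols_slope(cycles[mask], values[mask])
        rss_full += rss
        if se and np.isfinite(se) and se > 0:
            t = slope / se
            p = float(stats.t.sf(t, df)) if one_sided else float(2 * stats.t.sf(abs(t), df))
        else:
            p = np.nan
        rows.append(
            {"replication": r, "n": n, "intercept": intercept, "slope": slope,
             "se": se, "p_one_sided" if one_sided else "p": p}
        )
    per_rep = pd.DataFrame(rows)

    lrt_stat = lrt_p = None
    if len(reps) > 1:
        # reduced model: separate intercepts, one shared slope
        x_cols = [np.asarray(replications == r, dtype=float) for r in reps]
        x_red = np.column_stack(x_cols + [cycles])
        beta, *_ = np.linalg.lstsq(x_red, values, rcond=None)
        rss_red = float(np.sum((values - x_red @ beta) ** 2))
        lrt_stat = max(0.0, n_total * np.log(rss_red / rss_full))
        lrt_p = float(stats.chi2.sf(lrt_stat, len(reps) - 1))
    return RegressionFit(per_rep=per_rep, lrt_stat=lrt_stat, lrt_p=lrt_p)


def response_regression_from_means(
    means: np.ndarray,
    sizes: np.ndarray,
    cycles: np.ndarray,
    replication: str = "R1",
) -> RegressionFit:
    """Population-size-weighted regression of cycle means on cycle index.

    Because the predictor is constant within cycle, weighting the cycle
    means by population size is exactly the individual-level OLS slope.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    cycles = np.asarray(cycles, dtype=float)
    if len(np.unique(cycles)) < 2:
        raise ValueError("regression needs at least 2 distinct cycles")
    intercept, slope, se, _, n, df = _ols_slope(cycles, means, w=sizes)
    per_rep = pd.DataFrame(
        [{"replication": replication, "n": int(sizes.sum()), "intercept": intercept,
          "slope": slope, "se": np.nan, "p_one_sided": np.nan}]
    )
    return RegressionFit(per_rep=per_rep, lrt_stat=None, lrt_p=None)


def standardize_to_c0(
    values: np.ndarray,
    c0_values: np.ndarray,
    sd: float | None = None,
) -> np.ndarray:
    """Express values in units of the C0 baseline: (v - mean(C0)) / SD.

    ``sd`` overrides the empirical SD of ``c0_values`` — pass the genetic
    standard deviation of the random C0 sample when standardizing realized
    (phenotype-based) means.
    """
    c0_values = np.asarray(c0_values, dtype=float)
    scale = float(sd) if sd is not None else float(c0_values.std())
    if scale <= 0:
        raise ValueError("non-positive C0 standard deviation")
    return (np.asarray(values, dtype=float) - c0_values.mean()) / scale


# --------------------------------------------------------------- accuracy


@dataclass
class AccuracyReport:
    ability: float  # Pearson r(GEBV, adjusted mean)
    h2: float
    accuracy: float  # ability / sqrt(h2); may exceed 1, reported as computed
    n: int


def prediction_accuracy(gebvs: np.ndarray, adjusted_means: np.ndarray, h2: float) -> AccuracyReport:
    gebvs = np.asarray(gebvs, dtype=float)
    adjusted_means = np.asarray(adjusted_means, dtype=float)
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    if len(gebvs) != len(adjusted_means) or len(gebvs) < 3:
        raise ValueError("need at least 3 paired observations")
    r = float(np.corrcoef(gebvs, adjusted_means)[0, 1])
    return AccuracyReport(ability=r, h2=float(h2), accuracy=r / np.sqrt(h2), n=len(gebvs))


def retrain(
    training_sets: list[tuple[pd.DataFrame, str]],
    check_ids: list[str],
    value_col: str = "mean",
    reference_era: str | None = None,
) -> pd.DataFrame:
    """Combine adjusted-mean tables from different trial eras via common checks.

    Each era's values are shifted by (reference-era check mean - era check
    mean) before concatenation; genotypes present in several eras keep the
    record of the newest era (last in the list).
    """
    if not training_sets:
        raise ValueError("no training sets supplied")
    eras = [era for _, era in training_sets]
    ref = reference_era if reference_era is not None else eras[0]
    ref_df = dict(zip(eras, [df for df, _ in training_sets]))[ref]
    ref_checks = ref_df[ref_df["genotype"].isin(check_ids)]
    if ref_checks.empty:
        raise ValueError("reference era shares no checks")
    ref_mean = float(ref_checks[value_col].mean())
    frames = []
    for df, era in training_sets:
        checks = df[df["genotype"].isin(check_ids)]
        if checks.empty:
            raise ValueError(f"era {era!r} shares no checks with the reference era")
        shift = ref_mean - float(checks[value_col].mean())
        adj = df.copy()
        adj[value_col] = adj[value_col] + shift
        adj["era"] = era
        frames.append(adj)
    combined = pd.concat(frames, ignore_index=True)
    # newest record wins for duplicated genotypes (later frames are newer)
    combined = combined.drop_duplicates(subset="genotype", keep="last").reset_index(drop=True)
    return combined


# -------------------------------------------------------------- bootstrap


@dataclass
class BootstrapResult:
    diff_mean: float
    q025: float
    q975: float
    significant: bool
    b: int
    seed: int
    mode: str


def bootstrap_compare(
    set_a: tuple[np.ndarray, np.ndarray],
    set_b: tuple[np.ndarray, np.ndarray],
    mode: str = "independent",
    b: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the difference in prediction abilities of two sets.

    Each set is a pair (gebvs, adjusted means).  ``paired`` resamples a
    shared index vector (the sets must be equally sized and id-aligned);
    ``independent`` resamples each set separately.  The difference is called
    significant when zero lies outside the (2.5%, 97.5%) quantile interval.
    """
    ga, ma = (np.asarray(v, dtype=float) for v in set_a)
    gb, mb = (np.asarray(v, dtype=float) for v in set_b)
    if len(ga) < 5 or len(gb) < 5:
        raise ValueError("each set needs at least 5 observations")
    if mode not in ("paired", "independent"):
        raise ValueError("mode must be 'paired' or 'independent'")
    if mode == "paired" and len(ga) != len(gb):
        raise ValueError("paired mode requires equally sized, id-aligned sets")
    if b < 100:
        warnings.warn("bootstrap with B < 100 resamples is unreliable", stacklevel=2)
    rng = np.random.default_rng(seed)
    diffs = np.empty(b)
    na, nb = len(ga), len(gb)
    for k in range(b):
        if mode == "paired":
            idx = rng.integers(na, size=na)
            ra = _safe_corr(ga[idx], ma[idx])
            rb = _safe_corr(gb[idx], mb[idx])
        else:
            ia = rng.integers(na, size=na)
            ib = rng.integers(nb, size=nb)
            ra = _safe_corr(ga[ia], ma[ia])
            rb = _safe_corr(gb[ib], mb[ib])
        diffs[k] = ra - rb
    q025, q975 = np.quantile(diffs, [0.025, 0.975])
    return BootstrapResult(
        diff_mean=float(diffs.mean()),
        q025=float(q025),
        q975=float(q975),
        significant=bool(q025 > 0.0 or q975 < 0.0),
        b=b,
        seed=seed,
        mode=mode,
    )


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


# ----------------------------------------------------------- correlations


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * pvals[i])
        adj[i] = min(running, 1.0)
    return adj


def trait_correlations(
    means: pd.DataFrame,
    traits: list[str],
    by: str = "population",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-population Pearson correlations among traits with Holm-adjusted
    significance across the whole tested family."""
    rows = []
    for pop, grp in means.groupby(by):
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                x, y = grp[traits[i]].to_numpy(), grp[traits[j]].to_numpy()
                mask = np.isfinite(x) & np.isfinite(y)
                if mask.sum() < 3:
                    continue
                r, p = stats.pearsonr(x[mask], y[mask])
                rows.append({by: pop, "trait_a": traits[i], "trait_b": traits[j],
                             "r": float(r), "p": float(p), "n": int(mask.sum())})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        out["significant"] = out["p_holm"] < alpha
    return out


# ----------------------------------------------------------------- report


def report_tables(result, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Mean-GEBV table (C0-anchored) with per-cycle slopes, per replication.

    Rows are the 14 reported populations; slope rows cover the heterozygous
    selection units (two-cycle regression) and the DH sets (three-cycle
    regression), plus the DH slope re-expressed in C0 GEBV-SD units.
    """
    traits = list(result.config.trait_names)
    means = result.population_means("gebv")

    slope_rows = {}
    for rep in ("R1", "R2"):
        df = result.gebvs
        dh = df[df["population"].isin([f"C{c}-DH-{rep}" for c in (1, 2, 3)])]
        for trait in traits:
            fit = response_regression(dh[trait].to_numpy(), dh["cycle"].to_numpy())
            slope_rows.setdefault(("slope C1-DH..C3-DH", rep), {})[trait] = fit.slope(0)
            slope_rows.setdefault(("slope p C1-DH..C3-DH", rep), {})[trait] = float(
                fit.per_rep["p_one_sided"].iloc[0]
            )
            het = df[df["population"].isin([f"C1-S1-{rep}", f"C2-S0-{rep}"])]
            fit_het = response_regression(het[trait].to_numpy(), het["cycle"].to_numpy())
            slope_rows.setdefault(("slope C1-S1..C2-S0", rep), {})[trait] = fit_het.slope(0)
            slope_rows.setdefault(("slope DH in C0-SD units", rep), {})[trait] = (
                fit.slope(0) / result.c0_gebv_sd[trait]
            )

    mean_table = means.copy()
    mean_table["n"] = [len(result.populations[p]) for p in means.index]
    slope_table = pd.DataFrame(
        [{"row": row, "replication": rep, **vals} for (row, rep), vals in slope_rows.items()]
    )
    return {"population_means": mean_table.reset_index(), "slopes": slope_table}
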