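import numpy as np
import pandas as pd
import pytest

from rapidgs.response import (
    bootstrap_compare,
    holm_adjust,
    prediction_accuracy,
    report_tables,
    response_regression,
    response_regression_from_means,
    retrain,
    standardize_to_c0,
    trait_correlations,
)


# ------------------------------------------------------------- regression


def test_weighted_means_equals_individual_level_ols():
    rng = np.random.default_rng(0)
    cycles = np.repeat([1, 2, 3], [50, 40, 30])
    y = 0.5 * cycles + rng.normal(0, 1, len(cycles))
    fit_ind = response_regression(y, cycles)
    means = [y[cycles == c].mean() for c in (1, 2, 3)]
    fit_mean = response_regression_from_means(means, [50, 40, 30], [1, 2, 3])
    assert fit_mean.slope("R1") == pytest.approx(fit_ind.slope(0), abs=1e-12)


def test_two_cycle_slope_is_difference_of_means():
    means = [5.25, 7.14]
    fit = response_regression_from_means(means, [1003, 1005], [1, 2])
    assert fit.slope("R1") == pytest.approx(7.14 - 5.25)
    # group sizes are irrelevant with two cycles
    fit2 = response_regression_from_means(means, [10, 99999], [1, 2])
    assert fit2.slope("R1") == pytest.approx(fit.slope("R1"))


def test_single_cycle_rejected():
    with pytest.raises(ValueError):
        response_regression(np.array([1.0, 2.0]), np.array([1, 1]))


def test_lrt_type_one_rate_nested_slopes():
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        cycles = np.tile(np.repeat([1, 2, 3], 30), 2)
        reps = np.repeat(["R1", "R2"], 90)
        y = 0.4 * cycles + rng.normal(0, 1, 180)  # equal slopes in both reps
        fit = response_regression(y, cycles, reps)
        hits += fit.lrt_p < 0.05
    assert 0.03 <= hits / n_rep <= 0.075


def test_lrt_detects_different_slopes():
    rng = np.random.default_rng(2)
    cycles = np.tile(np.repeat([1, 2, 3], 60), 2)
    reps = np.repeat(["R1", "R2"], 180)
    slope = np.where(reps == "R1", 0.2, 1.2)
    y = slope * cycles + rng.normal(0, 1, 360)
    fit = response_regression(y, cycles, reps)
    assert fit.lrt_p < 0.01


def test_one_sided_p_for_positive_slope():
    rng = np.random.default_rng(3)
    cycles = np.repeat([1, 2, 3], 40)
    y = 1.0 * cycles + rng.normal(0, 1, 120)
    fit = response_regression(y, cycles)
    assert fit.per_rep["p_one_sided"].iloc[0] < 1e-4


# ---------------------------------------------------------- standardization


def test_standardize_c0_mean_zero():
    rng = np.random.default_rng(4)
    c0 = rng.normal(10, 2, 100)
    out = standardize_to_c0(c0, c0)
    assert out.mean() == pytest.approx(0.0, abs=1e-12)


def test_standardize_one_sd_above():
    c0 = np.array([0.0, 2.0])  # mean 1, SD 1
    assert standardize_to_c0(np.array([2.0]), c0)[0] == pytest.approx(1.0)


def test_standardize_with_genetic_sd():
    c0 = np.array([0.0, 2.0])
    out = standardize_to_c0(np.array([3.0]), c0, sd=4.0)
    assert out[0] == pytest.approx(0.5)


# --------------------------------------------------------------- accuracy


def test_accuracy_arithmetic():
    rng = np.random.default_rng(5)
    g = rng.normal(size=50)
    m = 0.4 * g + rng.normal(size=50)
    rep = prediction_accuracy(g, m, h2=0.64)
    assert rep.accuracy == pytest.approx(rep.ability / 0.8)


def test_accuracy_h2_one_equals_ability():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    m = np.array([1.1, 1.9, 3.2, 3.8])
    rep = prediction_accuracy(g, m, h2=1.0)
    assert rep.accuracy == rep.ability


def test_accuracy_input_validation():
    with pytest.raises(ValueError):
        prediction_accuracy(np.ones(2), np.ones(2), 0.5)
    with pytest.raises(ValueError):
        prediction_accuracy(np.ones(5), np.ones(5), 0.0)


# ---------------------------------------------------------------- retrain


def _era(genos, values):
    return pd.DataFrame({"genotype": genos, "mean": values})


def test_retrain_identical_checks_no_shift():
    a = _era(["chk1", "g1"], [5.0, 1.0])
    b = _era(["chk1", "g2"], [5.0, 2.0])
    out = retrain([(a, "2018"), (b, "2023")], check_ids=["chk1"])
    assert out.loc[out["genotype"] == "g2", "mean"].iloc[0] == pytest.approx(2.0)


def test_retrain_shift_invariance():
    a = _era(["chk1", "chk2", "g1"], [5.0, 7.0, 1.0])
    b = _era(["chk1", "chk2", "g2"], [15.0, 17.0, 11.0])  # era shifted by +10
    out = retrain([(a, "2018"), (b, "2023")], check_ids=["chk1", "chk2"])
    chk = out[out["genotype"].str.startswith("chk")]
    assert chk.groupby("genotype")["mean"].nunique().le(1).all()
    assert out.loc[out["genotype"] == "g2", "mean"].iloc[0] == pytest.approx(1.0)


def test_retrain_newest_record_wins():
    a = _era(["chk1", "dup"], [5.0, 1.0])
    b = _era(["chk1", "dup"], [5.0, 9.0])
    out = retrain([(a, "old"), (b, "new")], check_ids=["chk1"])
    assert out.loc[out["genotype"] == "dup", "mean"].iloc[0] == pytest.approx(9.0)
    assert out.loc[out["genotype"] == "dup", "era"].iloc[0] == "new"


def test_retrain_no_common_checks_rejected():
    a = _era(["chk1", "g1"], [5.0, 1.0])
    b = _era(["g2"], [2.0])
    with pytest.raises(ValueError):
        retrain([(a, "2018"), (b, "2023")], check_ids=["chk1"])


# -------------------------------------------------------------- bootstrap


def test_bootstrap_identical_sets_not_significant():
    rng = np.random.default_rng(6)
    g = rng.normal(size=40)
    m = 0.5 * g + rng.normal(size=40)
    res = bootstrap_compare((g, m), (g, m), mode="paired", b=500, seed=1)
    assert res.q025 == res.q975 == 0.0
    assert not res.significant


def test_bootstrap_seed_determinism():
    rng = np.random.default_rng(7)
    a = (rng.normal(size=30), rng.normal(size=30))
    b = (rng.normal(size=30), rng.normal(size=30))
    r1 = bootstrap_compare(a, b, b=300, seed=5)
    r2 = bootstrap_compare(a, b, b=300, seed=5)
    assert (r1.q025, r1.q975) == (r2.q025, r2.q975)


def test_bootstrap_rejects_tiny_sets():
    with pytest.raises(ValueError):
        bootstrap_compare((np.ones(3), np.ones(3)), (np.ones(3), np.ones(3)))


def test_bootstrap_warns_small_b():
    rng = np.random.default_rng(8)
    a = (rng.normal(size=20), rng.normal(size=20))
    with pytest.warns(UserWarning):
        bootstrap_compare(a, a, mode="paired", b=50, seed=0)


def test_bootstrap_interval_widens_with_smaller_n():
    rng = np.random.default_rng(9)
    g = rng.normal(size=200)
    m = 0.5 * g + rng.normal(size=200)
    g2 = rng.normal(size=200)
    m2 = 0.3 * g2 + rng.normal(size=200)
    wide = []
    for n in (200, 50):
        res = bootstrap_compare((g[:n], m[:n]), (g2[:n], m2[:n]), b=1000, seed=2)
        wide.append(res.q975 - res.q025)
    assert wide[1] > wide[0]


# ------------------------------------------------------------ correlations


def test_holm_by_hand():
    adj = holm_adjust(np.array([0.01, 0.04]))
    assert adj[0] == pytest.approx(0.02)
    assert adj[1] == pytest.approx(0.04)
    assert (adj < 0.05).all()


def test_trait_correlation_recovery(scheme_runs):
    hits = 0
    for res in scheme_runs:
        tb = res.tbvs[res.tbvs["population"] == "C0"]
        out = trait_correlations(tb.assign(population="C0"),
                                 ["PH_V4", "PH_V6", "FF"])
        r_v4v6 = out[(out.trait_a == "PH_V4") & (out.trait_b == "PH_V6")]["r"].iloc[0]
        ff_rows = out[(out.trait_b == "FF") | (out.trait_a == "FF")]
        hits += (r_v4v6 > 0.6) and (ff_rows["r"].abs() < 0.25).all()
    assert hits >= 9


def test_self_correlation_one():
    df = pd.DataFrame({"population": "P", "x": np.arange(10.0)})
    df["y"] = df["x"]
    out = trait_correlations(df, ["x", "y"])
    assert out["r"].iloc[0] == pytest.approx(1.0)


# ----------------------------------------------------------------- report


def test_report_tables_structure(scheme_runs):
    tables = report_tables(scheme_runs[0])
    means = tables["population_means"]
    assert len(means) == 14
    c0_row = means[means["population"] == "C0"]
    for t in scheme_runs[0].config.trait_names:
        assert c0_row[t].iloc[0] == pytest.approx(0.0, abs=1e-8)


def test_report_slopes_consistent_with_regression(scheme_runs):
    res = scheme_runs[0]
    tables = report_tables(res)
    slopes = tables["slopes"]
    df = res.gebvs
    dh = df[df["population"].isin([f"C{c}-DH-R1" for c in (1, 2, 3)])]
    fit = response_regression(dh["PH_V4"].to_numpy(), dh["cycle"].to_numpy())
    cell = slopes[(slopes["row"] == "slope C1-DH..C3-DH")
                  & (slopes["replication"] == "R1")]["PH_V4"].iloc[0]
    assert cell == pytest.approx(fit.slope(0), abs=1e-12)


# --------------------------------------------- accuracy-decline mechanism


def test_accuracy_declines_more_for_selected_traits(scheme_runs):
    """Directional selection erodes accuracy in later cycles; the
    uncorrelated trait is much less affected."""
    sel_declines, ff_declines = [], []
    for res in scheme_runs:
        g = res.gebvs.set_index("id")
        t = res.tbvs.set_index("id")
        def acc(pop, trait):
            ids = res.populations[pop].ids
            return np.corrcoef(g.loc[ids, trait], t.loc[ids, trait])[0, 1]
        for rep in ("R1", "R2"):
            base_sel = np.mean([acc("C0r", tr) for tr in ("PH_V4", "PH_V6")])
            late_sel = np.mean([acc(f"C{c}-DH-{rep}", tr)
                                for c in (2, 3) for tr in ("PH_V4", "PH_V6")])
            sel_declines.append(base_sel - late_sel)
            ff_declines.append(acc("C0r", "FF")
                               - np.mean([acc(f"C{c}-DH-{rep}", "FF") for c in (2, 3)]))
    wins = sum(s > f for s, f in zip(sel_declines, ff_declines))
    assert np.mean(sel_declines) > np.mean(ff_declines)
    assert wins >= int(0.7 * len(sel_declines))
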