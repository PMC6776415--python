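"""ANCOVA, permutation inference, MTPC cluster logic, partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tractnet as tn
from tractnet.gstats import _clusters_above
import _oracles as orc


def toy_design(rng, n=24, effect=0.0):
    group = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    Z = pd.DataFrame({"age": rng.uniform(50, 85, n),
                      "sex": rng.integers(0, 2, n)})
    y = rng.normal(size=n) + 0.02 * Z["age"].to_numpy() \
        + effect * (group == "b")
    return y, group, Z


# ---------------------------------------------------------------------------
# ancova_auc
# ---------------------------------------------------------------------------

def test_identical_groups_give_f_zero(rng):
    y = np.ones(12)
    group = ["a"] * 6 + ["b"] * 6
    Z = pd.DataFrame({"c": rng.normal(size=12)})
    res = tn.ancova_auc(y, group, Z)
    assert res.F == 0.0 and res.p == 1.0


def test_parametric_f_matches_statsmodels(rng):
    import statsmodels.api as sm

    y, group, Z = toy_design(rng, effect=0.8)
    res = tn.ancova_auc(y, group, Z, mode="parametric", force_transform="none")
    X = sm.add_constant(np.column_stack([(np.asarray(group) == "b").astype(float),
                                         Z.to_numpy()]))
    fit = sm.OLS(y, X).fit()
    # single-df F test on the group coefficient == squared t
    assert np.isclose(res.F, fit.tvalues[1] ** 2, atol=1e-8)
    assert np.isclose(res.p, fit.pvalues[1], atol=1e-10)
    assert res.df2 == int(fit.df_resid)


def test_parametric_and_permutation_share_f(rng):
    y, group, Z = toy_design(rng, effect=0.5)
    a = tn.ancova_auc(y, group, Z, mode="parametric", force_transform="none")
    b = tn.ancova_auc(y, group, Z, mode="permutation", n_perm=200, seed=0)
    assert np.isclose(a.F, b.F, atol=1e-10)


def test_exhaustive_permutation_matches_bruteforce(rng):
    n = 7
    y = rng.normal(size=n)
    group01 = np.array([0, 0, 0, 1, 1, 1, 1], dtype=float)
    Z = rng.normal(size=(n, 1))
    res = tn.ancova_auc(y, np.where(group01 > 0, "b", "a"),
                        pd.DataFrame({"z": Z[:, 0]}),
                        mode="permutation", n_perm=None)
    F_o, p_o = orc.group_f_exhaustive(y, group01, Z)
    assert np.isclose(res.F, F_o, atol=1e-9)
    assert np.isclose(res.p, p_o, atol=1e-12)


def test_permutation_p_invariant_to_covariate_rescaling(rng):
    y, group, Z = toy_design(rng, effect=0.6)
    p1 = tn.ancova_auc(y, group, Z, mode="permutation", n_perm=500, seed=3).p
    Z2 = Z * 1000.0 + 17.0
    p2 = tn.ancova_auc(y, group, Z2, mode="permutation", n_perm=500, seed=3).p
    assert np.isclose(p1, p2, atol=1e-12)


def test_no_covariate_permutation_equals_permutation_ttest(rng):
    n = 16
    y = rng.normal(size=n)
    group = np.array(["a"] * 8 + ["b"] * 8)
    res = tn.ancova_auc(y, group, None, mode="permutation",
                        n_perm=300, seed=5)
    # replicate: with no covariates the reduced model is the grand mean, so
    # Freedman-Lane reduces to permuting y itself; F* >= F <=> |t*| >= |t|
    gvec = (group == "b").astype(float)
    rng2 = np.random.default_rng(5)
    tobs = sps.ttest_ind(y[gvec == 1], y[gvec == 0]).statistic
    fitted = np.full(n, y.mean())
    resid = y - fitted
    count = 0
    done = 0
    while done < 300:
        m = min(2000, 300 - done)
        idx = np.argsort(rng2.random((m, n)), axis=1)
        for row in idx:
            ys = fitted + resid[row]
            tstar = sps.ttest_ind(ys[gvec == 1], ys[gvec == 0]).statistic
            if tstar ** 2 >= tobs ** 2 - 1e-12:
                count += 1
        done += m
    assert np.isclose(res.p, (count + 1) / 301, atol=1e-12)


def test_log10_screen_engages_for_skewed_data(rng):
    n = 40
    group = np.array(["a"] * 20 + ["b"] * 20)
    y = 10 ** rng.normal(size=n)  # lognormal: log10 restores gaussianity
    res = tn.ancova_auc(y, group, None, mode="parametric")
    assert res.transform == "log10"


def test_singular_design_names_column(rng):
    y, group, Z = toy_design(rng)
    Z["age_copy"] = Z["age"]
    with pytest.raises(ValueError, match="age"):
        tn.ancova_auc(y, group, Z)


def test_type_one_error_calibrated(rng):
    """Permutation ANCOVA under the null rejects at ~alpha."""
    n_rep = 400
    hits = 0
    for rep in range(n_rep):
        r = np.random.default_rng(10_000 + rep)
        y, group, Z = toy_design(r, n=20, effect=0.0)
        p = tn.ancova_auc(y, group, Z, mode="permutation", n_perm=199,
                          seed=rep).p
        hits += p <= 0.05
    lo, hi = sps.binom.ppf([0.025, 0.975], n_rep, 0.05)
    assert lo <= hits <= hi


# ---------------------------------------------------------------------------
# MTPC
# ---------------------------------------------------------------------------

def test_mtpc_cluster_run_length_rule():
    absT = np.array([1, 3, 3, 1, 3, 3, 3, 1], dtype=float)
    x = np.arange(8, dtype=float)
    cl = _clusters_above(absT, 2.0, cluster_min=3, x=x, area="above_critical")
    assert len(cl) == 1 and (cl[0].start, cl[0].end) == (4, 6)
    cl1 = _clusters_above(absT, 2.0, cluster_min=1, x=x, area="above_critical")
    assert len(cl1) == 2  # the 2-run now counts
    assert all(c.end - c.start + 1 >= 3 or (c.start, c.end) == (1, 2)
               for c in cl1)


def test_mtpc_cluster_area_variants():
    absT = np.array([0, 3, 3, 3, 0], dtype=float)
    x = np.arange(5, dtype=float)
    above = _clusters_above(absT, 2.0, 3, x, "above_critical")[0].auc_mtpc
    full = _clusters_above(absT, 2.0, 3, x, "full")[0].auc_mtpc
    assert np.isclose(above, 2.0)  # (3-2) over 2 threshold steps
    assert np.isclose(full, 6.0)


def test_mtpc_null_data_not_significant(rng):
    Y = rng.normal(size=(30, 20))
    group = ["a"] * 15 + ["b"] * 15
    r = tn.mtpc(Y, group, None, n_perm=300, seed=1)
    assert r.p_fwe > 0.05 or not r.significant
    assert r.critical > 0 and 0 < r.p_fwe <= 1


def test_mtpc_detects_broad_injected_effect(rng):
    Y = rng.normal(size=(40, 20))
    Y[20:] += 1.5  # group shift at every threshold
    group = ["a"] * 20 + ["b"] * 20
    r = tn.mtpc(Y, group, None, n_perm=500, seed=2)
    assert r.significant and r.p_fwe < 0.01
    assert len(r.clusters) >= 1
    assert max(c.end - c.start + 1 for c in r.clusters) >= 3


def test_mtpc_two_threshold_run_is_not_a_cluster(rng):
    Y = rng.normal(size=(40, 12)) * 0.3
    Y[20:, 5:7] += 4.0  # strong but only 2 consecutive thresholds
    group = ["a"] * 20 + ["b"] * 20
    r = tn.mtpc(Y, group, None, n_perm=400, seed=3)
    assert len(r.clusters) == 0 and not r.significant
    assert r.p_fwe < 0.05  # the peak itself is supra-critical


def test_mtpc_warns_on_tiny_n_perm(rng):
    Y = rng.normal(size=(12, 5))
    with pytest.warns(UserWarning):
        tn.mtpc(Y, ["a"] * 6 + ["b"] * 6, None, n_perm=50, seed=0)


# ---------------------------------------------------------------------------
# partial Spearman
# ---------------------------------------------------------------------------

def test_monotone_association_gives_rho_one(rng):
    x = rng.uniform(0, 10, 30)
    y = np.exp(x) + 5
    r = tn.partial_spearman(x, y)
    assert np.isclose(r.rho, 1.0) and r.p < 1e-10
    assert r.df == 28


def test_confound_removal(rng):
    n = 200
    c = rng.normal(size=n)
    x = 2 * c + rng.normal(size=n) * 0.4
    y = -3 * c + rng.normal(size=n) * 0.4
    raw = tn.partial_spearman(x, y)
    adj = tn.partial_spearman(x, y, pd.DataFrame({"c": c}))
    assert abs(raw.rho) > 0.6
    assert abs(adj.rho) < 0.15
    assert adj.df == n - 3


def test_partial_spearman_matches_bruteforce_and_pingouin(rng):
    n = 10
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    Z = rng.normal(size=(n, 2))
    r = tn.partial_spearman(x, y, pd.DataFrame(Z, columns=["a", "b"]))
    assert np.isclose(r.rho, orc.partial_spearman(x, y, Z), atol=1e-12)
    import pingouin as pg
    df = pd.DataFrame({"x": x, "y": y, "a": Z[:, 0], "b": Z[:, 1]})
    out = pg.partial_corr(df, x="x", y="y", covar=["a", "b"],
                          method="spearman")
    assert np.isclose(r.rho, out["r"].iloc[0], atol=1e-9)


def test_pairwise_deletion_counts(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    x[[2, 5]] = np.nan
    y[[5, 7]] = np.nan
    r = tn.partial_spearman(x, y)
    assert r.n_used == 17 and r.df == 15


def test_constant_input_rejected():
    with pytest.raises(ValueError):
        tn.partial_spearman(np.ones(10), np.arange(10.0))


# ---------------------------------------------------------------------------
# bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_worked_values():
    assert tn.bonferroni(0.01, 5) == 0.05
    assert tn.bonferroni(0.4, 5) == 1.0
    assert tn.bonferroni(0.123, 1) == 0.123
    assert np.allclose(tn.bonferroni(np.array([0.01, 0.4]), 5), [0.05, 1.0])
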