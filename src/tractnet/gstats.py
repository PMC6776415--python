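"""Group statistics on AUC summaries and metric curves.

* ANCOVA on per-subject AUC values: group F-test adjusting for covariates,
  either parametric (with an automated residual-normality screen deciding a
  log10 transform) or by Freedman-Lane residual permutation (default 10000
  permutations, as run by FSL randomise).
* Point-by-point curve comparison with multi-threshold permutation correction
  (MTPC): per-threshold group t statistics, a max-|t| permutation null giving
  the FWE-adjusted critical value, and a cluster rule requiring at least
  ``cluster_min`` consecutive supra-critical thresholds whose above-critical
  area exceeds the mean such area under the null.
* Partial Spearman correlations (rank regression residuals) with pairwise
  deletion, and Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AUCStatResult",
    "MTPCResult",
    "CorrelationResult",
    "ancova_auc",
    "mtpc",
    "partial_spearman",
    "bonferroni",
    "covariate_preset",
    "demographics_table",
]


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------

def _as_group(group) -> np.ndarray:
    g = np.asarray(group)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("group must have exactly two levels")
    return (g == levels[1]).astype(float)


def _covariate_matrix(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        Z = covariates.to_numpy(dtype=float)
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        names = [f"cov{j}" for j in range(Z.shape[1])]
    if Z.shape[0] != n:
        raise ValueError("covariate rows must match number of subjects")
    return Z, names


def _check_singular(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == r:
                raise ValueError(f"singular design: column '{names[j]}' is collinear")
        raise ValueError("singular design")


def _group_f(y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray
             ) -> tuple[float, int, int]:
    """F statistic for the group column (the one column X_full adds to X_red)."""
    n = len(y)
    df2 = n - X_full.shape[1]
    b_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(((y - X_full @ b_full) ** 2).sum())
    b_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_red = float(((y - X_red @ b_red) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    # constant outcome: no variance to test
    if df2 <= 0 or tss <= 1e-20 * max(float(np.sum(y * y)), 1.0):
        return 0.0, 1, max(df2, 0)
    if rss_full == 0.0:  # perfect full-model fit of a non-constant outcome
        return np.inf, 1, df2
    F = (rss_red - rss_full) / (rss_full / df2)
    return max(F, 0.0), 1, df2


def _gaussian_enough(resid: np.ndarray, skew_cut: float = 1.0,
                     kurt_cut: float = 2.0) -> bool:
    if len(resid) < 8:
        return True
    return (abs(sps.skew(resid)) <= skew_cut
            and abs(sps.kurtosis(resid)) <= kurt_cut)


# ---------------------------------------------------------------------------
# AUC ANCOVA
# ---------------------------------------------------------------------------

@dataclass
class AUCStatResult:
    metric: str
    F: float
    df1: int
    df2: int
    p: float
    p_bonferroni: float
    kind: str            # "parametric" | "permutation"
    transform: str       # "none" | "log10"
    n_perm: int = 0
    seed: Optional[int] = None


def _tfun(X_full: np.ndarray, gcol: int = 1):
    """Precompiled group-t evaluator for many outcome columns at once."""
    n, p = X_full.shape
    pinv = np.linalg.pinv(X_full)
    c = np.linalg.inv(X_full.T @ X_full)[gcol, gcol]
    df = n - p

    def tstat(Y: np.ndarray) -> np.ndarray:
        B = pinv @ Y
        R = Y - X_full @ B
        sigma2 = (R ** 2).sum(axis=0) / df
        se = np.sqrt(np.maximum(sigma2 * c, 1e-300))
        return B[gcol] / se

    return tstat, df


def _freedman_lane_f(y, X_full, X_red, n_perm, rng) -> tuple[float, float, int, int]:
    """Observed group F and its Freedman-Lane permutation p-value.

    Residuals of the reduced (covariates-only) model are permuted, added back
    to the reduced fit, and the full-model group F recomputed.  With
    ``n_perm=None`` all n! label permutations are enumerated and p is the
    exact fraction (identity included); otherwise p uses the
    (b + 1) / (m + 1) convention over random permutations.
    """
    F_obs, df1, df2 = _group_f(y, X_full, X_red)
    b_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    fitted = X_red @ b_red
    resid = y - fitted
    n = len(y)
    tstat, _ = _tfun(X_full)
    if n_perm is None:
        from itertools import permutations
        perms = np.array(list(permutations(range(n))))
        Y_star = fitted[:, None] + resid[perms].T
        F_star = tstat(Y_star) ** 2
        p = float(np.mean(F_star >= F_obs - 1e-12))
        return F_obs, p, df1, df2
    # batched random permutations
    batch = 2000
    count = 0
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        Y_star = fitted[:, None] + resid[idx].T
        F_star = tstat(Y_star) ** 2
        count += int(np.sum(F_star >= F_obs - 1e-12))
        done += m
    p = (count + 1) / (n_perm + 1)
    return F_obs, p, df1, df2


def ancova_auc(auc, group, covariates=None, mode: str = "parametric",
               n_perm: int = 10000, seed: Optional[int] = None,
               m_comparisons: int = 1, metric: str = "",
               force_transform: Optional[str] = None) -> AUCStatResult:
    """Group ANCOVA on per-subject AUC values.

    mode="parametric" fits AUC ~ group + covariates by OLS and tests the
    group term with an F test; if the full-model residuals fail a
    skew/kurtosis screen and all values are positive, the model is refit on
    log10(AUC).  mode="permutation" reports the same F with a Freedman-Lane
    permutation p-value.
    """
    y = np.asarray(auc, dtype=float)
    n = len(y)
    gvec = _as_group(group)
    if min((gvec == 0).sum(), (gvec == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    Z, znames = _covariate_matrix(covariates, n)
    if np.isnan(Z).any() or np.isnan(y).any():
        raise ValueError("ANCOVA requires complete data (listwise)")
    X_red = np.column_stack([np.ones(n), Z])
    X_full = np.column_stack([np.ones(n), gvec, Z])
    _check_singular(X_full, ["intercept", "group"] + znames)

    transform = "none"
    if mode == "parametric":
        if force_transform in ("none", "log10"):
            transform = force_transform
            if transform == "log10":
                y = np.log10(y)
        else:
            b, *_ = np.linalg.lstsq(X_full, y, rcond=None)
            if not _gaussian_enough(y - X_full @ b) and np.all(y > 0):
                ylog = np.log10(y)
                blog, *_ = np.linalg.lstsq(X_full, ylog, rcond=None)
                if _gaussian_enough(ylog - X_full @ blog):
                    y, transform = ylog, "log10"
        F, df1, df2 = _group_f(y, X_full, X_red)
        p = float(sps.f.sf(F, df1, df2)) if df2 > 0 else 1.0
        if F == 0.0:
            p = 1.0
        return AUCStatResult(metric=metric, F=F, df1=df1, df2=df2, p=p,
                             p_bonferroni=bonferroni(p, m_comparisons),
                             kind="parametric", transform=transform)
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        F, p, df1, df2 = _freedman_lane_f(y, X_full, X_red, n_perm, rng)
        return AUCStatResult(metric=metric, F=F, df1=df1, df2=df2, p=p,
                             p_bonferroni=bonferroni(p, m_comparisons),
                             kind="permutation", transform="none",
                             n_perm=n_perm or 0, seed=seed)
    raise ValueError("mode must be 'parametric' or 'permutation'")


# ---------------------------------------------------------------------------
# MTPC
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int
    end: int              # inclusive threshold indices
    auc_mtpc: float


@dataclass
class MTPCResult:
    t: np.ndarray                 # per-threshold group t
    t_max: float                  # signed t with the largest |t|
    tau: float                    # threshold value at the peak
    tau_index: int
    p_fwe: float
    critical: float               # FWE-adjusted two-tailed critical |t|
    clusters: list = field(default_factory=list)
    auc_crit: float = 0.0
    significant: bool = False
    df: int = 0
    n_perm: int = 0
    cluster_min: int = 3
    seed: Optional[int] = None


def _clusters_above(absT: np.ndarray, critical: float, cluster_min: int,
                    x: np.ndarray, area: str) -> list[Cluster]:
    out: list[Cluster] = []
    above = absT > critical
    i = 0
    T = len(absT)
    while i < T:
        if above[i]:
            j = i
            while j + 1 < T and above[j + 1]:
                j += 1
            if j - i + 1 >= cluster_min:
                seg = slice(i, j + 1)
                if area == "above_critical":
                    a = float(np.trapezoid(absT[seg] - critical, x[seg]))
                else:
                    a = float(np.trapezoid(absT[seg], x[seg]))
                out.append(Cluster(start=i, end=j, auc_mtpc=a))
            i = j + 1
        else:
            i += 1
    return out


def mtpc(Y, group, covariates=None, n_perm: int = 1000,
         cluster_min: int = 3, seed: Optional[int] = None,
         alpha: float = 0.05, thresholds: Optional[np.ndarray] = None,
         cluster_area: str = "above_critical") -> MTPCResult:
    """Point-by-point group comparison with multi-threshold permutation
    correction.

    Y is the subjects x thresholds curve matrix.  Per-threshold t statistics
    come from the covariate-adjusted OLS model; Freedman-Lane permutations of
    the reduced-model residuals give the null distribution of max |t| across
    thresholds, whose (1 - alpha) quantile is the FWE critical value.
    Observed runs of >= cluster_min consecutive supra-critical thresholds
    form clusters with area AUC_MTPC (of |t| above the critical value by
    default; cluster_area="full" integrates |t| itself); AUC_crit is the
    mean such null-cluster area.  A result is significant iff a cluster
    exists and its area exceeds AUC_crit.
    """
    import warnings

    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    if thresholds is None:
        thresholds = np.arange(1, T + 1, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse FWE estimate")
    gvec = _as_group(group)
    Z, znames = _covariate_matrix(covariates, n)
    X_red = np.column_stack([np.ones(n), Z])
    X_full = np.column_stack([np.ones(n), gvec, Z])
    _check_singular(X_full, ["intercept", "group"] + znames)
    df = n - X_full.shape[1]
    if df <= 0:
        raise ValueError("degenerate design: no residual degrees of freedom")

    tstat, _ = _tfun(X_full)
    t_obs = tstat(Y)
    rng = np.random.default_rng(seed)
    b_red, *_ = np.linalg.lstsq(X_red, Y, rcond=None)
    fitted = X_red @ b_red
    resid = Y - fitted
    null_T = np.empty((n_perm, T))
    for b in range(n_perm):
        null_T[b] = tstat(fitted + resid[rng.permutation(n)])
    max_null = np.abs(null_T).max(axis=1)
    critical = float(np.quantile(max_null, 1 - alpha))
    absT = np.abs(t_obs)
    peak = int(absT.argmax())
    t_max = float(t_obs[peak])
    p_fwe = float((np.sum(max_null >= absT[peak] - 1e-12) + 1) / (n_perm + 1))

    clusters = _clusters_above(absT, critical, cluster_min, thresholds,
                               cluster_area)
    null_areas: list[float] = []
    for b in range(n_perm):
        for cl in _clusters_above(np.abs(null_T[b]), critical, cluster_min,
                                  thresholds, cluster_area):
            null_areas.append(cl.auc_mtpc)
    auc_crit = float(np.mean(null_areas)) if null_areas else 0.0
    significant = any(cl.auc_mtpc > auc_crit for cl in clusters)
    return MTPCResult(t=t_obs, t_max=t_max, tau=float(thresholds[peak]),
                      tau_index=peak, p_fwe=p_fwe, critical=critical,
                      clusters=clusters, auc_crit=auc_crit,
                      significant=significant, df=df, n_perm=n_perm,
                      cluster_min=cluster_min, seed=seed)


# ---------------------------------------------------------------------------
# Partial Spearman
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    pair: tuple
    rho: float
    df: int
    p: float
    p_bonferroni: float
    n_used: int


def partial_spearman(x, y, covariates=None, m_comparisons: int = 1,
                     pair: tuple = ("x", "y")) -> CorrelationResult:
    """Partial Spearman correlation via rank-regression residuals.

    Ranks x, y and covariates (average ranks for ties), removes the linear
    effect of covariate ranks from both rank vectors, and correlates the
    residuals; df = n - 2 - n_covariates.  Rows with any missing value in
    x, y or the covariates are dropped (pairwise deletion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n0 = len(x)
    Z, _ = _covariate_matrix(covariates, n0)
    keep = np.isfinite(x) & np.isfinite(y)
    if Z.shape[1]:
        keep &= np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[keep], y[keep], Z[keep]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rZ = np.column_stack([np.ones(n)]
                         + [sps.rankdata(Z[:, j]) for j in range(Z.shape[1])])
    bx, *_ = np.linalg.lstsq(rZ, rx, rcond=None)
    by, *_ = np.linalg.lstsq(rZ, ry, rcond=None)
    ex = rx - rZ @ bx
    ey = ry - rZ @ by
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - Z.shape[1]
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        tstat = rho * np.sqrt(df / (1 - rho ** 2))
        p = float(2 * sps.t.sf(abs(tstat), df))
    return CorrelationResult(pair=pair, rho=rho, df=df, p=p,
                             p_bonferroni=bonferroni(p, m_comparisons),
                             n_used=n)


def bonferroni(p, m: int):
    """p_adj = min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m) if np.ndim(p) \
        else float(min(1.0, p * m))


# ---------------------------------------------------------------------------
# Covariate presets (age and sex always; TIV for the length-adjusted
# strategy, which carries no head-size correction of its own; pre-morbid IQ
# for cognition correlations)
# ---------------------------------------------------------------------------

def covariate_preset(table: pd.DataFrame, strategy: str = "length_adjusted",
                     cognition: bool = False) -> pd.DataFrame:
    cols = ["age", "sex"]
    if strategy == "length_adjusted":
        cols.append("TIV")
    if cognition:
        cols.append("premorbid_IQ")
    return table[cols]


# ---------------------------------------------------------------------------
# Convenience demographics report (t / chi-square / Mann-Whitney); a side
# table, not part of the network analyses
# ---------------------------------------------------------------------------

def demographics_table(table: pd.DataFrame,
                       continuous: Sequence[str] = ("age", "TIV",
                                                    "premorbid_IQ"),
                       binary: Sequence[str] = ("sex",)) -> pd.DataFrame:
    g = _as_group(table["group"])
    rows = []
    for col in continuous:
        a = table.loc[g == 0, col].dropna()
        b = table.loc[g == 1, col].dropna()
        t, p = sps.ttest_ind(a, b)
        rows.append({"variable": col, "test": "t", "stat": t, "p": p})
    for col in binary:
        ct = pd.crosstab(table["group"], table[col])
        chi2, p, _, _ = sps.chi2_contingency(ct)
        rows.append({"variable": col, "test": "chi2", "stat": chi2, "p": p})
    return pd.DataFrame(rows)
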