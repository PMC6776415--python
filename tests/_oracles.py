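"""Independent brute-force oracles for graph metrics and statistics.

Everything here is written directly from the metric definitions using naive
enumeration (Floyd-Warshall loops, explicit triangle scans, shortest-path
counting by distance decomposition) so tests compare two unrelated code
paths.  Intended for tiny graphs (n <= ~10).
"""

import itertools

import numpy as np

INF = float("inf")


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths; lengths[i][j] <= 0 means no edge."""
    n = lengths.shape[0]
    D = np.full((n, n), INF)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(n):
            if i != j and lengths[i, j] > 0:
                D[i, j] = lengths[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def _length_matrix(w_hat: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        with np.errstate(divide="ignore"):
            return np.where(w_hat > 0, 1.0 / w_hat, 0.0)
    return (w_hat > 0).astype(float)


def degree_strength(w_hat):
    a = (np.asarray(w_hat) > 0).astype(float)
    k = np.array([sum(a[i, j] for j in range(a.shape[0])) for i in range(a.shape[0])])
    kw = np.array([sum(w_hat[i, j] for j in range(a.shape[0]))
                   for i in range(a.shape[0])])
    return k, kw


def clustering(w_hat):
    """Triangle scan: unweighted count and cube-root weighted intensity."""
    n = w_hat.shape[0]
    a = (w_hat > 0).astype(float)
    C = np.zeros(n)
    Cw = np.zeros(n)
    for i in range(n):
        k = int(a[i].sum())
        if k < 2:
            continue
        t = tw = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    t += a[i, j] * a[i, h] * a[j, h]
                    tw += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        C[i] = t / (k * (k - 1))        # ordered (j,h) pairs = 2*t_i
        Cw[i] = tw / (k * (k - 1))
    return C, Cw


def efficiency_pathlength(w_hat, weighted: bool):
    D = floyd_warshall(_length_matrix(w_hat, weighted))
    n = D.shape[0]
    E = np.zeros(n)
    L = np.full(n, np.nan)
    for i in range(n):
        invs = [1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j]) and D[i, j] > 0]
        E[i] = sum(invs) / (n - 1)
        fin = [D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j])]
        if fin:
            L[i] = sum(fin) / len(fin)
    return E, L


def local_efficiency(w_hat):
    """Neighbourhood-subgraph efficiency; weighted per the cube-root
    convention (paths on cube-rooted inverse weights, pairs weighted by the
    cube root of incident weights)."""
    n = w_hat.shape[0]
    a = (w_hat > 0).astype(float)
    El = np.zeros(n)
    Elw = np.zeros(n)
    for u in range(n):
        nb = [j for j in range(n) if a[u, j]]
        k = len(nb)
        if k < 2:
            continue
        sub = w_hat[np.ix_(nb, nb)]
        Dn = floyd_warshall((sub > 0).astype(float))
        El[u] = sum(1.0 / Dn[x, y] for x in range(k) for y in range(k)
                    if x != y and np.isfinite(Dn[x, y]) and Dn[x, y] > 0) / (k * (k - 1))
        with np.errstate(divide="ignore"):
            lsub = np.where(sub > 0, (1.0 / sub) ** (1 / 3), 0.0)
        Dnw = floyd_warshall(lsub)
        acc = 0.0
        for x in range(k):
            for y in range(k):
                if x != y and np.isfinite(Dnw[x, y]) and Dnw[x, y] > 0:
                    acc += (w_hat[u, nb[x]] * w_hat[u, nb[y]]) ** (1 / 3) / Dnw[x, y]
        Elw[u] = acc / (k * (k - 1))
    return El, Elw


def betweenness(w_hat, weighted: bool, tol: float = 1e-12):
    """Shortest-path counting via the distance decomposition
    sigma_st(v) = sigma_sv * sigma_vt iff d_sv + d_vt = d_st."""
    n = w_hat.shape[0]
    lengths = _length_matrix(w_hat, weighted)
    D = floyd_warshall(lengths)
    # sigma[s][t]: number of shortest s-t paths, by Dijkstra-free recursion:
    sigma = np.zeros((n, n))
    order = {}
    for s in range(n):
        sigma[s, s] = 1.0
        # process targets in increasing distance
        targets = sorted((t for t in range(n) if t != s and np.isfinite(D[s, t])),
                         key=lambda t: D[s, t])
        for t in targets:
            tot = 0.0
            for u in range(n):
                if u != t and lengths[u, t] > 0 and np.isfinite(D[s, u]) \
                        and abs(D[s, u] + lengths[u, t] - D[s, t]) <= tol:
                    tot += sigma[s, u]
            sigma[s, t] = tot
    b = np.zeros(n)
    for v in range(n):
        acc = 0.0
        for s in range(n):
            for t in range(n):
                if s != t and s != v and t != v and np.isfinite(D[s, t]) \
                        and sigma[s, t] > 0:
                    if abs(D[s, v] + D[v, t] - D[s, t]) <= tol:
                        acc += sigma[s, v] * sigma[v, t] / sigma[s, t]
        b[v] = acc / ((n - 1) * (n - 2))
    return b


def partial_spearman(x, y, Z):
    """Rank everything, regress ranks on covariate ranks, correlate residuals."""
    from scipy.stats import rankdata

    n = len(x)
    rx, ry = rankdata(x), rankdata(y)
    X = np.ones((n, 1))
    if Z is not None and Z.size:
        X = np.column_stack([X] + [rankdata(Z[:, j]) for j in range(Z.shape[1])])
    hx = X @ np.linalg.lstsq(X, rx, rcond=None)[0]
    hy = X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    ex, ey = rx - hx, ry - hy
    return float(np.sum(ex * ey) / np.sqrt(np.sum(ex ** 2) * np.sum(ey ** 2)))


def group_f_exhaustive(y, group01, Z):
    """Exact Freedman-Lane permutation p over all n! residual permutations."""
    n = len(y)
    X_red = np.column_stack([np.ones(n)] + ([Z] if Z is not None and Z.size else []))
    X_full = np.column_stack([X_red[:, :1], group01, X_red[:, 1:]])

    def f_of(yv):
        bf, *_ = np.linalg.lstsq(X_full, yv, rcond=None)
        rss_f = ((yv - X_full @ bf) ** 2).sum()
        br, *_ = np.linalg.lstsq(X_red, yv, rcond=None)
        rss_r = ((yv - X_red @ br) ** 2).sum()
        df2 = n - X_full.shape[1]
        return (rss_r - rss_f) / (rss_f / df2)

    br, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    fitted = X_red @ br
    resid = y - fitted
    F_obs = f_of(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if f_of(fitted + resid[list(perm)]) >= F_obs - 1e-12:
            count += 1
    return F_obs, count / total
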