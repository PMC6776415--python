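"""Weighted and unweighted graph metrics for structural brain networks.

All weighted metrics operate on weights normalised by the maximum weight in
the network (w_hat in [0, 1]); weighted shortest-path lengths are sums of
inverse normalised weights.  Conventions follow the Brain Connectivity
Toolbox (Rubinov & Sporns):

* weighted clustering uses cube-root geometric-mean triangle intensities;
* weighted local efficiency uses cube-root weighting on the neighbourhood
  subgraph;
* betweenness is normalised by (n-1)(n-2) (a strict_print flag exposes the
  (n-1)^2 variant some sources print);
* small-worldness S = (C/C_rand)/(L/L_rand) against degree-preserving
  Maslov-Sneppen rewired nulls (weights carried with swapped edges).

Disconnected node pairs contribute zero to efficiencies and are excluded
from characteristic path length averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Graph",
    "NodalMetrics",
    "SmallWorldResult",
    "normalise",
    "degree_strength",
    "clustering",
    "efficiency_pathlength",
    "local_efficiency",
    "betweenness",
    "small_worldness",
    "nodal_metrics",
    "global_metrics",
]


# ---------------------------------------------------------------------------
# Graph container
# ---------------------------------------------------------------------------

@dataclass
class Graph:
    """Symmetric zero-diagonal network with max-normalised weights."""

    a: np.ndarray       # binary adjacency (int8)
    w_hat: np.ndarray   # normalised weights in [0, 1]

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.a, 1).sum())


def normalise(weights: np.ndarray) -> Graph:
    """Build a Graph, dividing weights by the maximum weight in the network.

    An empty network yields all-zero normalised weights (no error).
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(W < 0):
        raise ValueError("negative weights")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    a = (W > 0).astype(np.int8)
    wmax = W.max()
    w_hat = W / wmax if wmax > 0 else W
    return Graph(a=a, w_hat=w_hat)


def _as_graph(g) -> Graph:
    return g if isinstance(g, Graph) else normalise(g)


# ---------------------------------------------------------------------------
# Degree / strength
# ---------------------------------------------------------------------------

def degree_strength(g) -> tuple[np.ndarray, np.ndarray]:
    """Nodal degree k_i (row sums of a) and strength k_i^w (row sums of w_hat)."""
    g = _as_graph(g)
    return g.a.sum(axis=1).astype(float), g.w_hat.sum(axis=1)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def clustering(g) -> tuple[np.ndarray, np.ndarray]:
    """Nodal clustering coefficients, unweighted and weighted.

    C_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangle count; the weighted
    triangle intensity replaces each triangle by the cube root of its weight
    product.  Nodes with degree < 2 score 0.
    """
    g = _as_graph(g)
    A = g.a.astype(float)
    k = A.sum(axis=1)
    t = np.diag(A @ A @ A) / 2.0
    W3 = np.cbrt(g.w_hat)
    tw = np.diag(W3 @ W3 @ W3) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, 2 * t / denom, 0.0)
        Cw = np.where(denom > 0, 2 * tw / denom, 0.0)
    return C, Cw


# ---------------------------------------------------------------------------
# Shortest-path based metrics
# ---------------------------------------------------------------------------

def _distances(g: Graph) -> tuple[np.ndarray, np.ndarray]:
    """(hop-count distances, inverse-weight distances); inf when disconnected."""
    D = shortest_path(g.a, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        lengths = np.where(g.w_hat > 0, 1.0 / g.w_hat, 0.0)
    Dw = shortest_path(lengths, method="D", directed=False)
    return D, Dw


def _eff_from_dist(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node efficiency and path length from a distance matrix."""
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(off & np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    E = inv.sum(axis=1) / (n - 1)
    finite = off & np.isfinite(D)
    cnt = finite.sum(axis=1)
    tot = np.where(finite, D, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        L = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return E, L


def efficiency_pathlength(g) -> dict:
    """Nodal and global efficiency / characteristic path length.

    Unweighted distances count hops; weighted distances sum 1/w_hat along the
    path.  Disconnected pairs add 0 to efficiency and are excluded from L.
    """
    g = _as_graph(g)
    D, Dw = _distances(g)
    E, L = _eff_from_dist(D)
    Ew, Lw = _eff_from_dist(Dw)
    return {
        "E": E, "L": L, "Ew": Ew, "Lw": Lw,
        "E_global": float(E.mean()),
        "L_global": float(np.nanmean(L)) if not np.all(np.isnan(L)) else np.nan,
        "Ew_global": float(Ew.mean()),
        "Lw_global": float(np.nanmean(Lw)) if not np.all(np.isnan(Lw)) else np.nan,
    }


def local_efficiency(g) -> tuple[np.ndarray, np.ndarray]:
    """Nodal local efficiency (efficiency of the neighbourhood subgraph).

    Weighted form per the Brain Connectivity Toolbox: shortest paths on the
    neighbourhood with cube-rooted inverse-weight lengths, each pair weighted
    by the cube root of the two incident connection weights, normalised by
    k_i (k_i - 1).  Nodes with degree < 2 score 0.
    """
    g = _as_graph(g)
    n = g.n_nodes
    Eloc = np.zeros(n)
    Elocw = np.zeros(n)
    with np.errstate(divide="ignore"):
        lengths = np.where(g.w_hat > 0, 1.0 / g.w_hat, 0.0)
    for u in range(n):
        nb = np.flatnonzero(g.a[u])
        k = len(nb)
        if k < 2:
            continue
        sub = g.a[np.ix_(nb, nb)]
        Dn = shortest_path(sub, method="D", unweighted=True, directed=False)
        off = ~np.eye(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv = np.where(off & np.isfinite(Dn) & (Dn > 0), 1.0 / Dn, 0.0)
        Eloc[u] = inv.sum() / (k * (k - 1))
        # weighted: cube-root lengths on the neighbourhood subgraph
        subl = np.cbrt(lengths[np.ix_(nb, nb)])
        Dnw = shortest_path(subl, method="D", directed=False)
        with np.errstate(divide="ignore"):
            invw = np.where(off & np.isfinite(Dnw) & (Dnw > 0), 1.0 / Dnw, 0.0)
        sw = np.cbrt(g.w_hat[u, nb])
        Elocw[u] = (np.outer(sw, sw) * invw).sum() / (k * (k - 1))
    return Eloc, Elocw


# ---------------------------------------------------------------------------
# Betweenness
# ---------------------------------------------------------------------------

def betweenness(g, strict_print: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Nodal betweenness centrality, unweighted and weighted (1/w_hat lengths).

    Normalised by (n-1)(n-2) over ordered source-target pairs, so a path
    centre scores 1.  ``strict_print=True`` uses (n-1)^2 instead.
    """
    g = _as_graph(g)
    n = g.n_nodes
    if n < 3:
        return np.zeros(n), np.zeros(n)
    G = nx.from_numpy_array(g.a.astype(float))
    bc = nx.betweenness_centrality(G, normalized=True)
    b = np.array([bc[i] for i in range(n)])
    Gw = nx.Graph()
    Gw.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(g.w_hat, 1))
    for i, j in zip(iu, ju):
        Gw.add_edge(int(i), int(j), dist=1.0 / g.w_hat[i, j])
    bcw = nx.betweenness_centrality(Gw, weight="dist", normalized=True)
    bw = np.array([bcw[i] for i in range(n)])
    if strict_print:
        factor = (n - 2) / (n - 1)
        b, bw = b * factor, bw * factor
    return b, bw


# ---------------------------------------------------------------------------
# Small-worldness
# ---------------------------------------------------------------------------

@dataclass
class SmallWorldResult:
    S: float
    Sw: Optional[float]
    C: float
    L: float
    Cw: Optional[float]
    Lw: Optional[float]
    C_rand: float
    L_rand: float
    Cw_rand: Optional[float]
    Lw_rand: Optional[float]
    n_null: int
    seed: Optional[int]


def _rewire(w_hat: np.ndarray, rng: np.random.Generator,
            n_attempts: int) -> np.ndarray:
    """Maslov-Sneppen double-edge swaps; weights travel with swapped edges."""
    n = w_hat.shape[0]
    iu, ju = np.nonzero(np.triu(w_hat, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    weights = [w_hat[i, j] for i, j in edges]
    present = set(edges)
    m = len(edges)
    if m < 2:
        return w_hat.copy()
    for _ in range(n_attempts):
        e1, e2 = rng.integers(m), rng.integers(m)
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if len({a, b, c, d}) < 4:
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in present or n2 in present:
            continue
        present.discard(edges[e1])
        present.discard(edges[e2])
        present.add(n1)
        present.add(n2)
        edges[e1], edges[e2] = n1, n2
    out = np.zeros_like(w_hat)
    for (i, j), w in zip(edges, weights):
        out[i, j] = out[j, i] = w
    return out


def _cl_pair(g: Graph, weighted: bool) -> tuple[float, float, float, float]:
    C, Cw = clustering(g)
    ep = efficiency_pathlength(g)
    if weighted:
        return float(C.mean()), ep["L_global"], float(Cw.mean()), ep["Lw_global"]
    return float(C.mean()), ep["L_global"], np.nan, np.nan


def small_worldness(g, n_null: int = 100, seed: Optional[int] = None,
                    include_weighted: bool = True,
                    swaps_per_edge: int = 10) -> SmallWorldResult:
    """Small-worldness S = (C/C_rand) / (L/L_rand) against rewired nulls.

    Nulls are degree-preserving double-edge-swap randomisations
    (``swaps_per_edge`` x |E| attempts each); the weighted variant carries
    edge weights with the swaps.  Means over ``n_null`` nulls; seeded.
    """
    g = _as_graph(g)
    if g.n_edges < 4:
        raise ValueError("need at least 4 edges to rewire")
    rng = np.random.default_rng(seed)
    C, L, Cw, Lw = _cl_pair(g, include_weighted)
    n_attempts = swaps_per_edge * g.n_edges
    Cr, Lr, Cwr, Lwr = [], [], [], []
    for _ in range(n_null):
        wn = _rewire(g.w_hat, rng, n_attempts)
        gn = Graph(a=(wn > 0).astype(np.int8), w_hat=wn)
        c, l, cw, lw = _cl_pair(gn, include_weighted)
        Cr.append(c)
        Lr.append(l)
        Cwr.append(cw)
        Lwr.append(lw)
    C_rand, L_rand = float(np.mean(Cr)), float(np.nanmean(Lr))
    S = (C / C_rand) / (L / L_rand) if C_rand > 0 and L_rand > 0 else np.nan
    if include_weighted:
        Cw_rand, Lw_rand = float(np.mean(Cwr)), float(np.nanmean(Lwr))
        Sw = ((Cw / Cw_rand) / (Lw / Lw_rand)
              if Cw_rand > 0 and Lw_rand > 0 else np.nan)
    else:
        Cw_rand = Lw_rand = Sw = None
    return SmallWorldResult(S=float(S), Sw=Sw, C=C, L=L, Cw=Cw if include_weighted else None,
                            Lw=Lw if include_weighted else None,
                            C_rand=C_rand, L_rand=L_rand,
                            Cw_rand=Cw_rand, Lw_rand=Lw_rand,
                            n_null=n_null, seed=seed)


# ---------------------------------------------------------------------------
# Bundled tables
# ---------------------------------------------------------------------------

@dataclass
class NodalMetrics:
    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    clustering_w: np.ndarray
    local_efficiency: np.ndarray
    local_efficiency_w: np.ndarray
    efficiency: np.ndarray
    efficiency_w: np.ndarray
    path_length: np.ndarray
    path_length_w: np.ndarray
    betweenness: np.ndarray
    betweenness_w: np.ndarray


def nodal_metrics(g) -> NodalMetrics:
    """All per-node metrics of a network in one pass."""
    g = _as_graph(g)
    k, kw = degree_strength(g)
    C, Cw = clustering(g)
    ep = efficiency_pathlength(g)
    El, Elw = local_efficiency(g)
    b, bw = betweenness(g)
    return NodalMetrics(degree=k, strength=kw, clustering=C, clustering_w=Cw,
                        local_efficiency=El, local_efficiency_w=Elw,
                        efficiency=ep["E"], efficiency_w=ep["Ew"],
                        path_length=ep["L"], path_length_w=ep["Lw"],
                        betweenness=b, betweenness_w=bw)


def global_metrics(g, n_null: int = 0, seed: Optional[int] = None) -> dict:
    """Global (node-averaged) metrics; small-worldness only if n_null > 0."""
    nm = nodal_metrics(g)
    out = {
        "degree": float(nm.degree.mean()),
        "strength": float(nm.strength.mean()),
        "clustering": float(nm.clustering.mean()),
        "clustering_w": float(nm.clustering_w.mean()),
        "local_efficiency": float(nm.local_efficiency.mean()),
        "local_efficiency_w": float(nm.local_efficiency_w.mean()),
        "global_efficiency": float(nm.efficiency.mean()),
        "global_efficiency_w": float(nm.efficiency_w.mean()),
        "betweenness": float(nm.betweenness.mean()),
        "betweenness_w": float(nm.betweenness_w.mean()),
    }
    if n_null > 0:
        sw = small_worldness(g, n_null=n_null, seed=seed)
        out["small_worldness"] = sw.S
        out["small_worldness_w"] = sw.Sw
    return out
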