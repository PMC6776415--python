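"""Graph metrics against closed forms and exhaustive brute-force oracles."""

import numpy as np
import networkx as nx
import pytest

import tractnet as tn
from conftest import random_weight_matrix
import _oracles as orc


def complete(n):
    return np.ones((n, n)) - np.eye(n)


def star(leaves):
    W = np.zeros((leaves + 1, leaves + 1))
    W[0, 1:] = W[1:, 0] = 1.0
    return W


def path3():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
    return W


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def test_normalise_divides_by_max():
    W = np.array([[0, 2, 0], [2, 0, 4], [0, 4, 0.]])
    g = tn.normalise(W)
    assert g.w_hat.max() == 1.0
    assert g.w_hat[0, 1] == 0.5


def test_normalise_degenerate_cases():
    assert np.all(tn.normalise(np.zeros((4, 4))).w_hat == 0)  # empty: no error
    g = tn.normalise(complete(4) * 3.7)
    assert np.allclose(g.w_hat[g.a > 0], 1.0)  # equal weights -> all 1
    with pytest.raises(ValueError):
        tn.normalise(-complete(3))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_degree_closed_forms():
    k, _ = tn.degree_strength(tn.normalise(complete(4)))
    assert np.all(k == 3)
    k, _ = tn.degree_strength(tn.normalise(star(5)))
    assert k[0] == 5 and np.all(k[1:] == 1)


def test_clustering_closed_forms():
    C, Cw = tn.clustering(tn.normalise(complete(3)))
    assert np.allclose(C, 1.0) and np.allclose(Cw, 1.0)
    C, _ = tn.clustering(tn.normalise(path3()))
    assert np.all(C == 0)


def test_efficiency_closed_forms():
    ep = tn.efficiency_pathlength(tn.normalise(complete(5)))
    assert np.allclose(ep["E"], 1.0) and np.allclose(ep["L"], 1.0)
    ep = tn.efficiency_pathlength(tn.normalise(path3()))
    assert np.allclose(ep["E"], [0.75, 1.0, 0.75])
    assert np.isclose(ep["E_global"], 5 / 6)


def test_local_efficiency_closed_forms():
    El, Elw = tn.local_efficiency(tn.normalise(complete(4)))
    assert np.allclose(El, 1.0) and np.allclose(Elw, 1.0)
    El, Elw = tn.local_efficiency(tn.normalise(star(4)))
    assert np.all(El == 0) and np.all(Elw == 0)


def test_betweenness_closed_forms():
    b, bw = tn.betweenness(tn.normalise(path3()))
    assert np.allclose(b, [0, 1, 0]) and np.allclose(bw, [0, 1, 0])
    b, _ = tn.betweenness(tn.normalise(star(5)))
    assert np.isclose(b[0], 1.0) and np.allclose(b[1:], 0.0)


def test_betweenness_strict_print_variant():
    b, _ = tn.betweenness(tn.normalise(path3()), strict_print=True)
    n = 3
    assert np.allclose(b, np.array([0, 1, 0]) * (n - 2) / (n - 1))


# ---------------------------------------------------------------------------
# oracle equivalence on random graphs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("trial", range(20))
def test_all_metrics_match_bruteforce(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 9))
    binary = trial % 4 == 0
    W = random_weight_matrix(rng, n, density=0.6, binary=binary)
    g = tn.normalise(W)
    wh = g.w_hat

    k, kw = tn.degree_strength(g)
    ok, okw = orc.degree_strength(wh)
    assert np.allclose(k, ok, atol=1e-12) and np.allclose(kw, okw, atol=1e-12)

    C, Cw = tn.clustering(g)
    oC, oCw = orc.clustering(wh)
    assert np.allclose(C, oC, atol=1e-12) and np.allclose(Cw, oCw, atol=1e-12)

    ep = tn.efficiency_pathlength(g)
    oE, oL = orc.efficiency_pathlength(wh, weighted=False)
    oEw, oLw = orc.efficiency_pathlength(wh, weighted=True)
    assert np.allclose(ep["E"], oE, atol=1e-12)
    assert np.allclose(ep["Ew"], oEw, atol=1e-10)
    assert np.allclose(ep["L"], oL, atol=1e-12, equal_nan=True)
    assert np.allclose(ep["Lw"], oLw, atol=1e-10, equal_nan=True)

    El, Elw = tn.local_efficiency(g)
    oEl, oElw = orc.local_efficiency(wh)
    assert np.allclose(El, oEl, atol=1e-12)
    assert np.allclose(Elw, oElw, atol=1e-10)

    b, bw = tn.betweenness(g)
    assert np.allclose(b, orc.betweenness(wh, weighted=False), atol=1e-10)
    assert np.allclose(bw, orc.betweenness(wh, weighted=True), atol=1e-8)


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_binary_weights_reduce_weighted_to_unweighted(rng):
    W = random_weight_matrix(rng, 8, density=0.5, binary=True)
    g = tn.normalise(W)
    k, kw = tn.degree_strength(g)
    assert np.allclose(k, kw, atol=1e-12)
    C, Cw = tn.clustering(g)
    assert np.allclose(C, Cw, atol=1e-12)
    ep = tn.efficiency_pathlength(g)
    assert np.allclose(ep["E"], ep["Ew"], atol=1e-12)
    assert np.allclose(ep["L"], ep["Lw"], atol=1e-12, equal_nan=True)
    El, Elw = tn.local_efficiency(g)
    assert np.allclose(El, Elw, atol=1e-12)
    b, bw = tn.betweenness(g)
    assert np.allclose(b, bw, atol=1e-10)


def test_permutation_equivariance(rng):
    W = random_weight_matrix(rng, 7, density=0.6)
    perm = rng.permutation(7)
    Wp = W[np.ix_(perm, perm)]
    nm = tn.nodal_metrics(tn.normalise(W))
    nmp = tn.nodal_metrics(tn.normalise(Wp))
    for f in ("degree", "strength", "clustering", "efficiency_w",
              "betweenness", "local_efficiency_w"):
        assert np.allclose(getattr(nm, f)[perm], getattr(nmp, f), atol=1e-10)


def test_adding_edge_never_decreases_global_efficiency(rng):
    for _ in range(10):
        W = random_weight_matrix(rng, 7, density=0.4, binary=True)
        zeros = np.argwhere(np.triu(W == 0, 1))
        zeros = zeros[zeros[:, 0] != zeros[:, 1]]
        if not len(zeros):
            continue
        i, j = zeros[rng.integers(len(zeros))]
        e0 = tn.efficiency_pathlength(tn.normalise(W))["E_global"]
        W2 = W.copy()
        W2[i, j] = W2[j, i] = 1.0
        e1 = tn.efficiency_pathlength(tn.normalise(W2))["E_global"]
        assert e1 >= e0 - 1e-12


# ---------------------------------------------------------------------------
# small-worldness
# ---------------------------------------------------------------------------

def test_complete_graph_small_worldness_is_one():
    sw = tn.small_worldness(tn.normalise(complete(8)), n_null=5, seed=0)
    assert np.isclose(sw.S, 1.0) and np.isclose(sw.Sw, 1.0)


def test_watts_strogatz_is_small_world():
    g = nx.watts_strogatz_graph(90, 10, 0.05, seed=1)
    W = nx.to_numpy_array(g)
    sw = tn.small_worldness(tn.normalise(W), n_null=20, seed=2,
                            include_weighted=False)
    assert sw.S > 1.5


def test_erdos_renyi_is_its_own_null():
    g = nx.gnp_random_graph(90, 0.15, seed=3)
    W = nx.to_numpy_array(g)
    sw = tn.small_worldness(tn.normalise(W), n_null=20, seed=4,
                            include_weighted=False)
    assert 0.8 <= sw.S <= 1.2


def test_rewiring_preserves_degree_and_weight_multiset(rng):
    W = random_weight_matrix(rng, 20, density=0.3)
    g = tn.normalise(W)
    wn = tn.metrics._rewire(g.w_hat, rng, 10 * g.n_edges)
    assert np.allclose(np.sort((wn > 0).sum(1)), np.sort(g.a.sum(1)))
    assert np.allclose(np.sort(wn[np.triu_indices(20, 1)]),
                       np.sort(g.w_hat[np.triu_indices(20, 1)]))


def test_small_worldness_needs_enough_edges():
    with pytest.raises(ValueError):
        tn.small_worldness(tn.normalise(path3()), n_null=2, seed=0)
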