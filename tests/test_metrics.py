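"""Graph metrics against hand-computed values and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wmnet as w
from wmnet.metrics import _distances

from conftest import binary_graph_from_edges


# --- independent oracles ---------------------------------------------------


def floyd_warshall(adj):
    n = adj.shape[0]
    d = np.where(adj, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def betweenness_by_path_enumeration(adj):
    """BC by explicit enumeration of all shortest paths (tiny graphs only)."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    bc = np.zeros(n)

    def all_shortest_paths(s, t):
        if not np.isfinite(d[s, t]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in range(n):
                if adj[u, v] and d[s, v] == len(path) and d[v, t] == d[s, t] - len(path):
                    extend(path + [v])

        extend([s])
        return paths

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def random_small_graphs(n_graphs=200, max_n=8, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(3, max_n + 1))
        p = rng.uniform(0.2, 0.9)
        a = np.triu(rng.random((n, n)) < p, 1)
        a = a | a.T
        yield a


# --- sparsity thresholding -------------------------------------------------


def test_sparsity_90_nodes_retains_400_edges():
    rng = np.random.default_rng(0)
    m = rng.random((90, 90))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0)
    g = w.sparsity_threshold(m, 0.10)
    assert g.n_edges == 400  # floor(0.10 * 4005)
    assert not w.min_degree_check(g)  # mean degree 8.89 < 2 ln 90 = 9.00


def test_sparsity_one_gives_complete_graph():
    m = np.ones((10, 10)) * 0.5
    np.fill_diagonal(m, 0)
    g = w.sparsity_threshold(m, 1.0)
    assert g.n_edges == 45


def test_equal_weights_resolved_lexicographically():
    m = np.full((6, 6), 0.5)
    np.fill_diagonal(m, 0)
    g1 = w.sparsity_threshold(m, 0.3)  # floor(0.3*15) = 4 edges
    g2 = w.sparsity_threshold(m, 0.3)
    assert np.array_equal(g1.adjacency, g2.adjacency)
    assert [tuple(e) for e in g1.edge_list()] == [(0, 1), (0, 2), (0, 3), (0, 4)]


def test_sparsity_errors():
    m = np.full((6, 6), 0.5)
    np.fill_diagonal(m, 0)
    with pytest.raises(ValueError, match="zero edges"):
        w.sparsity_threshold(m, 0.01)
    with pytest.raises(ValueError, match=r"\(0, 1\]"):
        w.sparsity_threshold(m, 1.5)


def test_min_degree_check_extremes(k4):
    m = np.ones((90, 90)) * 0.5
    np.fill_diagonal(m, 0)
    assert w.min_degree_check(w.sparsity_threshold(m, 1.0))  # K90
    empty = w.BinaryGraph(np.zeros((90, 90), dtype=bool), 0.0)
    assert not w.min_degree_check(empty)


# --- global and nodal metrics ---------------------------------------------


def test_global_metrics_complete_graph(k4):
    gm = w.global_metrics(k4)
    assert (gm.cp, gm.lp, gm.eglo, gm.eloc) == (1.0, 1.0, 1.0, 1.0)


def test_global_metrics_cycle5(cycle5):
    gm = w.global_metrics(cycle5)
    assert gm.cp == 0.0
    assert gm.lp == pytest.approx(1.5)
    assert gm.eglo == pytest.approx(0.75)
    assert gm.eloc == 0.0


def test_global_metrics_star5(star5):
    gm = w.global_metrics(star5)
    assert gm.lp == pytest.approx(1.6)  # 8 ordered pairs at 1, 12 at 2
    assert gm.eglo == pytest.approx(0.7)


def test_nodal_metrics_star5(star5):
    nm = w.nodal_metrics(star5)
    assert nm.degree[0] == 4 and np.all(nm.degree[1:] == 1)
    assert nm.efficiency[0] == pytest.approx(1.0)
    assert np.allclose(nm.efficiency[1:], 0.625)
    assert nm.betweenness[0] == pytest.approx(1.0)
    assert np.allclose(nm.betweenness[1:], 0.0)


def test_nodal_metrics_path3_middle(path3):
    nm = w.nodal_metrics(path3)
    assert nm.betweenness[1] == pytest.approx(1.0)
    assert nm.efficiency[1] == pytest.approx(1.0)


def test_nodal_metrics_k4(k4):
    nm = w.nodal_metrics(k4)
    assert np.allclose(nm.betweenness, 0.0)
    assert np.allclose(nm.efficiency, 1.0)


def test_edgeless_graph_rejected():
    g = w.BinaryGraph(np.zeros((4, 4), dtype=bool), 0.0)
    with pytest.raises(ValueError, match="edgeless"):
        w.global_metrics(g)


def test_distances_and_betweenness_match_bruteforce_oracles():
    """200 random graphs with N <= 8: BFS distances vs Floyd–Warshall,
    Brandes betweenness vs explicit path enumeration."""
    for a in random_small_graphs(200, 8, seed=42):
        assert np.array_equal(_distances(a), floyd_warshall(a))
        g = w.BinaryGraph(a, 0.0)
        nm = w.nodal_metrics(g)
        assert np.allclose(nm.betweenness, betweenness_by_path_enumeration(a), atol=1e-12)


def test_eglo_monotone_in_sparsity():
    rng = np.random.default_rng(5)
    m = rng.random((40, 40))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0)
    prev = 0.0
    for s in (0.10, 0.15, 0.20, 0.30, 0.50):
        e = w.global_metrics(w.sparsity_threshold(m, s)).eglo
        assert e >= prev - 1e-12
        prev = e


# --- null ensemble and small-worldness -------------------------------------


def test_null_ensemble_preserves_degree_sequence():
    rng = np.random.default_rng(1)
    m = rng.random((30, 30))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0)
    g = w.sparsity_threshold(m, 0.2)
    nulls = w.generate_null_ensemble(g, n_null=20, seed=7)
    deg = np.sort(g.degrees)
    for ng in nulls:
        assert ng.n_edges == g.n_edges
        assert np.array_equal(np.sort(ng.degrees), deg)


def test_six_cycle_nulls_reach_other_configuration():
    g = binary_graph_from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0)])
    nulls = w.generate_null_ensemble(g, n_null=20, seed=3)
    assert any(not np.array_equal(ng.adjacency, g.adjacency) for ng in nulls)


def test_null_ensemble_seeded_reproducible():
    rng = np.random.default_rng(2)
    m = rng.random((20, 20))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0)
    g = w.sparsity_threshold(m, 0.3)
    a = w.generate_null_ensemble(g, n_null=5, seed=11)
    b = w.generate_null_ensemble(g, n_null=5, seed=11)
    for x, y in zip(a, b):
        assert np.array_equal(x.adjacency, y.adjacency)


def test_star_graph_nulls_warn_and_copy(star5):
    with pytest.warns(UserWarning):
        nulls = w.generate_null_ensemble(star5, n_null=3, seed=0)
    for ng in nulls:
        assert np.array_equal(ng.adjacency, star5.adjacency)


def test_small_world_indices_identities():
    real = w.metrics.GlobalMetrics(cp=0.5, lp=2.0, eglo=0.5, eloc=0.5)
    nulls = [w.metrics.GlobalMetrics(cp=0.5, lp=2.0, eglo=0.5, eloc=0.5)] * 3
    swi = w.small_world_indices(real, nulls)
    assert (swi.gamma, swi.lam, swi.sigma) == (1.0, 1.0, 1.0)
    swi2 = w.metrics.SmallWorldIndices(gamma=2.0, lam=1.0)
    assert swi2.sigma == 2.0


def test_synthetic_connectomes_are_small_world():
    """Modular distance-dependent connectomes show sigma > 1 at S = 0.15."""
    table = w.generate_cohort(w.CohortSpec(n_is=2, n_nis=2, seed=0))
    for seed in range(20):
        conns = w.generate_connectomes(table.iloc[:1], n_nodes=60, seed=seed)
        conn = next(iter(conns.values()))
        g = w.sparsity_threshold(conn, 0.15)
        gm = w.global_metrics(g)
        nulls = w.generate_null_ensemble(g, n_null=10, seed=seed)
        swi = w.small_world_indices(gm, [w.global_metrics(x) for x in nulls])
        assert swi.sigma > 1.0
        assert swi.gamma > 1.0


def test_null_family_graph_has_unit_gamma_lambda():
    """A graph drawn from the rewired ensemble itself scores gamma ~ lambda ~ 1."""
    rng = np.random.default_rng(8)
    m = rng.random((40, 40))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0)
    g0 = w.sparsity_threshold(m, 0.25)
    fake_real = w.generate_null_ensemble(g0, n_null=1, seed=100)[0]
    nulls = w.generate_null_ensemble(g0, n_null=30, seed=101)
    null_gm = [w.global_metrics(x) for x in nulls]
    swi = w.small_world_indices(w.global_metrics(fake_real), null_gm)
    cp_sd = np.std([x.cp for x in null_gm]) / np.mean([x.cp for x in null_gm])
    lp_sd = np.std([x.lp for x in null_gm]) / np.mean([x.lp for x in null_gm])
    assert abs(swi.gamma - 1) <= 3 * cp_sd + 1e-9
    assert abs(swi.lam - 1) <= 3 * lp_sd + 1e-9


# --- AUC --------------------------------------------------------------------


def test_auc_constant_and_linear():
    grid = w.default_sparsity_grid()
    assert len(grid) == 11
    const = np.full(11, 3.0)
    assert w.auc_trapezoid(const, grid) == pytest.approx(0.1 * 3.0)
    rise = np.linspace(0.0, 1.0, 11)
    assert w.auc_trapezoid(rise, grid) == pytest.approx(0.05)


def test_auc_single_point_warns():
    with pytest.warns(UserWarning, match="single-point"):
        assert w.auc_trapezoid(np.array([2.0]), np.array([0.1])) == 0.0


@settings(derandomize=True, max_examples=50)
@given(
    a=st.floats(-5, 5), b=st.floats(-5, 5),
    seed=st.integers(0, 1000),
)
def test_auc_linearity(a, b, seed):
    rng = np.random.default_rng(seed)
    grid = w.default_sparsity_grid()
    c1, c2 = rng.random(11), rng.random(11)
    lhs = w.auc_trapezoid(a * c1 + b * c2, grid)
    rhs = a * w.auc_trapezoid(c1, grid) + b * w.auc_trapezoid(c2, grid)
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_metric_curves_shapes(small_cohort):
    table, conns = small_cohort
    conn = next(iter(conns.values()))
    curves = w.metric_curves(conn, n_null=5, seed=0)
    assert set(curves) == {
        "Cp", "Lp", "Eglo", "Eloc", "gamma", "lambda", "sigma",
        "degree", "efficiency", "betweenness",
    }
    assert curves["Cp"].values.shape == (11,)
    assert curves["degree"].values.shape == (11, 30)
    assert np.allclose(
        curves["sigma"].values,
        curves["gamma"].values / curves["lambda"].values,
    )
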