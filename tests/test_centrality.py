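import numpy as np
import pytest

from multicens import (
    MultilayerNetwork,
    QuerySet,
    global_centrality,
    layer_specific_centrality,
    local_centrality,
    local_layer_centrality,
    local_set_centrality,
    query_set_centrality,
    solve_fixed_point,
    versatility,
)
from conftest import make_random_network
from helpers_oracle import oracle_all, rel_linf


def normalized_dec(net):
    return net.decompose().row_normalize()


class TestSolveFixedPoint:
    def test_zero_operator_returns_forcing_in_one_iteration(self):
        b = np.array([0.2, 0.5, 0.3])
        v, its, res = solve_fixed_point(np.zeros((3, 3)), b, p=0.85)
        np.testing.assert_array_equal(v, b)
        assert its == 1 and res == 0.0

    def test_matches_hand_inverted_2x2(self):
        T = np.array([[0.0, 0.5], [1.0, 0.0]])
        b = np.array([1.0, 2.0])
        p = 0.5
        expected = np.linalg.inv(np.eye(2) - p * T) @ b
        v, _, _ = solve_fixed_point(T, b, p, tol=1e-14)
        np.testing.assert_allclose(v, expected, rtol=1e-12)

    def test_solution_satisfies_fixed_point_equation(self):
        rng = np.random.default_rng(0)
        T = rng.random((6, 6))
        T /= T.sum(axis=0)  # column-stochastic
        b = rng.random(6)
        tol = 1e-10
        v, _, _ = solve_fixed_point(T, b, p=0.9, tol=tol)
        assert np.max(np.abs(v - (0.9 * T @ v + b))) <= 10 * tol

    def test_nonconvergence_raises_with_residual(self):
        T = np.eye(2) * 1.01  # spectral radius above 1/p
        with pytest.raises(RuntimeError, match="did not converge"):
            solve_fixed_point(T, np.ones(2), p=0.99, max_iter=50)


class TestTrivialSolutions:
    def test_local_on_edgeless_network_is_uniform_forcing(self, edgeless_net):
        dec = normalized_dec(edgeless_net)
        res = local_centrality(dec, p=0.85)
        np.testing.assert_allclose(res.scores, 0.05, atol=1e-12)  # (1-p)/n

    def test_p_zero_gives_uniform_one_over_n(self, small_net):
        res = local_centrality(normalized_dec(small_net), p=0.0)
        np.testing.assert_allclose(res.scores, 1 / small_net.n_nodes, atol=1e-12)

    def test_local_layer_edgeless_masks_other_layer(self):
        net = MultilayerNetwork(["L0", "L1"], list("abcd"), np.zeros((8, 8)))
        res = local_layer_centrality(normalized_dec(net), "L1", p=0.5)
        np.testing.assert_allclose(res.scores[4:], 0.125, atol=1e-12)  # (1-p)/n
        np.testing.assert_array_equal(res.scores[:4], np.zeros(4))

    def test_local_set_edgeless_places_mass_on_query_only(self):
        nodes = [f"n{i}" for i in range(10)]
        net = MultilayerNetwork(["L0", "L1"], nodes, np.zeros((20, 20)))
        dec = normalized_dec(net)
        res = local_set_centrality(dec, QuerySet("L0", ["n2", "n7"]), p=0.5)
        expected = np.zeros(20)
        expected[[2, 7]] = 0.05  # (1-p)/n on the two query supra-nodes
        np.testing.assert_allclose(res.scores, expected, atol=1e-12)

    def test_global_reduces_to_scaled_local_without_cross_edges(self):
        # C = 0: the global system is the local one with forcing scaled by n/N
        rng = np.random.default_rng(3)
        n, L = 6, 3
        M = np.zeros((n * L, n * L))
        for a in range(L):
            sl = slice(a * n, (a + 1) * n)
            W = np.triu(rng.random((n, n)), 1)
            M[sl, sl] = W + W.T
        net = MultilayerNetwork([f"L{a}" for a in range(L)], [f"n{i}" for i in range(n)], M)
        dec = normalized_dec(net)
        l = local_centrality(dec, p=0.85)
        g = global_centrality(dec, p=0.85, l=l)
        np.testing.assert_allclose(g.scores, l.scores / L, atol=1e-9)


@pytest.mark.parametrize("p", [0.0, 0.3, 0.85, 0.99])
@pytest.mark.parametrize("n,L,seed", [(10, 2, 0), (7, 3, 1), (5, 4, 2)])
def test_every_measure_matches_direct_linear_solve(n, L, seed, p):
    net = make_random_network(n, L, seed)
    dec = normalized_dec(net)
    layer = net.layer_names[-1]
    query = net.node_names[: max(2, n // 3)]
    q = QuerySet(layer, query)
    expected = oracle_all(net, p, layer, query)
    kw = dict(tol=1e-12, max_iter=6000)  # p=0.99 contracts slowly
    got = {
        "local": local_centrality(dec, p, **kw),
        "local_layer": local_layer_centrality(dec, layer, p, **kw),
        "global": global_centrality(dec, p, **kw),
        "layer_specific": layer_specific_centrality(dec, layer, p, **kw),
        "local_set": local_set_centrality(dec, q, p, **kw),
        "query_set": query_set_centrality(dec, q, p, **kw),
        "versatility": versatility(dec, p, **kw),
    }
    for name, res in got.items():
        assert rel_linf(res.scores, expected[name]) < 1e-8, name
        assert (res.scores >= -1e-15).all() and np.isfinite(res.scores).all()


class TestDecomposability:
    @pytest.mark.parametrize("p", [0.3, 0.85])
    def test_layer_locals_sum_to_local(self, small_net, p):
        dec = normalized_dec(small_net)
        total = sum(
            local_layer_centrality(dec, lay, p).scores for lay in small_net.layer_names
        )
        np.testing.assert_allclose(total, local_centrality(dec, p).scores, atol=1e-9)

    @pytest.mark.parametrize("p", [0.3, 0.85])
    def test_layer_specifics_sum_to_global(self, small_net, p):
        dec = normalized_dec(small_net)
        total = sum(
            layer_specific_centrality(dec, lay, p).scores
            for lay in small_net.layer_names
        )
        np.testing.assert_allclose(total, global_centrality(dec, p).scores, atol=1e-9)

    def test_local_plus_global_is_versatility_times_L_plus_one(self, small_net):
        p = 0.85
        dec = normalized_dec(small_net)
        l = local_centrality(dec, p)
        g = global_centrality(dec, p, l=l)
        x = versatility(dec, p)
        L = small_net.n_layers
        np.testing.assert_allclose(l.scores + g.scores, (L + 1) * x.scores, atol=1e-9)
        # and after unit-sum normalization the factor disappears
        lg = l.scores + g.scores
        np.testing.assert_allclose(lg / lg.sum(), x.normalized(), atol=1e-9)

    def test_whole_layer_query_equals_layer_measures(self, small_net):
        p = 0.85
        dec = normalized_dec(small_net)
        q = QuerySet("L0", small_net.node_names)
        np.testing.assert_allclose(
            local_set_centrality(dec, q, p).scores,
            local_layer_centrality(dec, "L0", p).scores,
            atol=1e-9,
        )

    def test_partition_sums_to_layer_measures(self, small_net):
        p = 0.85
        dec = normalized_dec(small_net)
        nodes = small_net.node_names
        parts = [nodes[:3], nodes[3:5], nodes[5:]]
        qs = [QuerySet("L1", part) for part in parts]
        local_sum = sum(local_set_centrality(dec, q, p).scores for q in qs)
        np.testing.assert_allclose(
            local_sum, local_layer_centrality(dec, "L1", p).scores, atol=1e-9
        )
        query_sum = sum(query_set_centrality(dec, q, p).scores for q in qs)
        np.testing.assert_allclose(
            query_sum, layer_specific_centrality(dec, "L1", p).scores, atol=1e-9
        )


class TestProperties:
    def test_teleportation_limit_returns_forcing_shape(self, small_net):
        # as p -> 0 every measure tends to its indicator/uniform forcing
        dec = normalized_dec(small_net)
        p = 1e-9
        q = QuerySet("L1", ["n000", "n003"])
        res = query_set_centrality(dec, q, p)
        expected = q.indicator(dec) / small_net.n_supra
        np.testing.assert_allclose(res.scores, expected, atol=1e-7)

    def test_permutation_equivariance(self):
        net = make_random_network(n=7, L=2, seed=13)
        rng = np.random.default_rng(5)
        perm = rng.permutation(net.n_nodes)
        pm = np.zeros((net.n_nodes, net.n_nodes))
        pm[np.arange(net.n_nodes), perm] = 1.0
        P = np.kron(np.eye(net.n_layers), pm)
        permuted = MultilayerNetwork(
            net.layer_names, [net.node_names[i] for i in perm], P @ net.M @ P.T
        )
        for measure in (local_centrality, versatility):
            s1 = measure(normalized_dec(net), 0.85).scores
            s2 = measure(normalized_dec(permuted), 0.85).scores
            np.testing.assert_allclose(P @ s1, s2, atol=1e-10)

    def test_ranking_breaks_ties_lexicographically(self, edgeless_net):
        dec = normalized_dec(edgeless_net)
        res = local_centrality(dec, p=0.85)  # all scores equal
        assert res.layer_ranking(dec, "L0") == ["n0", "n1", "n2"]


class TestErrors:
    @pytest.mark.parametrize("p", [-0.1, 1.0, 1.5])
    def test_p_outside_unit_interval_rejected(self, small_net, p):
        with pytest.raises(ValueError, match="p must lie"):
            local_centrality(normalized_dec(small_net), p)

    def test_unknown_layer_rejected(self, small_net):
        with pytest.raises(KeyError, match="unknown layer"):
            local_layer_centrality(normalized_dec(small_net), "nope", 0.5)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            QuerySet("L0", [])

    def test_global_rejects_mismatched_local_p(self, small_net):
        dec = normalized_dec(small_net)
        l = local_centrality(dec, 0.5)
        with pytest.raises(ValueError, match="local centrality at p"):
            global_centrality(dec, 0.85, l=l)

    def test_unnormalized_decomposition_rejected(self, small_net):
        with pytest.raises(ValueError, match="row-normalized"):
            local_centrality(small_net.decompose(), 0.85)
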