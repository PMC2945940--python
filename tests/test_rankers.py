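"""The five ranking strategies: closed forms, oracles, and fixtures."""

import numpy as np
import pytest
import scipy.linalg

from netprio.diffexpr import DifferentialExpression
from netprio.kernels import KernelMatrix, similarity_network
from netprio.network import Network, build_matrices
from netprio.rankers import (
    RidgeConfig,
    arnoldi_diffusion_ranking,
    arnoldi_expv,
    build_preference_vector,
    direct_neighborhood_ranking,
    direct_neighborhood_score,
    heat_kernel_diffusion_ranking,
    heat_kernel_rank,
    kernel_ridge_regression_ranking,
    ridge_smoothed_expression,
    ridge_solve,
    select_neighborhood,
    simple_expression_ranking,
)

from conftest import make_network, random_network


def make_de(values: dict, pvalues: dict | None = None, measure="log2_ratio"):
    genes = tuple(values)
    p = None
    if pvalues is not None:
        p = np.array([pvalues[g] for g in genes])
        measure = "t_stat"
    return DifferentialExpression(
        genes, np.array([values[g] for g in genes], float), measure, pvalues=p
    )


def random_de(net, seed):
    rng = np.random.default_rng(seed)
    return DifferentialExpression(
        net.node_ids, rng.normal(0, 1, net.n_nodes), "log2_ratio"
    )


class TestSimpleRanking:
    def test_magnitude_ordering(self):
        de = make_de({"g1": -3.0, "g2": 1.0, "g3": 0.0})
        r = simple_expression_ranking(de, ["g1", "g2", "g3"])
        assert r.genes == ("g1", "g2", "g3")

    def test_all_zero_ties_break_lexicographically(self):
        de = make_de({"b": 0.0, "a": 0.0, "c": 0.0})
        r = simple_expression_ranking(de, ["b", "a", "c"])
        assert r.genes == ("a", "b", "c")
        np.testing.assert_array_equal(r.scores, 0.0)

    def test_single_candidate(self):
        r = simple_expression_ranking(make_de({"x": 2.0}), ["x"])
        assert r.rank_of("x") == 1

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simple_expression_ranking(make_de({"x": 2.0}), [])

    def test_signed_mode_ranks_descending_value(self):
        de = make_de({"g1": -3.0, "g2": 1.0, "g3": 0.0})
        r = simple_expression_ranking(de, ["g1", "g2", "g3"], signed=True)
        assert r.genes == ("g2", "g3", "g1")

    def test_missing_candidate_scored_zero(self):
        de = make_de({"g1": 2.0})
        r = simple_expression_ranking(de, ["g1", "zz"])
        assert r.rank_of("zz") == 2 and r.scores[1] == 0.0


class TestSelectNeighborhood:
    def kernel(self, sims: dict) -> KernelMatrix:
        ids = ("x", *sims)
        n = len(ids)
        V = np.zeros((n, n))
        for j, g in enumerate(sims, start=1):
            V[0, j] = V[j, 0] = sims[g]
        np.fill_diagonal(V, 1.0)
        return KernelMatrix(V, "centered", 0.5, ids)

    def test_top_nn_positive(self):
        K = self.kernel({"b": 0.9, "c": 0.4, "d": -0.1})
        assert select_neighborhood(K, "x", nn=2) == ["b", "c"]

    def test_all_negative_falls_back_to_top_two(self):
        K = self.kernel({"b": -0.2, "c": -0.5, "d": -0.9})
        assert select_neighborhood(K, "x", nn=50) == ["b", "c"]

    def test_fewer_positives_than_nn_returns_all(self):
        sims = {f"n{i}": 0.5 - 0.02 * i for i in range(10)}
        K = self.kernel(sims)
        assert len(select_neighborhood(K, "x", nn=50)) == 10

    def test_absent_gene_rejected(self):
        K = self.kernel({"b": 0.5})
        with pytest.raises(KeyError):
            select_neighborhood(K, "zz")


class TestRidge:
    def test_scalar_neighborhood_formula(self):
        # single neighbor, unit similarity: y_hat = y / (1 + lambda)
        for lam, y in [(1.0, 3.0), (0.5, -2.0), (10.0, 1.0)]:
            assert ridge_solve([[1.0]], [1.0], [y], lam) == pytest.approx(
                y / (1 + lam)
            )

    def test_large_lambda_shrinks_to_zero(self, triangle_mats):
        K = similarity_network(triangle_mats)
        de = make_de({"a": 5.0, "b": -3.0, "c": 2.0})
        y = ridge_smoothed_expression(K, de, "a", RidgeConfig(lam=1e12))
        assert abs(y) < 1e-6

    def test_matches_dense_solve_oracle(self):
        net = random_network(5, p=0.8, seed=2, connected=True)
        mats = build_matrices(net)
        K_C = similarity_network(mats)
        de = random_de(net, 5)
        cfg = RidgeConfig(lam=1.0, nn=4)
        gene = net.node_ids[0]
        nbrs = [gene] + select_neighborhood(K_C, gene, cfg.nn - 1)
        idx = [K_C.index_of(g) for g in nbrs]
        K = K_C.values[np.ix_(idx, idx)]
        Kx = K_C.values[K_C.index_of(gene), idx]
        Y = np.array([de.value(g) for g in nbrs])
        oracle = Kx @ np.linalg.inv(K + np.eye(len(nbrs))) @ Y
        assert ridge_smoothed_expression(K_C, de, gene, cfg) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_zero_expression_gives_zero_smoothed_values(self, triangle_mats):
        K = similarity_network(triangle_mats)
        de = make_de({"a": 0.0, "b": 0.0, "c": 0.0})
        r = kernel_ridge_regression_ranking(K, de, ["a", "b", "c"])
        np.testing.assert_array_equal(r.scores, 0.0)

    def test_linearity_in_expression_scale(self):
        net = random_network(8, p=0.5, seed=3, connected=True)
        K = similarity_network(build_matrices(net))
        de = random_de(net, 1)
        de3 = DifferentialExpression(de.genes, 3.0 * de.values, de.measure)
        cands = list(net.node_ids[:5])
        r1 = kernel_ridge_regression_ranking(K, de, cands)
        r3 = kernel_ridge_regression_ranking(K, de3, cands)
        assert r1.genes == r3.genes
        np.testing.assert_allclose(r3.scores, 3.0 * r1.scores, atol=1e-10)

    def test_differentially_expressed_clique_outranks_silent_one(self):
        # two 5-cliques bridged weakly; equal own expression for the two
        # candidate hubs, but only one sits amid strong responders
        edges = []
        for grp in ("a", "b"):
            for i in range(5):
                for j in range(i + 1, 5):
                    edges.append((f"{grp}{i}", f"{grp}{j}", 0.9))
        edges.append(("a0", "b0", 0.2))
        net = make_network(edges)
        values = {g: 0.0 for g in net.node_ids}
        values.update({f"a{i}": -3.0 for i in range(1, 5)})
        values["a0"] = values["b0"] = -1.0
        de = make_de(values)
        K = similarity_network(build_matrices(net))
        r = kernel_ridge_regression_ranking(K, de, ["a0", "b0"], RidgeConfig(nn=6))
        assert r.genes[0] == "a0"


class TestPreferenceVector:
    def setup_method(self):
        self.node_ids = ("a", "b", "c", "d")
        self.de = make_de({"a": 2.5, "b": -1.0, "c": 0.3},
                          pvalues={"a": 0.01, "b": 0.2, "c": 0.04})

    def test_scenario1_binary_candidates(self):
        p = build_preference_vector(1, self.de, ["a", "b"], self.node_ids)
        np.testing.assert_array_equal(p.values, [1, 1, 0, 0])

    def test_scenario2_candidate_expression(self):
        p = build_preference_vector(2, self.de, ["a"], self.node_ids)
        np.testing.assert_array_equal(p.values, [2.5, 0, 0, 0])

    def test_scenario3_all_expression(self):
        p = build_preference_vector(3, self.de, ["a"], self.node_ids)
        np.testing.assert_array_equal(p.values, [2.5, -1.0, 0.3, 0])

    def test_scenario4_binary_significance(self):
        p = build_preference_vector(4, self.de, ["a"], self.node_ids)
        np.testing.assert_array_equal(p.values, [1, 0, 1, 0])

    def test_scenario4_needs_pvalues(self):
        de = make_de({"a": 1.0})
        with pytest.raises(ValueError, match="p-values"):
            build_preference_vector(4, de, ["a"], self.node_ids)


class TestHeatKernelRank:
    def test_alpha_zero_returns_p0(self, triangle_mats):
        p0 = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            heat_kernel_rank(triangle_mats, p0, alpha=0.0, n_steps=5), p0
        )

    def test_converges_to_operator_exponential(self):
        mats = build_matrices(random_network(20, p=0.3, seed=6, connected=True))
        rng = np.random.default_rng(0)
        p0 = rng.normal(size=20)
        exact = p0 @ scipy.linalg.expm(
            -0.5 * (np.eye(20) - mats.transition.toarray())
        )
        approx = heat_kernel_rank(mats, p0, alpha=0.5, n_steps=10_000)
        assert np.abs(approx - exact).max() < 1e-4

    def test_error_halves_when_steps_double(self):
        mats = build_matrices(random_network(15, p=0.4, seed=8, connected=True))
        rng = np.random.default_rng(1)
        p0 = rng.normal(size=15)
        exact = p0 @ scipy.linalg.expm(
            -0.5 * (np.eye(15) - mats.transition.toarray())
        )
        errs = [
            np.abs(heat_kernel_rank(mats, p0, 0.5, n) - exact).max()
            for n in (64, 128, 256)
        ]
        for e_n, e_2n in zip(errs, errs[1:]):
            assert 0.3 < e_2n / e_n < 0.7  # first-order convergence

    def test_isolated_node_signal_preserved(self):
        net = make_network([("a", "b", 1.0)], extra_nodes=["z"])
        mats = build_matrices(net)
        p0 = np.array([0.0, 0.0, 5.0])
        out = heat_kernel_rank(mats, p0, alpha=0.5, n_steps=2)
        assert out[2] == pytest.approx(5.0)

    def test_negative_steps_rejected(self, triangle_mats):
        with pytest.raises(ValueError):
            heat_kernel_rank(triangle_mats, np.zeros(3), n_steps=-1)


class TestHeatRanking:
    def test_zero_preference_gives_lexicographic_order(self, triangle_mats):
        de = make_de({"a": 0.0, "b": 0.0, "c": 0.0})
        r = heat_kernel_diffusion_ranking(triangle_mats, de, ["c", "a", "b"])
        assert r.genes == ("a", "b", "c")

    def test_permutation_equivariance(self):
        net = random_network(12, p=0.4, seed=10, connected=True)
        de = random_de(net, 2)
        cands = list(net.node_ids[:6])
        r1 = heat_kernel_diffusion_ranking(build_matrices(net), de, cands)
        perm_ids = tuple(sorted(net.node_ids, reverse=True))
        net2 = Network(perm_ids, net.graph)
        r2 = heat_kernel_diffusion_ranking(build_matrices(net2), de, cands)
        assert r1.genes == r2.genes


class TestArnoldi:
    def test_full_subspace_matches_dense_oracle(self):
        mats = build_matrices(random_network(15, p=0.3, seed=12, connected=True))
        rng = np.random.default_rng(3)
        v = rng.normal(size=15)
        A = -(np.eye(15) - mats.transition.toarray()).T
        oracle = scipy.linalg.expm(0.5 * A) @ v
        u = arnoldi_expv(mats, v, m=15, alpha=0.5)
        np.testing.assert_allclose(u, oracle, atol=1e-8)

    def test_alpha_zero_returns_v(self, triangle_mats):
        v = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(
            arnoldi_expv(triangle_mats, v, m=2, alpha=0.0), v, atol=1e-12
        )

    def test_isolated_node_start_vector_fixed_point(self):
        net = make_network([("a", "b", 1.0)], extra_nodes=["z"])
        mats = build_matrices(net)
        v = np.array([0.0, 0.0, 5.0])
        np.testing.assert_allclose(
            arnoldi_expv(mats, v, m=3, alpha=0.5), v, atol=1e-10
        )

    def test_zero_start_vector_rejected(self, triangle_mats):
        with pytest.raises(ValueError, match="zero"):
            arnoldi_expv(triangle_mats, np.zeros(3), m=2)

    def test_error_nonincreasing_in_m_and_zero_at_full(self):
        n = 20
        mats = build_matrices(random_network(n, p=0.3, seed=13, connected=True))
        rng = np.random.default_rng(4)
        v = rng.normal(size=n)
        A = -(np.eye(n) - mats.transition.toarray()).T
        oracle = scipy.linalg.expm(0.5 * A) @ v
        errs = [
            np.linalg.norm(arnoldi_expv(mats, v, m=m, alpha=0.5) - oracle)
            for m in (1, 2, 4, 8, n)
        ]
        for a, b in zip(errs, errs[1:]):
            assert b <= a + 1e-10
        assert errs[-1] < 1e-8

    def test_large_m_reproduces_heat_ranking(self):
        net = random_network(30, p=0.2, seed=14, connected=True)
        mats = build_matrices(net)
        de = random_de(net, 6)
        cands = list(net.node_ids[:15])
        r_heat = heat_kernel_diffusion_ranking(mats, de, cands, n_steps=10_000)
        r_arn = arnoldi_diffusion_ranking(mats, de, cands, m=30)
        assert r_heat.genes == r_arn.genes

    def test_deterministic_across_runs(self, triangle_mats):
        de = make_de({"a": 1.0, "b": -0.5, "c": 0.2})
        r1 = arnoldi_diffusion_ranking(triangle_mats, de, ["a", "b", "c"], m=2)
        r2 = arnoldi_diffusion_ranking(triangle_mats, de, ["a", "b", "c"], m=2)
        assert r1.genes == r2.genes
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_all_zero_signal_surfaces_as_error(self, triangle_mats):
        de = make_de({"a": 0.0, "b": 0.0, "c": 0.0})
        with pytest.raises(ValueError, match="signal"):
            arnoldi_diffusion_ranking(triangle_mats, de, ["a", "b"], m=2)


class TestDirectNeighborhood:
    def test_a_one_is_own_magnitude(self):
        net = make_network([("x", "y", 0.9)])
        de = make_de({"x": -2.0, "y": 5.0})
        assert direct_neighborhood_score(net, de, "x", a=1.0) == pytest.approx(2.0)

    def test_mixing_arithmetic(self):
        net = make_network([("x", "y", 0.9)])
        de = make_de({"x": 1.0, "y": 2.0})
        assert direct_neighborhood_score(net, de, "x", a=0.5) == pytest.approx(1.5)

    def test_eps_filters_weak_edges(self):
        net = make_network([("x", "p", 0.1), ("x", "q", 0.2), ("x", "r", 0.9)])
        de = make_de({"x": 0.0, "p": 100.0, "q": 2.0, "r": 4.0})
        # only q and r survive eps=0.15: mean(|2|, |4|) = 3
        assert direct_neighborhood_score(net, de, "x", a=0.5, eps=0.15) == pytest.approx(1.5)

    def test_absent_gene_isolated_treatment(self):
        net = make_network([("a", "b", 0.5)])
        de = make_de({"zz": -4.0})
        assert direct_neighborhood_score(net, de, "zz", a=0.5) == pytest.approx(2.0)

    def test_a_one_ranking_reduces_to_simple(self):
        net = random_network(10, p=0.4, seed=15)
        de = random_de(net, 7)
        cands = list(net.node_ids[:6])
        r_dn = direct_neighborhood_ranking(net, de, cands, a=1.0)
        r_simple = simple_expression_ranking(de, cands)
        assert r_dn.genes == r_simple.genes

    def test_responsive_neighborhood_outranks_silent_one(self):
        edges = [("hub", f"n{i}", 0.8) for i in range(4)]
        edges += [("lone", f"m{i}", 0.8) for i in range(4)]
        net = make_network(edges)
        values = {g: 0.0 for g in net.node_ids}
        values.update({f"n{i}": -3.0 for i in range(4)})
        values["hub"] = values["lone"] = -1.0
        r = direct_neighborhood_ranking(net, make_de(values), ["hub", "lone"])
        assert r.genes[0] == "hub"


def test_strategies_degrade_without_the_knockouts_own_signal():
    """Erasing the planted gene's own expression must worsen its mean rank
    for every strategy — each leans on the knockout's own signal."""
    from netprio.benchmark import ALL_STRATEGIES, run_benchmark
    from netprio.evaluation import mean_rank
    from netprio.synthetic import SyntheticSpec

    spec = SyntheticSpec(n_genes=300, n_cases=10, seed=42)
    base = run_benchmark(spec, ALL_STRATEGIES, measure="log2_ratio")
    zero = run_benchmark(spec, ALL_STRATEGIES, measure="log2_ratio",
                         zero_knockout=True)
    for s in ALL_STRATEGIES:
        assert mean_rank(zero[s]) > mean_rank(base[s]), s


def test_attenuated_knockout_favors_diffusion_over_baseline():
    """When the planted gene's own response is damped to 25%, the heat-kernel
    strategy recovers it from its neighborhood and beats the baseline's mean
    rank (aggregated over 20 seeded cases)."""
    from netprio.benchmark import run_benchmark
    from netprio.evaluation import mean_rank
    from netprio.synthetic import SyntheticSpec

    simple_ranks, heat_ranks = [], []
    for seed in range(1, 21):
        spec = SyntheticSpec(n_genes=300, n_cases=1, self_attenuation=0.75,
                             seed=seed)
        res = run_benchmark(spec, ("simple", "heat"), measure="log2_ratio")
        simple_ranks += res["simple"]
        heat_ranks += res["heat"]
    assert mean_rank(heat_ranks) < mean_rank(simple_ranks)
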