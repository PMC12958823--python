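"""Structure learning: decorrelation, BIC/BGe scores, hill climbing against
an exhaustive oracle, tabu search, bootstrap averaging."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import multigammaln

from pinesem.bn import (
    BnError,
    DagStructure,
    GaussianData,
    arc_removal_delta,
    bge_score,
    bic_score,
    bootstrap_average,
    decorrelate_bvs,
    exhaustive_search,
    hill_climb,
    tabu_search,
)
from pinesem.kinship import RelationshipMatrix


def dag(names, *edges):
    return DagStructure(tuple(names), frozenset(edges))


def linear_system_data(rng, n, coefs, t=4, noise=1.0):
    """X_j = sum_i coefs[(i, j)] X_i + noise; topological in index order."""
    X = np.zeros((n, t))
    for j in range(t):
        X[:, j] = noise * rng.standard_normal(n)
        for (i, jj), b in coefs.items():
            if jj == j:
                X[:, j] += b * X[:, i]
    return GaussianData(X, tuple(f"x{k}" for k in range(t)))


class TestDecorrelate:
    def test_identity_kinship_is_noop(self, rng):
        bv = pd.DataFrame(rng.standard_normal((5, 2)),
                          index=[f"t{i}" for i in range(5)], columns=["a", "b"])
        K = RelationshipMatrix(list(bv.index), np.eye(5), "G")
        out = decorrelate_bvs(bv, K)
        np.testing.assert_allclose(out.values.to_numpy(), bv.to_numpy())

    def test_hand_cholesky_two_trees(self):
        K = RelationshipMatrix(["u", "v"],
                               np.array([[1.0, 0.5], [0.5, 1.0]]), "G")
        bv = pd.DataFrame({"y": [1.0, 1.0]}, index=["u", "v"])
        out = decorrelate_bvs(bv, K).values["y"].to_numpy()
        # L = [[1, 0], [0.5, 0.8660]]; L^-1 (1,1)' = (1, 0.57735)
        np.testing.assert_allclose(out, [1.0, 0.57735], atol=1e-5)

    def test_recorrelation_round_trip(self, rng):
        n = 30
        M = rng.standard_normal((n, n))
        K = RelationshipMatrix([f"t{i}" for i in range(n)],
                               M @ M.T / n + np.eye(n), "G")
        bv = pd.DataFrame(rng.standard_normal((n, 3)), index=K.ids,
                          columns=list("abc"))
        dec = decorrelate_bvs(bv, K)
        L = np.linalg.cholesky(K.values)
        np.testing.assert_allclose(L @ dec.values.to_numpy(), bv.to_numpy(),
                                   atol=1e-10)

    def test_removes_cross_tree_covariance(self, rng):
        # a ~ N(0, Sigma (x) K) with block kinship: after the transform,
        # rows are uncorrelated while the trait covariance stays Sigma
        fam = 80
        K = np.kron(np.eye(fam), np.full((5, 5), 0.25) + 0.75 * np.eye(5))
        n = 5 * fam
        Sigma = np.array([[1.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(K)
        a = L @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(Sigma).T
        ids = [f"t{i}" for i in range(n)]
        bv = pd.DataFrame(a, index=ids, columns=["y1", "y2"])
        dec = decorrelate_bvs(bv, RelationshipMatrix(ids, K, "G")).values
        v = dec.to_numpy()
        sib_cov = np.mean([v[5 * f] * v[5 * f + 1] for f in range(fam)])
        assert abs(sib_cov) < 3 / np.sqrt(fam)
        np.testing.assert_allclose(np.cov(v.T), Sigma, atol=0.2)

    def test_non_pd_kinship_rejected(self):
        K = RelationshipMatrix(["u", "v"], np.array([[1.0, 1.0], [1.0, 1.0]]),
                               "G")
        bv = pd.DataFrame({"y": [0.0, 0.0]}, index=["u", "v"])
        with pytest.raises(BnError, match="positive definite"):
            decorrelate_bvs(bv, K)


class TestScores:
    def test_bic_decomposability_exact(self, rng):
        data = linear_system_data(rng, 200, {(0, 1): 0.8, (1, 2): -0.5})
        g = dag(data.names, ("x0", "x1"), ("x1", "x2"), ("x0", "x3"))
        total = bic_score(data, g)
        partial = sum(
            bic_score(data, dag(data.names, *[e for e in g.edges
                                              if e[1] == child]))
            - bic_score(data, dag(data.names))
            for child in data.names
        ) + bic_score(data, dag(data.names))
        assert total == pytest.approx(partial, abs=1e-9)

    def test_empty_beats_single_edge_on_independent_data(self, rng):
        data = GaussianData(rng.standard_normal((500, 3)), ("a", "b", "c"))
        empty = bic_score(data, dag(data.names))
        for p, c in itertools.permutations(data.names, 2):
            assert empty >= bic_score(data, dag(data.names, (p, c)))

    def test_true_edge_raises_bic(self, rng):
        data = linear_system_data(rng, 500, {(0, 1): 0.8}, t=2)
        assert (bic_score(data, dag(data.names, ("x0", "x1")))
                > bic_score(data, dag(data.names)))

    def test_bge_score_equivalence_all_three_node_classes(self, rng):
        data = GaussianData(rng.standard_normal((60, 3)) @
                            np.array([[1, .5, .2], [0, 1, .4], [0, 0, 1.]]),
                            ("a", "b", "c"))
        # chains and fork a<-b->c are Markov equivalent; collider is not
        chain1 = dag(data.names, ("a", "b"), ("b", "c"))
        chain2 = dag(data.names, ("c", "b"), ("b", "a"))
        fork = dag(data.names, ("b", "a"), ("b", "c"))
        collider = dag(data.names, ("a", "b"), ("c", "b"))
        s1, s2, s3 = (bge_score(data, g) for g in (chain1, chain2, fork))
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert s1 == pytest.approx(s3, abs=1e-9)
        assert bge_score(data, collider) != pytest.approx(s1, abs=1e-6)
        # two-node equivalence, exactly
        d2 = GaussianData(data.X[:, :2], ("a", "b"))
        assert (bge_score(d2, dag(d2.names, ("a", "b")))
                == pytest.approx(bge_score(d2, dag(d2.names, ("b", "a"))),
                                 abs=1e-10))

    def test_bge_complete_dag_matches_joint_marginal(self, rng):
        # telescoping oracle: local scores of a complete DAG must sum to the
        # closed-form normal-Wishart marginal likelihood of the full data
        n, t = 40, 3
        X = rng.standard_normal((n, t))
        data = GaussianData(X, ("a", "b", "c"))
        total = bge_score(data, dag(data.names, ("a", "b"), ("a", "c"),
                                    ("b", "c")))
        am, aw, ts = 1.0, t + 2.0, 1.0
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar)
        R = ts * np.eye(t) + S + (am * n / (am + n)) * np.outer(xbar, xbar)
        expected = (
            -0.5 * t * n * np.log(np.pi)
            + 0.5 * t * np.log(am / (am + n))
            + multigammaln(0.5 * (n + aw), t) - multigammaln(0.5 * aw, t)
            + 0.5 * aw * t * np.log(ts)
            - 0.5 * (n + aw) * np.linalg.slogdet(R)[1]
        )
        assert total == pytest.approx(expected, abs=1e-8)

    def test_bge_and_bic_rank_chain_above_empty(self, rng):
        data = linear_system_data(rng, 500, {(0, 1): 0.7, (1, 2): 0.7}, t=3)
        chain = dag(data.names, ("x0", "x1"), ("x1", "x2"))
        empty = dag(data.names)
        assert bic_score(data, chain) > bic_score(data, empty)
        assert bge_score(data, chain) > bge_score(data, empty)

    def test_too_many_parents_rejected(self, rng):
        data = GaussianData(rng.standard_normal((3, 4)), tuple("abcd"))
        g = dag(data.names, ("a", "d"), ("b", "d"), ("c", "d"))
        with pytest.raises(BnError, match="parents"):
            bic_score(data, g)


class TestSearch:
    def test_independent_columns_yield_empty_graph(self, rng):
        data = GaussianData(rng.standard_normal((400, 4)), tuple("abcd"))
        assert hill_climb(data).n_edges == 0
        assert tabu_search(data).n_edges == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_hill_climb_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coefs = {}
        for i, j in itertools.combinations(range(4), 2):
            if rng.random() < 0.5:
                coefs[(i, j)] = rng.uniform(-1, 1)
        data = linear_system_data(rng, 300, coefs)
        found = hill_climb(data, score="bic")
        _, best = exhaustive_search(data, score="bic")
        assert bic_score(data, found) == pytest.approx(best, abs=1e-8)

    def test_deterministic_given_inputs(self, rng):
        data = linear_system_data(rng, 200, {(0, 2): 0.6, (1, 3): -0.7})
        assert hill_climb(data, seed=1).edges == hill_climb(data, seed=1).edges
        assert (tabu_search(data, seed=2).edges
                == tabu_search(data, seed=2).edges)

    @pytest.mark.parametrize("seed", range(15))
    def test_tabu_never_below_hill_climb(self, seed):
        rng = np.random.default_rng(100 + seed)
        coefs = {}
        for i, j in itertools.combinations(range(6), 2):
            if rng.random() < 0.4:
                coefs[(i, j)] = rng.uniform(-0.9, 0.9)
        data = linear_system_data(rng, 150, coefs, t=6)
        s_hc = bic_score(data, hill_climb(data))
        s_tabu = bic_score(data, tabu_search(data))
        assert s_tabu >= s_hc - 1e-9


class TestBootstrap:
    def test_strong_edge_has_full_strength(self, rng):
        data = linear_system_data(rng, 400, {(0, 1): 0.9}, t=3)
        avg = bootstrap_average(data, n_boot=100, seed=0)
        assert avg.strength("x0", "x1") >= 0.99
        # orientation of an isolated edge is not identifiable
        assert (("x0", "x1") in avg.consensus.edges
                or ("x1", "x0") in avg.consensus.edges)

    def test_strengths_invariant_to_row_permutation(self, rng):
        # rows are exchangeable: a permuted dataset yields the same strong
        # arcs (replicate-level draws differ, so agreement is statistical)
        data = linear_system_data(rng, 150, {(0, 1): 0.8, (1, 2): 0.6}, t=3)
        perm = GaussianData(data.X[rng.permutation(150)], data.names)
        a = bootstrap_average(data, n_boot=60, seed=5)
        b = bootstrap_average(perm, n_boot=60, seed=5)
        for u, v in (("x0", "x1"), ("x1", "x2")):
            assert a.strength(u, v) > 0.9 and b.strength(u, v) > 0.9
            assert a.strength(u, v) == pytest.approx(b.strength(u, v),
                                                     abs=0.1)

    def test_collider_direction_identified(self, rng):
        # x0 -> x2 <- x1: the v-structure orients both edges
        data = linear_system_data(rng, 500, {(0, 2): 0.8, (1, 2): 0.8}, t=3)
        avg = bootstrap_average(data, n_boot=80, seed=1)
        for arc in (("x0", "x2"), ("x1", "x2")):
            row = avg.arcs[(avg.arcs["from"] == arc[0])
                           & (avg.arcs["to"] == arc[1])]
            assert len(row) == 1 and row["direction"].iloc[0] > 0.5

    def test_invalid_replicate_count(self, rng):
        data = GaussianData(rng.standard_normal((20, 2)), ("a", "b"))
        with pytest.raises(BnError):
            bootstrap_average(data, n_boot=0)


class TestArcRemoval:
    def test_delta_is_local_to_child(self, rng):
        data = linear_system_data(rng, 300, {(0, 1): 0.8, (1, 2): -0.6})
        g = dag(data.names, ("x0", "x1"), ("x1", "x2"))
        table = arc_removal_delta(data, g, "bic")
        for row in table.itertuples():
            reduced = dag(data.names,
                          *(e for e in g.edges if e != (row._1, row.to)))
            assert row.delta == pytest.approx(
                bic_score(data, g) - bic_score(data, reduced), abs=1e-9)
        assert list(table["delta"]) == sorted(table["delta"], reverse=True)

    def test_spurious_arc_has_negative_delta(self, rng):
        data = GaussianData(rng.standard_normal((800, 2)), ("a", "b"))
        g = dag(data.names, ("a", "b"))
        assert arc_removal_delta(data, g)["delta"].iloc[0] < 0

    def test_empty_dag_rejected(self, rng):
        data = GaussianData(rng.standard_normal((50, 2)), ("a", "b"))
        with pytest.raises(BnError, match="arcs"):
            arc_removal_delta(data, dag(data.names))
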