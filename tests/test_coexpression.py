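"""Partial-correlation screen: Spearman matrix, recursion formula, Fisher-z
p-values, pair aggregation, network construction and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coexpareto import (ConfounderTriad, ExpressionStudy, PlantedModule,
                        SyntheticSpec, build_network, first_order_partial,
                        pair_significance, partial_p_value, permutation_null,
                        simulate, spearman_matrix)
from coexpareto.coexpression import _pairwise_stats


def _frame(rows, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"g{k}" for k in range(rows.shape[0])]
    return pd.DataFrame(rows, index=genes,
                        columns=[f"s{k}" for k in range(rows.shape[1])])


def _study_from_matrix(values, genes=None, condition="post"):
    expr = _frame(values, genes)
    cond = pd.Series([condition] * expr.shape[1], index=expr.columns)
    return ExpressionStudy(expr=expr, condition=cond)


class TestSpearmanMatrix:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),   # 1 - 6*2/(4*15)
    ])
    def test_known_values(self, x, y, expected):
        corr, genes = spearman_matrix(_frame([x, y]))
        assert corr[0, 1] == pytest.approx(expected, abs=1e-12)
        assert genes == ["g0", "g1"]

    def test_constant_gene_excluded(self):
        corr, genes = spearman_matrix(_frame([[1, 2, 3], [5, 5, 5],
                                              [3, 1, 2]]))
        assert genes == ["g0", "g2"]
        assert corr.shape == (2, 2)

    def test_ties_use_average_ranks(self):
        x, y = [1, 1, 2, 3], [4, 4, 5, 6]
        corr, _ = spearman_matrix(_frame([x, y]))
        assert corr[0, 1] == pytest.approx(
            sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 25))
        warped = np.exp(base)
        warped[2] = base[2] ** 3
        a, _ = spearman_matrix(_frame(base))
        b, _ = spearman_matrix(_frame(warped))
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestFirstOrderPartial:
    @pytest.mark.parametrize("rxy, rxz, ryz, expected", [
        (0.6, 0.0, 0.0, 0.6),       # independent conditioner
        (0.48, 0.6, 0.8, 0.0),      # fully explained by conditioner
        (0.7, 0.5, 0.5, 0.6),       # (0.7 - 0.25)/0.75
    ])
    def test_known_values(self, rxy, rxz, ryz, expected):
        assert first_order_partial(rxy, rxz, ryz) == pytest.approx(
            expected, abs=1e-12)

    def test_degenerate_conditioner(self):
        with pytest.raises(ZeroDivisionError):
            first_order_partial(0.5, 1.0, 0.2)

    def test_rank_residual_oracle(self):
        # recursion formula == Pearson correlation of the residuals of
        # rank-transformed x and y regressed on rank-transformed z
        rng = np.random.default_rng(4)
        values = rng.normal(size=(15, 30))
        ranks = sps.rankdata(values, axis=1)
        corr = np.corrcoef(ranks)
        centered = ranks - ranks.mean(axis=1, keepdims=True)
        for z in range(15):
            zc = centered[z]
            beta = centered @ zc / (zc @ zc)
            resid = centered - np.outer(beta, zc)
            with np.errstate(invalid="ignore"):   # row z residual is ~0
                oracle = np.corrcoef(resid)
            for x in range(15):
                for y in range(x + 1, 15):
                    if z in (x, y):
                        continue
                    ours = first_order_partial(corr[x, y], corr[x, z],
                                               corr[y, z])
                    assert ours == pytest.approx(oracle[x, y], abs=1e-10)


class TestPartialPValue:
    def test_zero_correlation(self):
        assert partial_p_value(0.0, n=30) == pytest.approx(1.0)

    def test_monotone_in_magnitude(self):
        assert partial_p_value(0.3, 30) > partial_p_value(0.6, 30)

    def test_fisher_z_example(self):
        # r = 0.5, n = 20, k = 1: z = 0.5493, se = 0.25, p = 2*Phi(-2.197)
        assert partial_p_value(0.5, n=20, k=1) == pytest.approx(0.0280,
                                                                abs=5e-4)

    def test_perfect_correlation(self):
        assert partial_p_value(1.0, n=20) == 0.0

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            partial_p_value(0.5, n=4, k=1)


class TestPairSignificance:
    def test_two_gene_universe_reduces_to_zero_order(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        pair_p, min_partial, argmin = pair_significance(corr, 0, 1, n=20)
        assert pair_p == pytest.approx(partial_p_value(0.6, 20, k=0))
        assert np.isnan(min_partial) and argmin == -1

    def test_min_partial_is_weakest(self):
        # pair (0,1) strongly coupled to conditioner 2, independent of 3
        corr = np.array([
            [1.0, 0.48, 0.6, 0.0],
            [0.48, 1.0, 0.8, 0.0],
            [0.6, 0.8, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0]])
        pair_p, min_partial, argmin = pair_significance(corr, 0, 1, n=50)
        assert min_partial == pytest.approx(0.0, abs=1e-12)
        assert argmin == 2
        assert pair_p == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(6, 40))
        corr, _ = spearman_matrix(_frame(values))
        s = _pairwise_stats(corr, n=40)
        for key in ("pair_p", "min_partial"):
            np.testing.assert_allclose(s[key], s[key].T, atol=1e-12,
                                       equal_nan=True)


class TestBuildNetwork:
    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(6)
        study = _study_from_matrix(rng.normal(size=(10, 30)))
        net = build_network(study, "post", alpha=0.0)
        assert net.n_edges == 0

    def test_planted_module_recovery(self):
        # 5-gene module at rho_s = 0.9, n = 60.  The first-order screen caps
        # each within-module partial at rho/(1+rho) ~ 0.47 (every other
        # member explains part of the pair), so full 10-edge recovery is not
        # guaranteed; most edges are recovered, always with + sign.
        total, minimum = 0, 10
        for seed in range(10):
            spec = SyntheticSpec(n_genes=5, n_samples=(5, 60),
                                 modules=[PlantedModule((0, 1, 2, 3, 4),
                                                        rho_s=0.9,
                                                        condition="post")],
                                 seed=seed)
            study, _ = simulate(spec)
            net = build_network(study, "post")
            assert (net.edges["sign"] == 1).all()
            total += net.n_edges
            minimum = min(minimum, net.n_edges)
        assert total >= 60      # >= 60% of the 100 plantable edges
        assert minimum >= 3

    def test_confounder_pair_screened_out(self):
        spec = SyntheticSpec(n_genes=3, n_samples=(5, 500),
                             triads=[ConfounderTriad(driver=0, driven=(1, 2),
                                                     rho_s=0.8,
                                                     condition="post")],
                             seed=2)
        study, _ = simulate(spec)
        net = build_network(study, "post")
        pairs = net.pairs()
        assert ("G0000", "G0001") in pairs and ("G0000", "G0002") in pairs
        assert ("G0001", "G0002") not in pairs

    def test_sample_reorder_invariance(self):
        rng = np.random.default_rng(7)
        study = _study_from_matrix(rng.normal(size=(8, 40)))
        shuffled = study.expr.sample(frac=1, axis=1, random_state=1)
        study2 = ExpressionStudy(expr=shuffled,
                                 condition=study.condition[shuffled.columns])
        a = build_network(study, "post", alpha=0.2)
        b = build_network(study2, "post", alpha=0.2)
        pd.testing.assert_frame_equal(a.edges, b.edges)

    def test_single_gene_universe_warns_empty(self):
        rng = np.random.default_rng(8)
        study = _study_from_matrix(rng.normal(size=(3, 20)))
        net = build_network(study, "post", universe={"g0"})
        assert net.n_edges == 0


class TestPermutationNull:
    def test_empirical_p_formula(self):
        from coexpareto.coexpression import PermutationNull
        null = PermutationNull(B=1, null_counts=np.array([0]),
                               observed_count=5)
        assert null.empirical_p == pytest.approx(0.5)    # (1+0)/2
        null = PermutationNull(B=1000, null_counts=np.zeros(1000, dtype=int),
                               observed_count=1)
        assert null.empirical_p == pytest.approx(1 / 1001)

    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_genes=8, n_samples=(5, 30), seed=3)
        study, _ = simulate(spec)
        a = permutation_null(study, "post", B=20, seed=9)
        b = permutation_null(study, "post", B=20, seed=9)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)
        assert a.observed_count == b.observed_count

    def test_planted_structure_rejects_null(self):
        spec = SyntheticSpec(
            n_genes=10, n_samples=(5, 60),
            modules=[PlantedModule(tuple(range(6)), rho_s=0.9,
                                   condition="post")], seed=4)
        study, _ = simulate(spec)
        null = permutation_null(study, "post", B=99, seed=1)
        assert null.empirical_p == pytest.approx(1 / 100)
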