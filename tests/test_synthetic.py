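"""Generator correctness: copula calibration, planted structure, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from coexpareto import (ConfigurationError, ConfounderTriad, PlantedHub,
                        PlantedModule, SyntheticSpec,
                        assemble_target_correlation, simulate,
                        spearman_to_pearson)
from coexpareto.coexpression import first_order_partial


class TestSpearmanToPearson:
    @pytest.mark.parametrize("rho_s, expected", [
        (0.0, 0.0),
        (1.0, 1.0),
        (-1.0, -1.0),
        (0.5, 2 * math.sin(math.pi / 12)),   # 0.51764...
    ])
    def test_known_values(self, rho_s, expected):
        assert spearman_to_pearson(rho_s) == pytest.approx(expected, abs=1e-5)

    def test_odd_function(self):
        for r in np.linspace(0, 1, 11):
            assert spearman_to_pearson(-r) == pytest.approx(
                -spearman_to_pearson(r), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            spearman_to_pearson(1.5)


class TestAssembleTargetCorrelation:
    def test_no_structure_is_identity(self):
        spec = SyntheticSpec(n_genes=6, seed=0)
        for cond in ("pre", "post"):
            np.testing.assert_array_equal(
                assemble_target_correlation(spec, cond), np.eye(6))

    def test_module_entry_is_converted_target(self):
        spec = SyntheticSpec(
            n_genes=4, modules=[PlantedModule((0, 1), rho_s=0.9)], seed=0)
        corr = assemble_target_correlation(spec, "pre")
        assert corr[0, 1] == pytest.approx(spearman_to_pearson(0.9), abs=1e-12)
        assert corr[0, 1] == corr[1, 0]

    def test_hub_row_signs_and_magnitude(self):
        # 2 positive + 1 negative partners at rho_s = 0.6: hub-row entries
        # have signs (+, +, -) and magnitude 2*sin(0.1*pi)
        spec = SyntheticSpec(
            n_genes=4,
            hubs=[PlantedHub(hub=0, n_pos=2, n_neg=1, rho_s=0.6,
                             partners_pos=(1, 2), partners_neg=(3,))],
            seed=0)
        corr = assemble_target_correlation(spec, "post")
        r = 2 * math.sin(0.1 * math.pi)
        assert corr[0, 1] == pytest.approx(r, abs=1e-6)
        assert corr[0, 2] == pytest.approx(r, abs=1e-6)
        assert corr[0, 3] == pytest.approx(-r, abs=1e-6)

    def test_condition_masks(self):
        spec = SyntheticSpec(
            n_genes=4, modules=[PlantedModule((0, 1), rho_s=0.8,
                                              condition="post")], seed=0)
        assert assemble_target_correlation(spec, "pre")[0, 1] == 0.0
        assert assemble_target_correlation(spec, "post")[0, 1] != 0.0

    def test_conflicting_assignment_names_pair(self):
        spec = SyntheticSpec.__new__(SyntheticSpec)  # bypass validation
        spec.n_genes = 3
        spec.n_samples = (10, 10)
        spec.modules = [PlantedModule((0, 1), rho_s=0.8),
                        PlantedModule((0, 1), rho_s=0.3)]
        spec.hubs, spec.triads, spec.de_genes = [], [], {}
        with pytest.raises(ConfigurationError, match=r"\(0, 1\)"):
            assemble_target_correlation(spec, "pre")

    def test_output_is_psd_with_unit_diagonal(self):
        spec = SyntheticSpec(
            n_genes=30,
            hubs=[PlantedHub(hub=0, n_pos=15, n_neg=10, rho_s=0.7)],
            triads=[ConfounderTriad(driver=26, driven=(27, 28), rho_s=0.8)],
            seed=0)
        corr = assemble_target_correlation(spec, "post")
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(corr)[0] > -1e-10


class TestSpecValidation:
    def test_hub_partner_budget(self):
        with pytest.raises(ConfigurationError, match="exceeds n_genes"):
            SyntheticSpec(n_genes=10,
                          hubs=[PlantedHub(hub=0, n_pos=8, n_neg=6, rho_s=0.5)])

    def test_gene_id_range(self):
        with pytest.raises(ConfigurationError, match="out of range"):
            SyntheticSpec(n_genes=3, modules=[PlantedModule((0, 5), rho_s=0.5)])

    def test_target_rho_below_one(self):
        with pytest.raises(ConfigurationError):
            SyntheticSpec(n_genes=3, modules=[PlantedModule((0, 1), rho_s=1.0)])

    def test_partners_resolved_disjointly(self):
        spec = SyntheticSpec(
            n_genes=20,
            modules=[PlantedModule((0, 1), rho_s=0.5)],
            hubs=[PlantedHub(hub=2, n_pos=3, n_neg=2, rho_s=0.5)],
            de_genes={3: 1.0})
        partners = set(spec.hubs[0].partners_pos + spec.hubs[0].partners_neg)
        assert len(partners) == 5
        assert partners.isdisjoint({0, 1, 2, 3})


class TestSimulate:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_genes=10, n_samples=(8, 8),
                             modules=[PlantedModule((0, 1), rho_s=0.7)], seed=3)
        a, _ = simulate(spec)
        b, _ = simulate(spec)
        np.testing.assert_array_equal(a.expr.to_numpy(), b.expr.to_numpy())
        assert list(a.expr.columns) == list(b.expr.columns)

    def test_copula_fidelity_at_n200(self):
        # realized Spearman of a planted rho_s = 0.9 pair within 0.05
        spec = SyntheticSpec(n_genes=5, n_samples=(200, 5),
                             modules=[PlantedModule((0, 1), rho_s=0.9,
                                                    condition="pre")], seed=7)
        study, _ = simulate(spec)
        pre = study.subset("pre")
        rho = stats.spearmanr(pre.iloc[0], pre.iloc[1]).statistic
        assert rho == pytest.approx(0.9, abs=0.05)

    def test_confounder_partial_is_small(self):
        # partial Spearman of the driven pair given the driver, n = 500
        spec = SyntheticSpec(n_genes=3, n_samples=(500, 5),
                             triads=[ConfounderTriad(driver=0, driven=(1, 2),
                                                     rho_s=0.8,
                                                     condition="pre")], seed=11)
        study, _ = simulate(spec)
        ranks = stats.rankdata(study.subset("pre").to_numpy(), axis=1)
        corr = np.corrcoef(ranks)
        partial = first_order_partial(corr[1, 2], corr[0, 1], corr[0, 2])
        assert abs(partial) < 0.1
        assert abs(corr[1, 2]) > 0.4   # marginally correlated nonetheless

    def test_type_one_error_calibration(self):
        # all-independent genes: ~5% of pairwise Spearman tests at p < 0.05
        from coexpareto.coexpression import partial_p_value
        fractions = []
        for seed in range(20):
            spec = SyntheticSpec(n_genes=50, n_samples=(100, 5), seed=seed)
            study, _ = simulate(spec)
            ranks = stats.rankdata(study.subset("pre").to_numpy(), axis=1)
            corr = np.clip(np.corrcoef(ranks), -1, 1)
            iu, ju = np.triu_indices(50, k=1)
            p = partial_p_value(corr[iu, ju], n=100, k=0)
            fractions.append((p < 0.05).mean())
        assert np.mean(fractions) == pytest.approx(0.05, abs=0.01)

    def test_de_shift_applied_to_post_only(self):
        spec = SyntheticSpec(n_genes=4, n_samples=(400, 400),
                             de_genes={0: 2.0}, noise_sd=0.5, seed=5)
        study, truth = simulate(spec)
        shift = study.subset("post").mean(axis=1) - study.subset("pre").mean(axis=1)
        assert shift.iloc[0] == pytest.approx(2.0, abs=0.15)
        assert abs(shift.iloc[1]) < 0.15
        assert truth.de_genes == {0}

    def test_truth_tables_consistent(self):
        spec = SyntheticSpec(
            n_genes=12,
            modules=[PlantedModule((0, 1), rho_s=0.8, condition="pre")],
            hubs=[PlantedHub(hub=2, n_pos=2, n_neg=1, rho_s=0.6,
                             condition="post",
                             partners_pos=(3, 4), partners_neg=(5,))],
            triads=[ConfounderTriad(driver=6, driven=(7, 8), rho_s=0.7,
                                    condition="both")],
            seed=0)
        _, truth = simulate(spec)
        assert (0, 1, 1) in truth.true_edges_pre
        assert (0, 1, 1) not in truth.true_edges_post
        assert {(2, 3, 1), (2, 4, 1), (2, 5, -1)} <= truth.true_edges_post
        assert (7, 8) in truth.confounder_pairs
        assert (3, 4) in truth.confounder_pairs   # hub siblings are non-edges
        # confounder pairs never appear as true edges of the same condition
        for cond in ("pre", "post"):
            assert truth.confounder_pairs.isdisjoint(truth.edge_pairs(cond))
        assert truth.hub_ids == {2}

    def test_zero_samples_rejected(self):
        spec = SyntheticSpec(n_genes=3, n_samples=(0, 10), seed=0)
        with pytest.raises(ConfigurationError):
            simulate(spec)
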