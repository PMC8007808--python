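import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from comodule.data import ConfigurationError
from comodule.detection import (
    Dendrogram,
    ModuleAssignment,
    average_linkage_cluster,
    dynamic_tree_cut,
    gene_significance,
    gs_mm_quality,
    module_eigengenes,
    module_membership,
)
from comodule.network import (
    correlation_matrix,
    signed_adjacency,
    tom_dissimilarity,
    topological_overlap,
)
from comodule.simulate import SimulationConfig, generate_dataset

from .conftest import make_expression


def detect_modules(expr, beta=10, **cut_kwargs):
    cor = correlation_matrix(expr)
    tom = topological_overlap(signed_adjacency(cor, beta=beta))
    dend = average_linkage_cluster(tom_dissimilarity(tom), tom.gene_ids)
    return dend, dynamic_tree_cut(dend, **cut_kwargs)


class TestAverageLinkage:
    def test_two_zero_blocks(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        dend = average_linkage_cluster(d, list("abcdef"))
        h = np.sort(dend.heights)
        np.testing.assert_allclose(h[:4], 0.0, atol=1e-12)
        assert h[-1] == pytest.approx(1.0)

    def test_four_leaf_hand_instance(self):
        # d(a,b)=0.1, d(c,d)=0.2, all cross distances 0.8:
        # UPGMA merges at 0.1, 0.2 and finally mean(cross) = 0.8
        d = np.full((4, 4), 0.8)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        dend = average_linkage_cluster(d, list("abcd"))
        np.testing.assert_allclose(np.sort(dend.heights), [0.1, 0.2, 0.8], atol=1e-12)

    def test_permutation_invariance(self, rng):
        n = 12
        d = rng.random((n, n))
        d = (d + d.T) / 2  # generic: no ties
        np.fill_diagonal(d, 0.0)
        ids = [f"g{i}" for i in range(n)]
        dend = average_linkage_cluster(d, ids)
        perm = rng.permutation(n)
        dend_p = average_linkage_cluster(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        np.testing.assert_allclose(np.sort(dend.heights), np.sort(dend_p.heights), atol=1e-12)
        # same partition at a mid-range cut
        cut = np.median(dend.heights)
        a1 = dynamic_tree_cut(dend, min_module_size=2, cut_height=cut)
        a2 = dynamic_tree_cut(dend_p, min_module_size=2, cut_height=cut)
        lab1 = [a1.labels[g] for g in ids]
        lab2 = [a2.labels[g] for g in ids]
        assert adjusted_rand_score(lab1, lab2) == pytest.approx(1.0)

    def test_asymmetric_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage_cluster(d, list("abc"))

    def test_nonzero_diagonal_rejected(self):
        d = np.eye(3)
        with pytest.raises(ValueError, match="diagonal"):
            average_linkage_cluster(d, list("abc"))

    def test_newick_roundtrip(self, rng):
        import dendropy

        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [f"g{i}" for i in range(8)]
        dend = average_linkage_cluster(d, ids)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert sorted(t.label for t in tree.taxon_namespace) == sorted(ids)
        # root age equals the final merge height
        tree.calc_node_ages(ultrametricity_precision=1e-6)
        assert tree.seed_node.age == pytest.approx(dend.max_height, abs=1e-6)


class TestDynamicTreeCut:
    def test_planted_blocks_perfect_recovery(self):
        cfg = SimulationConfig(
            n_samples=300, module_sizes=(50, 40), n_background=300,
            loading_range=(0.6, 0.9), seed=2,
        )
        expr, _, truth = generate_dataset(cfg)
        _, assign = detect_modules(expr, min_module_size=10)
        planted = np.array([truth.gene_module_labels[g] for g in expr.gene_ids])
        found = np.array([assign.labels[g] for g in expr.gene_ids])
        mask = planted != 0
        assert adjusted_rand_score(planted[mask], found[mask]) == pytest.approx(1.0)
        assert len(assign.module_labels) == 2

    def test_small_block_demoted_to_grey(self):
        cfg = SimulationConfig(
            n_samples=300, module_sizes=(40, 5), n_background=200,
            loading_range=(0.7, 0.9), seed=3,
        )
        expr, _, truth = generate_dataset(cfg)
        _, assign = detect_modules(expr, min_module_size=10)
        small = truth.module_members(2)
        assert all(assign.labels[g] == 0 for g in small)

    def test_pure_noise_mostly_grey(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = make_expression(rng.standard_normal((150, 300)))
            _, assign = detect_modules(expr, min_module_size=10)
            fracs.append(np.mean([v == 0 for v in assign.labels.values()]))
        assert np.mean(fracs) >= 0.8

    def test_min_size_monotone_module_count(self, small_dataset):
        expr, _, _ = small_dataset
        dend, _ = detect_modules(expr, min_module_size=10)
        counts = [
            len(dynamic_tree_cut(dend, min_module_size=s).module_labels)
            for s in (5, 10, 30)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_min_size_below_two_rejected(self, small_dataset):
        expr, _, _ = small_dataset
        dend, _ = detect_modules(expr)
        with pytest.raises(ConfigurationError):
            dynamic_tree_cut(dend, min_module_size=1)

    def test_bad_cut_height_rejected(self, small_dataset):
        expr, _, _ = small_dataset
        dend, _ = detect_modules(expr)
        with pytest.raises(ConfigurationError):
            dynamic_tree_cut(dend, cut_height=dend.max_height * 2)

    def test_labels_ordered_by_size_with_colors(self):
        cfg = SimulationConfig(
            n_samples=300, module_sizes=(20, 60), n_background=200,
            loading_range=(0.7, 0.9), seed=4,
        )
        expr, _, truth = generate_dataset(cfg)
        _, assign = detect_modules(expr, min_module_size=10)
        sizes = assign.sizes()
        mods = assign.module_labels
        ordered = [sizes[m] for m in mods]
        assert ordered == sorted(ordered, reverse=True)
        # module 1 is the largest and is named by the first palette colour
        assert sizes[1] == max(sizes[m] for m in mods)
        assert assign.color_of(1) == "turquoise"
        assert assign.color_of(0) == "grey"


class TestModuleEigengenes:
    def test_single_gene_module(self, rng):
        x = rng.standard_normal((30, 1))
        expr = make_expression(x)
        assign = ModuleAssignment({"G0": 1})
        eig = module_eigengenes(expr, assign)
        z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1)
        np.testing.assert_allclose(eig.scores.iloc[:, 0], z, atol=1e-10)
        assert eig.variance_explained[0] == pytest.approx(1.0)

    def test_duplicated_genes_module(self, rng):
        x = rng.standard_normal((25, 1))
        expr = make_expression(np.hstack([x] * 4))
        assign = ModuleAssignment({f"G{i}": 1 for i in range(4)})
        eig = module_eigengenes(expr, assign)
        z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1)
        np.testing.assert_allclose(eig.scores.iloc[:, 0], z, atol=1e-10)
        assert eig.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_eigen_oracle(self, rng):
        x = rng.standard_normal((40, 20))
        expr = make_expression(x)
        assign = ModuleAssignment({f"G{i}": 1 for i in range(20)})
        eig = module_eigengenes(expr, assign)
        evals = np.linalg.eigvalsh(np.corrcoef(x, rowvar=False))
        assert eig.variance_explained[0] == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-8
        )

    def test_duplication_invariance(self, rng):
        x = rng.standard_normal((30, 8))
        expr1 = make_expression(x)
        a1 = ModuleAssignment({f"G{i}": 1 for i in range(8)})
        e1 = module_eigengenes(expr1, a1)
        expr2 = make_expression(np.hstack([x, x]))
        a2 = ModuleAssignment({f"G{i}": 1 for i in range(16)})
        e2 = module_eigengenes(expr2, a2)
        np.testing.assert_allclose(
            e1.scores.iloc[:, 0], e2.scores.iloc[:, 0], atol=1e-8
        )

    def test_zero_mean_columns(self, small_dataset):
        expr, _, truth = small_dataset
        assign = ModuleAssignment(dict(truth.gene_module_labels))
        eig = module_eigengenes(expr, assign)
        np.testing.assert_allclose(eig.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_orientation_positive_vs_mean_profile(self, small_dataset):
        expr, _, truth = small_dataset
        assign = ModuleAssignment(dict(truth.gene_module_labels))
        eig = module_eigengenes(expr, assign)
        frame = expr.to_frame()
        for col, m in zip(eig.scores.columns, eig.module_labels):
            z = frame[assign.members(m)].apply(lambda c: (c - c.mean()) / c.std(ddof=1))
            r = np.corrcoef(eig.scores[col], z.mean(axis=1))[0, 1]
            assert r >= 0

    def test_empty_module_rejected(self, rng):
        expr = make_expression(rng.standard_normal((10, 2)))
        assign = ModuleAssignment({"G0": 1, "G1": 1, "ABSENT": 2})
        with pytest.raises(ValueError, match="no member"):
            module_eigengenes(expr, assign)


class TestModuleMembership:
    def test_sole_member_mm_one(self, rng):
        expr = make_expression(rng.standard_normal((30, 1)))
        assign = ModuleAssignment({"G0": 1})
        eig = module_eigengenes(expr, assign)
        mm = module_membership(expr, eig)
        assert mm.iloc[0, 0] == pytest.approx(1.0)

    def test_negated_eigengene_mm_minus_one(self, rng):
        x = rng.standard_normal((30, 1))
        expr = make_expression(np.hstack([x, -x]))
        assign = ModuleAssignment({"G0": 1})
        eig = module_eigengenes(expr, assign)
        mm = module_membership(expr, eig)
        assert mm.loc["G1"].iloc[0] == pytest.approx(-1.0)

    def test_direct_formula_spot_check(self, small_dataset, rng):
        expr, _, truth = small_dataset
        assign = ModuleAssignment(dict(truth.gene_module_labels))
        eig = module_eigengenes(expr, assign)
        mm = module_membership(expr, eig)
        frame = expr.to_frame()
        genes = rng.choice(expr.gene_ids, 5, replace=False)
        for g in genes:
            for col in eig.scores.columns:
                expected = np.corrcoef(frame[g], eig.scores[col])[0, 1]
                assert mm.loc[g, col] == pytest.approx(expected, abs=1e-12)


class TestGeneSignificance:
    def test_trait_equal_to_gene(self, small_dataset):
        expr, traits, _ = small_dataset
        t2 = traits.traits.copy()
        t2["CIMTavg"] = expr.to_frame()["G000001"]
        from comodule.data import TraitTable

        table = TraitTable(t2, traits.covariates, traits.trait_groups)
        gs = gene_significance(expr, table)
        assert gs.loc["G000001", "CIMTavg"] == pytest.approx(1.0)

    def test_noise_trait_small_gs(self):
        cfg = SimulationConfig(
            n_samples=1000, module_sizes=(2,), n_background=500,
            trait_effects=np.zeros((10, 1)), seed=8,
        )
        expr, traits, _ = generate_dataset(cfg)
        gs = gene_significance(expr, traits)
        assert (gs["CIMTavg"].abs() < 0.1).mean() >= 0.98

    def test_row_permutation_invariance(self, small_dataset):
        expr, traits, _ = small_dataset
        from comodule.data import TraitTable

        perm = np.random.default_rng(0).permutation(len(traits.traits))
        table = TraitTable(
            traits.traits.iloc[perm], traits.covariates.iloc[perm], traits.trait_groups
        )
        gs1 = gene_significance(expr, traits)
        gs2 = gene_significance(expr, table)
        np.testing.assert_allclose(gs1.to_numpy(), gs2.to_numpy(), atol=1e-12)

    def test_too_few_shared_samples(self, rng):
        expr = make_expression(rng.standard_normal((10, 3)))
        from comodule.data import TraitTable
        import pandas as pd

        table = TraitTable(
            pd.DataFrame({"CIMTavg": [1.0, 2.0]}, index=["X1", "X2"]),
            pd.DataFrame(index=["X1", "X2"]),
            {"CIMTavg": "athero"},
        )
        with pytest.raises(ValueError, match="shared samples"):
            gene_significance(expr, table)


class TestGsMmQuality:
    def test_gs_equal_mm_r_one(self, rng):
        v = rng.random(10)
        rec = gs_mm_quality(v, v, [f"g{i}" for i in range(10)])
        assert rec.r_gs_mm == pytest.approx(1.0)
        assert rec.p_value < 1e-10

    def test_three_gene_boundary(self):
        rec = gs_mm_quality(
            np.array([0.1, 0.2, 0.3]), np.array([0.1, 0.2, 0.3]), ["a", "b", "c"]
        )
        assert rec.n_members == 3
        assert rec.p_value == 0.0  # |r| = 1 handled at the boundary

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            gs_mm_quality(np.array([0.1, 0.2]), np.array([0.1, 0.2]), ["a", "b"])

    def test_driver_module_high_gs_mm(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = SimulationConfig(
                n_samples=300, module_sizes=(30,), n_background=0,
                trait_effects=np.vstack([np.full((1, 1), 0.5)] * 10), seed=seed,
            )
            expr, traits, truth = generate_dataset(cfg)
            assign = ModuleAssignment(dict(truth.gene_module_labels))
            eig = module_eigengenes(expr, assign)
            gs = gene_significance(expr, traits)
            mm = module_membership(expr, eig)
            members = truth.module_members(1)
            rec = gs_mm_quality(gs["CIMTavg"], mm.iloc[:, 0], members, 1, "CIMTavg")
            hits += rec.r_gs_mm > 0.34
        assert hits >= int(0.9 * n_runs)
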