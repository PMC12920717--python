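"""HSC cohort simulator: determinism, clonal-expansion bookkeeping, mutation
clock, and the ground-truth decay identity."""

from __future__ import annotations

import numpy as np
import pytest

import vfsage as v
from _oracles import decay_by_tree_traversal


class TestSimulateIndividual:
    def test_deterministic_given_seed(self):
        params = v.SimulationParams(n_lineages=60, seed=4)
        a = v.simulate_individual(40, params)
        b = v.simulate_individual(40, params)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert list(a.vfs.variant_ids) == list(b.vfs.variant_ids)
        np.testing.assert_array_equal(a.vfs.vaf, b.vfs.vaf)
        assert a.ch_events == b.ch_events

    def test_star_like_young_individual(self):
        """Without clonal expansions and with negligible embryonic branch
        lengths, every mutation is tip-private, so the thresholded spectrum
        is empty and the decay metric is zero."""
        params = v.SimulationParams(n_lineages=300, ch_rate=0,
                                    embryonic_window=1e-6, seed=2)
        ind = v.simulate_individual(0.2, params)
        assert ind.ch_events == []
        assert np.all(ind.vfs.vaf <= 1.0 / 600 + 1e-12)
        filtered = v.filter_tip_variants(ind.vfs, 0.01)
        assert len(filtered) == 0
        assert v.lambda_metric(ind.vfs) == 0.0
        assert ind.true_decay == 0.0

    def test_forced_clade_frequency_and_truth(self):
        """A clade of 60/300 tips founded at age 10 places every founding-
        branch mutation at VAF 0.10; with no other shared branches the truth
        is exactly 0.10 × (founding-branch mutation count)."""
        params = v.SimulationParams(n_lineages=300, ch_rate=0,
                                    embryonic_window=1e-6, clade_spread=0.0,
                                    seed=5)
        ind = v.simulate_individual(40, params, forced_ch_events=[(10.0, 60)])
        assert ind.ch_events == [(10.0, 60)]
        assert ind.tree.n_tips == 300
        counts = ind.tree.tip_counts()
        founding = [n for n in ind.tree.nodes()
                    if not n.is_tip and counts[n] == 60 and n.mutations]
        assert len(founding) == 1
        n_founding = len(founding[0].mutations)
        shared_vafs = ind.vfs.vaf[ind.vfs.vaf >= 0.01]
        assert len(shared_vafs) == n_founding
        np.testing.assert_allclose(shared_vafs, 0.10)
        assert ind.true_decay == pytest.approx(0.10 * n_founding, abs=1e-9)

    def test_forced_clade_too_large(self):
        params = v.SimulationParams(n_lineages=20, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            v.simulate_individual(40, params, forced_ch_events=[(10.0, 25)])

    def test_ultrametric_and_binary(self):
        ind = v.simulate_individual(
            35, v.SimulationParams(n_lineages=50, seed=8),
            forced_ch_events=[(12.0, 10)],
        )
        ind.tree.validate_ultrametric()
        for node in ind.tree.nodes():
            assert len(node.children) in (0, 2)

    def test_small_lineage_count_warns(self):
        with pytest.warns(UserWarning, match="n_lineages"):
            v.simulate_individual(30, v.SimulationParams(n_lineages=20, seed=1))

    def test_mutation_clock(self):
        """Mutations per tip lineage average mutation_rate × age."""
        rate, age = 17.0, 10.0
        ind = v.simulate_individual(
            age, v.SimulationParams(n_lineages=300, mutation_rate=rate, seed=9)
        )
        per_tip = []
        for tip in ind.tree.tips():
            count, node = 0, tip
            while node is not None:
                count += len(node.mutations)
                node = node.parent
            per_tip.append(count)
        mean = np.mean(per_tip)
        se = np.sqrt(rate * age / len(per_tip))
        assert abs(mean - rate * age) < 3 * se + 1e-9

    def test_clade_tip_bookkeeping(self):
        ind = v.simulate_individual(
            60, v.SimulationParams(n_lineages=100, seed=14),
            forced_ch_events=[(10.0, 30), (25.0, 20)],
        )
        assert ind.tree.n_tips == 100
        assert sum(size for _, size in ind.ch_events) <= 100


class TestTrueDecayIdentity:
    def test_identity_on_seeded_cohort(self):
        cohort = v.simulate_cohort(
            [20, 35, 50, 65, 80], v.SimulationParams(n_lineages=60, seed=21),
            seed=21,
        )
        for ind in cohort:
            lam = v.lambda_metric(ind.vfs, 0.01)
            assert lam == pytest.approx(ind.true_decay, abs=1e-9)
            assert decay_by_tree_traversal(ind.tree, 0.01) == pytest.approx(
                ind.true_decay, abs=1e-9
            )

    def test_star_tree_zero(self):
        ind = v.simulate_individual(
            5, v.SimulationParams(n_lineages=80, ch_rate=0,
                                  embryonic_window=1e-6, seed=3)
        )
        assert v.true_decay(ind.tree) == 0.0

    def test_single_internal_branch_arithmetic(self):
        """One shared branch at carrier fraction 0.5 with 7 mutations
        contributes 0.25 × 7."""
        from vfsage.trees import PhylogenyTree, TreeNode

        root = TreeNode(0.0, 1.0)
        left = TreeNode(1.0, 10.0)
        right = TreeNode(1.0, 10.0)
        root.add_child(left)
        root.add_child(right)
        for child, label0 in ((left, "a"), (right, "c")):
            child.add_child(TreeNode(10.0, 40.0, label=label0))
            child.add_child(TreeNode(10.0, 40.0, label=label0 + "2"))
        left.mutations = [f"m{i}" for i in range(7)]
        tree = PhylogenyTree(root, 40.0)
        assert v.true_decay(tree, 0.01) == pytest.approx(0.25 * 7)

    def test_matrix_consistent_with_tree_and_vfs(self):
        with pytest.warns(UserWarning, match="n_lineages"):
            ind = v.simulate_individual(
                30, v.SimulationParams(n_lineages=20, seed=6,
                                       embryonic_window=1e-6),
                forced_ch_events=[(8.0, 6)], build_matrix=True,
            )
        assert ind.matrix is not None
        counts = ind.tree.tip_counts()
        carriers_by_variant = {}
        for node in ind.tree.nodes():
            for mut in node.mutations:
                carriers_by_variant[mut] = counts[node]
        col_sums = ind.matrix.sum(axis=0)
        for vid in ind.vfs.variant_ids:
            assert col_sums[vid] == carriers_by_variant[vid]
        derived = v.genotype_matrix_to_vfs(ind.matrix)
        vaf_by_id = dict(zip(derived.variant_ids, derived.vaf))
        for vid, vaf in zip(ind.vfs.variant_ids, ind.vfs.vaf):
            assert vaf_by_id[vid] == pytest.approx(vaf, abs=1e-12)


class TestSimulateCohort:
    def test_deterministic(self):
        params = v.SimulationParams(n_lineages=60, seed=30)
        a = v.simulate_cohort([25, 55, 75], params, seed=30)
        b = v.simulate_cohort([25, 55, 75], params, seed=30)
        for x, y in zip(a, b):
            assert x.tree.to_newick() == y.tree.to_newick()
            np.testing.assert_array_equal(x.vfs.vaf, y.vfs.vaf)

    def test_empty_ages_error(self):
        with pytest.raises(ValueError):
            v.simulate_cohort([], v.SimulationParams())

    def test_singleton_cohort(self):
        cohort = v.simulate_cohort([42], v.SimulationParams(n_lineages=60,
                                                            seed=1))
        assert len(cohort) == 1 and cohort[0].age == 42

    def test_mean_decay_increases_with_age(self):
        """Age-dependent clonal expansion makes the expected decay metric
        grow across ages 10 → 40 → 80 (Monte-Carlo over 50 replicates)."""
        params = v.SimulationParams(n_lineages=100, seed=0)
        means = []
        for age in (10, 40, 80):
            lams = []
            for rep in range(50):
                ind = v.simulate_individual(
                    age, params, rng=np.random.default_rng([age, rep]),
                    tip_mutations=False,
                )
                lams.append(v.lambda_metric(ind.vfs))
            means.append(np.mean(lams))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]


class TestCalibratedCohort:
    def test_noiseless_exact(self):
        cohort = v.calibrated_cohort(-1.65, 0.084, [50])
        assert cohort[0][1] == pytest.approx(np.exp(2.55), abs=1e-9)
        assert cohort[0][1] == pytest.approx(12.807, abs=1e-3)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            v.calibrated_cohort(-1.65, -0.01, [20, 40])

    def test_seeded_noise_reproducible(self):
        a = v.calibrated_cohort(-1.65, 0.084, [20, 40, 60], noise_sigma=0.3,
                                seed=7)
        b = v.calibrated_cohort(-1.65, 0.084, [20, 40, 60], noise_sigma=0.3,
                                seed=7)
        assert a == b
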