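import numpy as np
import pytest

from stweave import SimConfig, simulate
from stweave.evaluate import ari, cluster_embeddings
from stweave.preprocess import pca_embed
from stweave.simulate import (apply_dropout, assign_labels_ambiguous,
                              assign_labels_distinct, calibrate_tau,
                              confound_map, grid_coords, place_centers,
                              sample_modality)


class TestPlaceCenters:
    def test_deterministic_per_seed(self):
        a = place_centers(6, (30, 30), seed=4)
        b = place_centers(6, (30, 30), seed=4)
        np.testing.assert_array_equal(a, b)

    def test_k4_well_separated_on_30x30(self):
        c = place_centers(4, (30, 30), seed=0)
        D = np.linalg.norm(c[:, None] - c[None], axis=2)
        assert D[np.triu_indices(4, 1)].min() >= 10

    def test_k1_near_middle(self):
        c = place_centers(1, (30, 30), seed=1)
        assert np.all(np.abs(c[0] - 15) < 3)


class TestLabelAssignment:
    def test_distinct_matches_brute_force(self, rng):
        coords = rng.uniform(0, 30, (50, 2))
        centers = place_centers(5, (30, 30), seed=2)
        labels = assign_labels_distinct(coords, centers)
        for i in range(50):
            d = [np.linalg.norm(coords[i] - c) for c in centers]
            assert labels[i] == int(np.argmin(d))

    def test_spot_at_center_gets_that_label(self):
        centers = place_centers(4, (30, 30), seed=0)
        labels = assign_labels_distinct(centers, centers)
        np.testing.assert_array_equal(labels, np.arange(4))

    def test_tiny_tau_recovers_distinct(self):
        coords = grid_coords((20, 20))
        centers = place_centers(4, (20, 20), seed=1)
        amb, _ = assign_labels_ambiguous(coords, centers, tau=1e-4, seed=0)
        np.testing.assert_array_equal(amb, assign_labels_distinct(coords, centers))

    def test_huge_tau_near_uniform(self):
        coords = grid_coords((30, 30))
        centers = place_centers(4, (30, 30), seed=1)
        amb, _ = assign_labels_ambiguous(coords, centers, tau=1e5, seed=0)
        freq = np.bincount(amb, minlength=4) / 900
        bound = 3 * np.sqrt(0.25 * 0.75 / 900)
        assert np.all(np.abs(freq - 0.25) < bound)

    def test_auto_tau_calibrated_to_80pct_agreement(self):
        coords = grid_coords((30, 30))
        centers = place_centers(10, (30, 30), seed=3)
        nearest = assign_labels_distinct(coords, centers)
        agrees = []
        for seed in range(10):
            amb, tau = assign_labels_ambiguous(coords, centers, "auto", seed)
            agrees.append(np.mean(amb == nearest))
            assert tau > 0
        assert 0.77 <= np.mean(agrees) <= 0.83
        assert all(0.74 <= a <= 0.86 for a in agrees)

    def test_calibrate_tau_hits_expected_agreement(self):
        coords = grid_coords((20, 20))
        centers = place_centers(6, (20, 20), seed=0)
        tau = calibrate_tau(coords, centers, target_agreement=0.8)
        from stweave.simulate import _softmax_probs
        P = _softmax_probs(coords, centers, tau)
        nearest = assign_labels_distinct(coords, centers)
        assert P[np.arange(400), nearest].mean() == pytest.approx(0.8, abs=0.01)


class TestConfoundMap:
    def test_k4_enumeration(self):
        gmap, imap = confound_map(4)
        np.testing.assert_array_equal(gmap, [0, 0, 1, 1])
        np.testing.assert_array_equal(imap, [0, 1, 1, 0])
        joint = set(zip(gmap, imap))
        assert len(joint) == 4   # all clusters recoverable from the pair

    def test_k10_joint_codes_distinct(self):
        gmap, imap = confound_map(10)
        assert len(set(gmap)) == 5 and len(set(imap)) == 5
        assert len(set(zip(gmap, imap))) == 10

    @pytest.mark.parametrize("k", [4, 6, 8, 10])
    def test_group_counts(self, k):
        gmap, imap = confound_map(k)
        assert len(set(gmap)) == k // 2 == len(set(imap))

    def test_odd_k_fatal(self):
        with pytest.raises(ValueError, match="even"):
            confound_map(5)


class TestSampleModality:
    def test_marker_block_means_near_effect(self):
        groups = np.repeat(np.arange(3), 300)
        X = sample_modality(groups, n_feat=60, effect=1.0, noise=1.0,
                            markers_per_group=10, seed=0)
        for g in range(3):
            block = X[groups == g][:, g * 10:(g + 1) * 10]
            assert abs(block.mean() - 1.0) < 3 / np.sqrt(block.size)

    def test_zero_noise_groups_identical_and_recoverable(self):
        groups = np.repeat(np.arange(2), 20)
        X = sample_modality(groups, 40, effect=1.0, noise=1e-9,
                            markers_per_group=5, seed=1)
        from stweave import EmbeddingSet
        labels = cluster_embeddings(EmbeddingSet(X, "x"), 2, seed=0).labels
        assert ari(labels, groups) == 1.0

    def test_zero_effect_no_structure(self):
        rng_groups = np.repeat(np.arange(5), 180)
        X = sample_modality(rng_groups, 100, effect=1e-12, noise=1.0,
                            markers_per_group=20, seed=2)
        from stweave import EmbeddingSet
        labels = cluster_embeddings(EmbeddingSet(X, "x"), 5, seed=0).labels
        assert abs(ari(labels, rng_groups)) < 0.05

    def test_too_many_markers_fatal(self):
        with pytest.raises(ValueError, match="exceed"):
            sample_modality(np.array([0, 1]), 10, markers_per_group=6)


class TestApplyDropout:
    def test_zero_rate_identity(self, rng):
        X = rng.normal(size=(50, 20))
        np.testing.assert_array_equal(apply_dropout(X, 0.0, 0), X)

    def test_rate_within_binomial_bound(self, rng):
        X = rng.normal(size=(900, 200))
        out = apply_dropout(X, 0.9, seed=3)
        frac = np.mean(out == 0.0)
        assert abs(frac - 0.9) < 0.003

    def test_same_seed_same_mask(self, rng):
        X = rng.normal(size=(30, 30))
        np.testing.assert_array_equal(apply_dropout(X, 0.5, 7),
                                      apply_dropout(X, 0.5, 7))


class TestSimulate:
    def test_bitwise_reproducible(self):
        cfg = SimConfig(grid=(10, 10), k=4, dropout=0.5, seed=9)
        a, b = simulate(cfg), simulate(cfg)
        np.testing.assert_array_equal(a.dataset.expression, b.dataset.expression)
        np.testing.assert_array_equal(a.dataset.image_features,
                                      b.dataset.image_features)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_joint_codes_identify_labels(self, small_sim):
        seen = {}
        for lab, g, m in zip(small_sim.labels, small_sim.gene_groups,
                             small_sim.image_groups):
            assert seen.setdefault((g, m), lab) == lab

    def test_noiseless_concat_recovers_truth_exactly(self):
        res = simulate(SimConfig(grid=(20, 20), k=4, noise=1e-6, seed=2))
        from stweave import run_strategy
        emb = run_strategy(res.dataset, "CONCAT")
        labels = cluster_embeddings(emb, 4, seed=0).labels
        assert ari(labels, res.labels) == 1.0

    def test_single_modality_bounded_by_merge_ceiling(self):
        res = simulate(SimConfig(grid=(20, 20), k=4, noise=0.2, seed=4))
        from stweave import run_strategy
        for strat, groups in (("GENE", res.gene_groups),
                              ("IMAGE", res.image_groups)):
            emb = run_strategy(res.dataset, strat)
            labels = cluster_embeddings(emb, 4, seed=0).labels
            assert ari(res.labels, labels) <= ari(res.labels, groups) + 0.05

    def test_dropout_only_hits_expression(self):
        res = simulate(SimConfig(grid=(15, 15), k=4, dropout=0.8, seed=6))
        assert np.mean(res.dataset.expression == 0) > 0.7
        assert np.mean(res.dataset.image_features == 0) < 0.01

    def test_distinct_vs_ambiguous_spatial_coherence_split(self):
        """The distinct pattern passes the Average Similarity diagnostic
        at the 90% bar; the ambiguous pattern (tau auto) falls below it."""
        from stweave import avg_similarity_diag, spatial_neighbors
        from stweave.preprocess import preprocess_modality
        fracs = {}
        for pattern in ("distinct", "ambiguous"):
            fr = []
            for rep in range(3):
                res = simulate(SimConfig(pattern=pattern, seed=50 + rep))
                emb = preprocess_modality(res.dataset.expression)
                g = spatial_neighbors(res.dataset.coords, "grid")
                fr.append(avg_similarity_diag(emb, g, seed=rep)[1])
            fracs[pattern] = np.mean(fr)
        assert fracs["distinct"] >= 0.90
        assert fracs["ambiguous"] < 0.90

    def test_dropout_monotonically_degrades_gene_recovery(self):
        from stweave import run_strategy
        means = []
        for d in (0.0, 0.3, 0.6, 0.9):
            scores = []
            for rep in range(3):
                res = simulate(SimConfig(grid=(20, 20), k=4, dropout=d,
                                         seed=300 + rep))
                emb = run_strategy(res.dataset, "GENE")
                scores.append(ari(res.labels,
                                  cluster_embeddings(emb, 4, seed=rep).labels))
            means.append(np.mean(scores))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.05
        assert means[-1] < means[0]
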