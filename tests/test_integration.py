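import numpy as np
import pytest
from scipy.spatial.distance import pdist

from stweave import (EmbeddingSet, StrategySpec, affinity_fuse, concat_embed,
                     run_strategy, wnn_integrate)
from stweave.integration import StrategyParams


def _blobs(rng, n_per=20, centers=((0, 0), (8, 8), (0, 8)), dim=2, sd=0.5):
    mus = [np.pad(np.asarray(c, dtype=float), (0, dim - 2)) for c in centers]
    return np.vstack([rng.normal(mu, sd, size=(n_per, dim)) for mu in mus])


def wnn_weights_oracle(Zg, Zm, k):
    """Straight-line independent recomputation of the per-spot weights."""
    n = len(Zg)

    def knn(Z, i):
        d = [(np.linalg.norm(Z[i] - Z[j]), j) for j in range(n) if j != i]
        d.sort()
        return [j for _, j in d[:k]]

    w = np.empty(n)
    for i in range(n):
        r = {}
        for name, Zown, Zoth in (("g", Zg, Zm), ("m", Zm, Zg)):
            own_nb = knn(Zown, i)
            oth_nb = knn(Zoth, i)
            within = np.mean([Zown[j] for j in own_nb], axis=0)
            cross = np.mean([Zown[j] for j in oth_nb], axis=0)
            s = np.linalg.norm(Zown[i] - Zown[own_nb[0]]) + 1e-12
            r[name] = (np.linalg.norm(Zown[i] - cross)
                       - np.linalg.norm(Zown[i] - within)) / s
        w[i] = np.exp(r["g"]) / (np.exp(r["g"]) + np.exp(r["m"]))
    return w


def fused_affinity_oracle(Zg, Zm, k, w_gene):
    """Independent recomputation of the fused affinities as a dict."""
    n = len(Zg)

    def knn(Z, i):
        d = sorted((np.linalg.norm(Z[i] - Z[j]), j) for j in range(n) if j != i)
        return [j for _, j in d[:k]], [v for v, _ in d]

    half = int(np.ceil(k / 2))
    out = {}
    for i in range(n):
        nbg, dg = knn(Zg, i)
        nbm, dm = knn(Zm, i)
        sg = dg[half - 1] + 1e-12
        sm = dm[half - 1] + 1e-12
        for j in set(nbg) | set(nbm):
            out[(i, j)] = (w_gene[i] * np.exp(-np.linalg.norm(Zg[i] - Zg[j]) / sg)
                           + (1 - w_gene[i]) * np.exp(-np.linalg.norm(Zm[i] - Zm[j]) / sm))
    return out


class TestWnnIntegrate:
    def test_identical_modalities_weights_exactly_half(self, rng):
        Z = _blobs(rng)
        g = wnn_integrate(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), k_nn=5)
        np.testing.assert_array_equal(g.weights.w_gene, 0.5)
        np.testing.assert_array_equal(g.weights.w_image, 0.5)

    def test_structureless_image_modality_favors_gene(self, rng):
        # clustered gene embedding vs an uninformative (iid noise) image
        # embedding: the per-spot weights should lean toward gene.  Note a
        # row permutation would NOT do here: it destroys the spot
        # correspondence but keeps the modality internally predictable,
        # which is what the weight mechanism measures.
        Z = _blobs(rng, n_per=30, dim=4)
        noise = rng.normal(0, Z.std(), Z.shape)
        g = wnn_integrate(EmbeddingSet(Z, "g"), EmbeddingSet(noise, "m"), k_nn=10)
        assert g.weights.w_gene.mean() > 0.5

    def test_row_permuted_modality_stays_balanced(self, rng):
        # row permutation keeps within-modality structure, so neither
        # modality dominates on average
        Z = _blobs(rng, n_per=30, dim=4)
        perm = rng.permutation(len(Z))
        g = wnn_integrate(EmbeddingSet(Z, "g"), EmbeddingSet(Z[perm], "m"), k_nn=10)
        assert abs(g.weights.w_gene.mean() - 0.5) < 0.15

    def test_four_spot_toy_matches_oracle(self, rng):
        Zg = np.array([[0.0, 0], [1, 0], [0, 1], [3, 3]])
        Zm = np.array([[0.0, 0], [0, 1.5], [2, 0], [3, 2.5]])
        g = wnn_integrate(EmbeddingSet(Zg, "g"), EmbeddingSet(Zm, "m"), k_nn=2)
        np.testing.assert_allclose(g.weights.w_gene,
                                   wnn_weights_oracle(Zg, Zm, 2), atol=1e-10)
        oracle = fused_affinity_oracle(Zg, Zm, 2, g.weights.w_gene)
        assert len(oracle) == len(g.edges)
        for (i, j), a in zip(g.edges, g.affinities):
            assert a == pytest.approx(oracle[(i, j)], abs=1e-10)

    def test_weights_sum_to_one_random_inputs(self, rng):
        Zg = rng.normal(size=(40, 6))
        Zm = rng.normal(size=(40, 3))
        g = wnn_integrate(EmbeddingSet(Zg, "g"), EmbeddingSet(Zm, "m"), k_nn=8)
        np.testing.assert_allclose(g.weights.w_gene + g.weights.w_image, 1.0)
        assert g.affinities.min() >= 0 and g.affinities.max() <= 1

    def test_small_k_fatal(self, rng):
        Z = rng.normal(size=(10, 2))
        with pytest.raises(ValueError, match="k_nn"):
            wnn_integrate(EmbeddingSet(Z, "g"), EmbeddingSet(Z, "m"), k_nn=1)


class TestAffinityFuse:
    def test_identical_modalities_equals_wnn(self, rng):
        Z = _blobs(rng)
        f = affinity_fuse(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), k_nn=5)
        w = wnn_integrate(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), k_nn=5)
        np.testing.assert_array_equal(f.edges, w.edges)
        np.testing.assert_allclose(f.affinities, w.affinities, atol=1e-12)

    def test_toy_matches_oracle_at_half_weights(self, rng):
        Zg = rng.normal(size=(4, 2))
        Zm = rng.normal(size=(4, 2))
        f = affinity_fuse(EmbeddingSet(Zg, "g"), EmbeddingSet(Zm, "m"), k_nn=2)
        oracle = fused_affinity_oracle(Zg, Zm, 2, np.full(4, 0.5))
        for (i, j), a in zip(f.edges, f.affinities):
            assert a == pytest.approx(oracle[(i, j)], abs=1e-10)

    def test_duplicated_modality_preserves_knn_ranking(self, rng):
        Z = rng.normal(size=(15, 3))
        f = affinity_fuse(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), k_nn=4)
        A = f.to_matrix(symmetrize=False)
        D = np.linalg.norm(Z[:, None] - Z[None], axis=2)
        for i in range(15):
            js = np.where(A[i] > 0)[0]
            order_aff = js[np.argsort(-A[i, js], kind="stable")]
            order_dist = js[np.argsort(D[i, js], kind="stable")]
            np.testing.assert_array_equal(order_aff, order_dist)


class TestConcatEmbed:
    def test_alpha_one_is_standardized_gene(self, rng):
        Zg, Zm = rng.normal(size=(20, 4)), rng.normal(size=(20, 3))
        out = concat_embed(EmbeddingSet(Zg, "g"), EmbeddingSet(Zm, "m"), alpha=1.0)
        assert np.all(out.matrix[:, 4:] == 0)
        np.testing.assert_allclose(pdist(out.matrix),
                                   pdist(Zg) / np.sqrt((Zg - Zg.mean(0)).var(0).sum()),
                                   atol=1e-9)

    def test_alpha_zero_is_image_only(self, rng):
        Zg, Zm = rng.normal(size=(20, 4)), rng.normal(size=(20, 3))
        out = concat_embed(EmbeddingSet(Zg, "g"), EmbeddingSet(Zm, "m"), alpha=0.0)
        assert np.all(out.matrix[:, :4] == 0)

    def test_identical_modalities_sqrt2_scaling(self, rng):
        Z = rng.normal(size=(20, 4))
        single = concat_embed(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), 1.0)
        both = concat_embed(EmbeddingSet(Z, "g"), EmbeddingSet(Z.copy(), "m"), 0.5)
        np.testing.assert_allclose(pdist(both.matrix),
                                   pdist(single.matrix) * 0.5 * np.sqrt(2) / 1.0,
                                   atol=1e-9)


class TestStrategySpec:
    @pytest.mark.parametrize("raw", ["GENE", "IMAGE", "SME", "GENE+SK", "SME+SK",
                                     "WNN", "SK+WNN", "SME+WNN", "SME+SK+WNN",
                                     "FUSE", "CONCAT", "sk+wnn"])
    def test_valid_strings_parse(self, raw):
        spec = StrategySpec.parse(raw)
        assert spec.raw == raw.upper()

    @pytest.mark.parametrize("raw,msg", [
        ("GENE+BOGUS", "unknown"),
        ("WNN+FUSE", "at most one"),
        ("WNN+SK", "last"),
        ("GENE+IMAGE", "integrator"),
        ("GENE+GENE", "repeated"),
        ("SK+SME", "precede"),
        ("", "empty"),
    ])
    def test_invalid_strings_cite_grammar(self, raw, msg):
        with pytest.raises(ValueError, match=msg):
            StrategySpec.parse(raw)


class TestRunStrategy:
    def test_gene_equals_preprocessed_pca(self, small_sim):
        from stweave.preprocess import PreprocessConfig, preprocess_modality
        ds = small_sim.dataset
        out = run_strategy(ds, "GENE")
        direct = preprocess_modality(ds.expression, PreprocessConfig())
        np.testing.assert_allclose(out.matrix, direct.matrix, atol=1e-9)
        assert out.provenance == "GENE"

    def test_sk_wnn_composition(self, small_sim):
        from stweave.spatial_aware import spatial_kernel_refine
        from stweave.preprocess import PreprocessConfig, preprocess_modality
        ds = small_sim.dataset
        params = StrategyParams(k_nn=10)
        out = run_strategy(ds, "SK+WNN", params)
        cfg = PreprocessConfig()
        eg = spatial_kernel_refine(preprocess_modality(ds.expression, cfg), ds.coords)
        em = spatial_kernel_refine(preprocess_modality(ds.image_features, cfg), ds.coords)
        direct = wnn_integrate(eg, em, k_nn=10)
        np.testing.assert_allclose(out.affinities, direct.affinities, atol=1e-12)
        assert out.provenance == "SK+WNN"

    def test_sme_sk_provenance_bookkeeping(self, small_sim):
        out = run_strategy(small_sim.dataset, "SME+SK")
        assert out.provenance == "SME+SK"

    def test_image_strategy_without_features_fatal(self, small_sim):
        from stweave import SpatialDataset
        ds = small_sim.dataset
        bare = SpatialDataset(ds.spot_ids, ds.coords, ds.expression)
        with pytest.raises(ValueError, match="image features"):
            run_strategy(bare, "WNN")
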