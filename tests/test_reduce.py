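"""Per-bin PCA, diploid combination and block concatenation."""

import numpy as np
import pytest
from scipy import linalg

from epiprs.extract import FeatureStore, SyntheticExtractor, extract_cohort
from epiprs.reduce import (
    BinPCAModel,
    ReductionConfig,
    concat_blocks,
    fit_bin_pca,
    fit_block_models,
    reduce_cohort,
    reduce_sample,
)
from epiprs.windows import LDBlock, WindowConfig, tile_block


class TestFitBinPca:
    def test_identical_vectors_map_to_zero(self):
        vectors = np.tile([1.0, 2.0, 3.0], (5, 1))
        model = fit_bin_pca(vectors, d_prime=2)
        np.testing.assert_allclose(model.transform(vectors), 0.0)
        assert model.rank_deficient

    def test_axis_aligned_variance(self):
        vectors = np.zeros((4, 3))
        vectors[:, 0] = [0.0, 1.0, 2.0, 3.0]
        model = fit_bin_pca(vectors, d_prime=1)
        np.testing.assert_allclose(model.components[0], [1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(model.explained_variance_ratio, [1.0])

    def test_matches_dense_eigendecomposition(self, rng):
        vectors = rng.standard_normal((20, 10))
        model = fit_bin_pca(vectors, d_prime=4)
        cov = np.cov(vectors, rowvar=False)
        evals, evecs = linalg.eigh(cov)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        for j in range(4):
            v = evecs[:, j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.components[j], v, atol=1e-8)
        np.testing.assert_allclose(
            model.explained_variance_ratio, evals[:4] / evals.sum(), atol=1e-8
        )

    def test_orthonormal_components_and_variance_ordering(self, rng):
        for _ in range(5):
            vectors = rng.standard_normal((30, 12))
            model = fit_bin_pca(vectors, d_prime=5)
            gram = model.components @ model.components.T
            np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
            ratio = model.explained_variance_ratio
            assert np.all(np.diff(ratio) <= 1e-12)
            assert ratio.sum() <= 1 + 1e-8

    def test_too_few_vectors_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_bin_pca(np.ones((1, 4)), d_prime=1)

    def test_rank_deficit_pads_with_zeros(self, rng):
        vectors = np.outer(rng.standard_normal(6), [1.0, 2.0, 0.5])
        model = fit_bin_pca(vectors, d_prime=3)
        assert model.rank_deficient and model.d_eff == 1
        proj = model.transform(vectors[0])
        assert proj.shape == (3,) and proj[1] == proj[2] == 0.0


class _CountingStore(FeatureStore):
    """Records which samples' tensors are read (leakage instrumentation)."""

    def __init__(self, inner: FeatureStore):
        super().__init__(inner.spec, inner.window_cfg)
        self._data = inner._data
        self.reads: set[str] = set()

    def get(self, sample, hap, window_id):
        self.reads.add(sample)
        return super().get(sample, hap, window_id)


@pytest.fixture()
def block_setup(tiny_window, tiny_extractor, rng):
    block = LDBlock("b", "c1", 3072, 3072 + tiny_window.central_length)
    windows = tile_block(block, tiny_window, contig_length=12_000)
    bases = np.array(list("ACGT"))
    seqs = {
        s: (
            "".join(bases[rng.integers(0, 4, 12_000)]),
            "".join(bases[rng.integers(0, 4, 12_000)]),
        )
        for s in ["a", "b", "c", "d", "e", "f"]
    }
    get = lambda s, w: tuple(x[w.input_start : w.input_end] for x in seqs[s])
    store = extract_cohort(get, list(seqs), windows, tiny_extractor)
    return store, windows, list(seqs)


class TestReduceSample:
    def test_vector_length_is_bins_times_components(self, block_setup):
        store, windows, samples = block_setup
        cfg = ReductionConfig(d_prime=5)
        models = fit_block_models(store, windows, samples[:4], cfg)
        vec = reduce_sample(store, windows, samples[0], models, cfg)
        assert vec.shape == (16 * 5,)

    def test_sample_at_training_mean_maps_to_zero(self, tiny_window):
        ex = SyntheticExtractor(tiny_window, d=8, seed=1)
        store = FeatureStore(ex.spec, tiny_window)
        rng = np.random.default_rng(0)
        windows = tile_block(
            LDBlock("b", "c1", 3072, 3072 + tiny_window.central_length),
            tiny_window,
            contig_length=12_000,
        )
        w = windows[0]
        t_a = rng.standard_normal((16, 8))
        t_b = rng.standard_normal((16, 8))
        mean = (t_a + t_b) / 2
        store.put("a", 1, w.id, t_a)
        store.put("a", 2, w.id, t_b)
        store.put("m", 1, w.id, mean)
        store.put("m", 2, w.id, mean)
        cfg = ReductionConfig(d_prime=2)
        models = fit_block_models(store, windows, ["a"], cfg)
        np.testing.assert_allclose(
            reduce_sample(store, windows, "m", models, cfg), 0.0, atol=1e-10
        )

    def test_haplotype_swap_invariance_under_mean_rule(self, block_setup):
        store, windows, samples = block_setup
        cfg = ReductionConfig(d_prime=3, combine="mean")
        models = fit_block_models(store, windows, samples[:4], cfg)
        swapped = FeatureStore(store.spec, store.window_cfg)
        for (s, h, wid), v in store._data.items():
            swapped.put(s, 3 - h, wid, v)
        v1 = reduce_sample(store, windows, samples[5], models, cfg)
        v2 = reduce_sample(swapped, windows, samples[5], models, cfg)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_concat_rule_doubles_length_and_breaks_symmetry(self, block_setup):
        store, windows, samples = block_setup
        cfg = ReductionConfig(d_prime=2, combine="concat")
        models = fit_block_models(store, windows, samples[:4], cfg)
        vec = reduce_sample(store, windows, samples[0], models, cfg)
        assert vec.shape == (16 * 2 * 2,)

    def test_reduce_cohort_matches_per_sample_path(self, block_setup):
        store, windows, samples = block_setup
        cfg = ReductionConfig(d_prime=4)
        models = fit_block_models(store, windows, samples[:4], cfg)
        batched = reduce_cohort(store, windows, samples, models, cfg)
        for i, s in enumerate(samples):
            np.testing.assert_allclose(
                batched[i], reduce_sample(store, windows, s, models, cfg), atol=1e-12
            )

    def test_fit_never_reads_test_samples(self, block_setup):
        store, windows, samples = block_setup
        counting = _CountingStore(store)
        fit_block_models(counting, windows, samples[:3], ReductionConfig(d_prime=2))
        assert counting.reads == set(samples[:3])

    def test_missing_model_names_the_bin(self, block_setup):
        store, windows, samples = block_setup
        cfg = ReductionConfig(d_prime=2)
        models = fit_block_models(store, windows, samples[:4], cfg)
        del models[(windows[0].id, 7)]
        with pytest.raises(KeyError, match="bin 7"):
            reduce_sample(store, windows, samples[0], models, cfg)


class TestConcatBlocks:
    def test_single_block_is_identity(self, rng):
        x = rng.standard_normal((4, 10))
        np.testing.assert_array_equal(concat_blocks({"b1": x}), x)

    def test_block_order_is_canonical(self, rng):
        a, b = rng.standard_normal((3, 5)), rng.standard_normal((3, 7))
        out1 = concat_blocks({"a": a, "b": b})
        out2 = concat_blocks({"b": b, "a": a})
        np.testing.assert_array_equal(out1, out2)
        assert out1.shape == (3, 12)

    def test_five_blocks_of_full_geometry_width(self, rng):
        blocks = {f"b{i}": rng.standard_normal((2, 4480)) for i in range(5)}
        assert concat_blocks(blocks).shape == (2, 22_400)

    def test_sample_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            concat_blocks({"a": rng.standard_normal((3, 2)), "b": rng.standard_normal((4, 2))})
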