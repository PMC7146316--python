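"""Band handling, splitting, PCA, patches and input construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hsicnn.hsi_io import GroundTruth, HSICube, parse_band_removal
from hsicnn.preprocess import (
    PatchGeometry,
    build_augmented_vector,
    build_input_layers,
    extract_patch,
    extract_patches,
    make_batches,
    mask_bands,
    pca_fit,
    pca_transform,
    remove_bands,
    split_train_test,
)


class TestRemoveBands:
    def test_benchmark_counts(self, rng):
        cube224 = HSICube(rng.uniform(size=(3, 3, 224)))
        out = remove_bands(cube224, parse_band_removal("108-112,154-167,224"))
        assert out.n_bands == 204
        cube220 = HSICube(rng.uniform(size=(3, 3, 220)))
        out2 = remove_bands(cube220, parse_band_removal("104-108,150-163,220"))
        assert out2.n_bands == 200

    def test_survivors_keep_original_ids(self, rng):
        cube = HSICube(rng.uniform(size=(2, 2, 10)))
        out = remove_bands(cube, parse_band_removal("3-5"))
        assert out.band_ids.tolist() == [1, 2, 6, 7, 8, 9, 10]

    def test_empty_spec_is_identity(self, rng):
        cube = HSICube(rng.uniform(size=(2, 2, 6)))
        out = remove_bands(cube, parse_band_removal(""))
        np.testing.assert_array_equal(out.values, cube.values)

    def test_out_of_range_index_rejected(self, rng):
        cube = HSICube(rng.uniform(size=(2, 2, 6)))
        with pytest.raises(ValueError):
            remove_bands(cube, parse_band_removal("7"))

    def test_removal_composes_on_band_ids(self, rng):
        cube = HSICube(rng.uniform(size=(2, 2, 10)))
        once = remove_bands(cube, parse_band_removal("2-4"))
        twice = remove_bands(once, parse_band_removal("9"))
        assert twice.band_ids.tolist() == [1, 5, 6, 7, 8, 10]
        with pytest.raises(ValueError):
            remove_bands(once, parse_band_removal("3"))  # already gone


class TestMaskBands:
    def test_keep_two_of_ten(self):
        out = mask_bands(np.ones(10), {1, 3})
        assert out.sum() == 2 and out[0] == 1 and out[2] == 1

    def test_full_keep_is_identity(self, rng):
        x = rng.normal(size=12)
        np.testing.assert_array_equal(mask_bands(x, range(1, 13)), x)

    def test_empty_keep_zeroes_everything(self):
        assert not mask_bands(np.ones(5), []).any()

    def test_zero_count_at_benchmark_scale(self, rng):
        out = mask_bands(rng.normal(size=204) + 10, range(1, 71))
        assert int((out == 0).sum()) == 134

    def test_batch_masking(self, rng):
        X = rng.normal(size=(7, 10)) + 5
        out = mask_bands(X, {2, 9})
        assert out.shape == X.shape
        assert (out != 0).sum() == 14

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mask_bands(np.ones(5), {6})


class TestSplit:
    def _gt(self, counts, rows=20, cols=20, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.zeros(rows * cols, dtype=int)
        pos = rng.permutation(rows * cols)
        start = 0
        for cls, n in enumerate(counts, start=1):
            labels[pos[start:start + n]] = cls
            start += n
        return GroundTruth(labels.reshape(rows, cols))

    def test_fifty_percent_protocol(self):
        gt = self._gt([60, 40])
        split = split_train_test(gt, 0.5, seed=7)
        assert split.n_train == 50 and split.n_test == 50

    def test_same_seed_reproduces(self):
        gt = self._gt([30, 30])
        a = split_train_test(gt, 0.4, seed=5)
        b = split_train_test(gt, 0.4, seed=5)
        np.testing.assert_array_equal(a.train_pixels, b.train_pixels)
        c = split_train_test(gt, 0.4, seed=6)
        assert not np.array_equal(a.train_pixels, c.train_pixels)

    def test_stratified_per_class_rounding(self):
        gt = self._gt([10, 30])
        split = split_train_test(gt, 0.5, seed=1, stratified=True)
        train_counts = np.bincount(split.train_pixels[:, 2], minlength=3)[1:]
        assert train_counts.tolist() == [5, 15]

    def test_exact_partition_without_label_zero(self):
        gt = self._gt([25, 17, 9])
        split = split_train_test(gt, 0.3, seed=2)
        both = np.vstack([split.train_pixels, split.test_pixels])
        assert (both[:, 2] > 0).all()
        keys = {tuple(p) for p in both.tolist()}
        expected = {tuple(p) for p in gt.labeled_pixels().tolist()}
        assert keys == expected and len(keys) == len(both)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_domain(self, frac):
        with pytest.raises(ValueError):
            split_train_test(self._gt([10]), frac, seed=0)


class TestPCA:
    def test_known_diagonal_covariance(self):
        # orthogonal +/-1 columns scaled so the sample covariance (n-1
        # denominator) is exactly diag(4, 1, 0.25)
        c1 = np.array([1, 1, -1, -1.0])
        c2 = np.array([1, -1, 1, -1.0])
        c3 = np.array([1, -1, -1, 1.0])
        X = np.column_stack([
            np.sqrt(4 * 3 / 4) * c1,
            np.sqrt(1 * 3 / 4) * c2,
            np.sqrt(0.25 * 3 / 4) * c3,
        ])
        cube = HSICube(X.reshape(2, 2, 3))
        basis = pca_fit(cube, Q=2)
        np.testing.assert_allclose(basis.explained_variance, [4.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(np.abs(basis.components), np.eye(3)[:2], atol=1e-10)
        # sign rule: the dominant loading is positive
        assert basis.components[0, 0] > 0 and basis.components[1, 1] > 0

    def test_components_orthonormal(self, rng):
        cube = HSICube(rng.normal(size=(6, 7, 12)))
        basis = pca_fit(cube, Q=5)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)

    def test_rank_one_cube(self, rng):
        curve = rng.uniform(0.5, 1.5, size=10)
        scale = rng.uniform(1, 3, size=(4, 5))
        cube = HSICube(scale[..., None] * curve)
        basis = pca_fit(cube, Q=1)
        total_var = cube.spectra().var(axis=0, ddof=1).sum()
        assert basis.explained_variance[0] == pytest.approx(total_var, rel=1e-10)
        scores = pca_transform(cube, basis)
        recon = basis.inverse(scores.reshape(-1, 1))
        np.testing.assert_allclose(recon, cube.spectra(), rtol=1e-6, atol=1e-6)

    def test_mean_spectrum_projects_to_zero(self, rng):
        cube = HSICube(rng.normal(size=(5, 5, 8)))
        basis = pca_fit(cube, Q=3)
        np.testing.assert_allclose(basis.transform(basis.mean_spectrum[None]), 0, atol=1e-10)

    def test_two_pixel_hand_projection(self):
        cube = HSICube(np.array([[0.0, 0.0], [2.0, 4.0]]).reshape(2, 1, 2))
        basis = pca_fit(cube, Q=1)
        np.testing.assert_allclose(basis.mean_spectrum, [1.0, 2.0])
        np.testing.assert_allclose(basis.components[0], [1, 2] / np.sqrt(5), atol=1e-12)
        scores = pca_transform(cube, basis)[:, 0, 0]
        np.testing.assert_allclose(scores, [-np.sqrt(5), np.sqrt(5)], atol=1e-12)

    def test_reconstruction_error_non_increasing_in_q(self, rng):
        cube = HSICube(rng.normal(size=(8, 8, 10)) @ np.diag(rng.uniform(0.5, 3, 10)))
        errors = []
        for q in range(1, 7):
            basis = pca_fit(cube, Q=q)
            recon = basis.inverse(basis.transform(cube.spectra()))
            errors.append(np.linalg.norm(recon - cube.spectra()))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_q_exceeding_bands_rejected(self, rng):
        cube = HSICube(rng.normal(size=(3, 3, 4)))
        with pytest.raises(ValueError):
            pca_fit(cube, Q=5)

    def test_train_only_scope(self, rng):
        cube = HSICube(rng.normal(size=(6, 6, 5)))
        pix = np.array([[0, 0, 1], [1, 2, 1], [3, 4, 2], [5, 5, 2]])
        basis = pca_fit(cube, Q=2, pixel_scope="train-only", train_pixels=pix)
        expected_mean = cube.values[pix[:, 0], pix[:, 1], :].mean(axis=0)
        np.testing.assert_allclose(basis.mean_spectrum, expected_mean)


class TestPatches:
    def test_interior_pixel_is_verbatim(self, rng):
        grid = rng.normal(size=(7, 7, 2))
        patch = extract_patch(grid, (3, 3), 3)
        np.testing.assert_array_equal(patch, grid[2:5, 2:5, :])

    def test_corner_is_mirrored(self):
        grid = np.arange(9.0).reshape(3, 3, 1)
        patch = extract_patch(grid, (0, 0), 3)[:, :, 0]
        # reflect padding: row/col 1 mirrors outside the corner
        expected = np.array([[4, 3, 4], [1, 0, 1], [4, 3, 4.0]])
        np.testing.assert_array_equal(patch, expected)

    def test_even_r_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_patch(rng.normal(size=(5, 5, 1)), (2, 2), 4)

    def test_shape_contract_at_benchmark_window(self, rng):
        grid = rng.normal(size=(40, 40, 1))
        patch = extract_patch(grid, (0, 39), 21)
        assert patch.shape == (21, 21, 1) and patch.size == 441

    def test_batched_matches_single(self, rng):
        grid = rng.normal(size=(10, 11, 3))
        pixels = np.array([[0, 0], [5, 5], [9, 10], [0, 10]])
        batch = extract_patches(grid, pixels, 5)
        for i, (r, c) in enumerate(pixels):
            np.testing.assert_array_equal(batch[i], extract_patch(grid, (r, c), 5))


class TestAugmentedVector:
    def test_small_arithmetic(self, rng):
        vec = build_augmented_vector(rng.normal(size=4), rng.normal(size=(1, 1, 1)))
        assert vec.shape == (5,)

    def test_ordering_spectrum_then_patch_component_fastest(self):
        spectrum = np.array([10.0, 20.0])
        patch = np.arange(8.0).reshape(2, 2, 2)  # invalid R (even) should fail
        with pytest.raises(ValueError):
            build_augmented_vector(spectrum, patch)
        patch = np.arange(9.0 * 2).reshape(3, 3, 2)
        vec = build_augmented_vector(spectrum, patch)
        np.testing.assert_array_equal(vec[:2], spectrum)
        # row-major, component index fastest
        np.testing.assert_array_equal(vec[2:6], [0, 1, 2, 3])

    @given(
        n=st.integers(1, 300),
        r=st.sampled_from([1, 3, 5, 7, 21]),
        q=st.integers(1, 5),
    )
    def test_length_is_n_plus_r2q(self, n, r, q):
        geometry = PatchGeometry(R=r, Q=q, N=n)
        vec = build_augmented_vector(np.zeros(n), np.zeros((r, r, q)))
        assert vec.shape == (geometry.augmented_length,) == (n + r * r * q,)

    def test_input_layers_shape_and_channels(self, rng):
        grid = rng.normal(size=(30, 30, 4))
        layers = build_input_layers(grid, (15, 15), 21)
        assert layers.shape == (21, 21, 4)
        const = build_input_layers(np.full((9, 9, 1), 2.5), (4, 4), 3)
        assert (const == 2.5).all()


class TestBatches:
    def test_trailing_singleton_merges(self):
        batches = make_batches(33, 16, seed=0)
        assert [len(b) for b in batches] == [16, 17]

    def test_exact_fit_single_batch(self):
        assert [len(b) for b in make_batches(16, 16, seed=0)] == [16]

    def test_partition_and_determinism(self):
        a = make_batches(50, 8, seed=9)
        b = make_batches(50, 8, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert sorted(np.concatenate(a).tolist()) == list(range(50))

    def test_batch_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            make_batches(10, 1, seed=0)
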