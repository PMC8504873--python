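"""Feature bank against hand formulas and brute-force texture oracles."""

import numpy as np
import pytest

from elastomics.conversion import ColorImage
from elastomics.errors import DomainError, FeatureExtractionError
from elastomics.features import (FeatureBankConfig, FeatureTable, discretize,
                                 extract_direct, extract_rgb3, first_order,
                                 glcm_features, glcm_features_from_matrix,
                                 glcm_matrix, glrlm_features, glrlm_matrix,
                                 shape_features, GLCM_DIRECTIONS,
                                 GLRLM_DIRECTIONS)
from elastomics.roi import ROIMask

# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the vectorized implementations)


def brute_glcm(labels, mask, offset, bins):
    """Enumerate every in-mask pixel pair explicitly."""
    h, w = labels.shape
    mat = np.zeros((bins, bins))
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = labels[r, c] - 1, labels[r2, c2] - 1
                mat[i, j] += 1
                mat[j, i] += 1
    if mat.sum():
        mat /= mat.sum()
    return mat


def brute_runs(labels, mask, direction):
    """Walk every line pixel by pixel, collecting maximal runs."""
    h, w = labels.shape
    dr, dc = direction
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        r, c = r0, c0
        current, length = None, 0
        while 0 <= r < h and 0 <= c < w:
            if mask[r, c] and labels[r, c] == current:
                length += 1
            else:
                if current is not None and length:
                    runs.append((current, length))
                current = labels[r, c] if mask[r, c] else None
                length = 1 if mask[r, c] else 0
            r, c = r + dr, c + dc
        if current is not None and length:
            runs.append((current, length))
    return sorted(runs)


# ---------------------------------------------------------------------------
# Discretization


class TestDiscretize:
    def test_constant_roi_maps_to_bin_one(self):
        assert set(discretize(np.full(10, 7.0), 8)) == {1}

    def test_two_extremes_two_bins(self):
        assert sorted(set(discretize(np.array([0.0, 255.0]), 2))) == [1, 2]

    def test_uniform_ramp_bins_are_balanced(self):
        labels = discretize(np.arange(256, dtype=float), 32)
        counts = np.bincount(labels)[1:]
        assert counts.max() - counts.min() <= 1
        assert counts.sum() == 256

    def test_empty_input_raises(self):
        with pytest.raises(DomainError):
            discretize(np.array([]), 8)


# ---------------------------------------------------------------------------
# First order


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order(np.full(20, 42.0))
        assert f["mean"] == 42.0 and f["variance"] == 0.0 and f["entropy"] == 0.0
        assert f["skewness"] == 0.0 and f["kurtosis"] == 0.0

    def test_two_point_symmetric_sample(self):
        f = first_order(np.array([0.0, 255.0] * 8))
        assert f["mean"] == 127.5
        assert f["entropy"] == pytest.approx(1.0)  # one bit

    def test_moments_match_hand_formulas_on_ten_values(self):
        v = np.array([3.0, 7.0, 7.0, 9.0, 12.0, 15.0, 18.0, 21.0, 29.0, 40.0])
        mean = v.sum() / 10
        m2 = ((v - mean) ** 2).sum() / 10
        m3 = ((v - mean) ** 3).sum() / 10
        m4 = ((v - mean) ** 4).sum() / 10
        f = first_order(v)
        assert f["mean"] == pytest.approx(mean)
        assert f["variance"] == pytest.approx(m2)
        assert f["skewness"] == pytest.approx(m3 / m2 ** 1.5)
        assert f["kurtosis"] == pytest.approx(m4 / m2 ** 2)
        assert f["energy"] == pytest.approx((v ** 2).sum())
        assert f["rms"] == pytest.approx(np.sqrt((v ** 2).sum() / 10))
        assert f["mad"] == pytest.approx(np.abs(v - mean).mean())

    def test_feature_count_is_19(self):
        assert len(first_order(np.arange(10.0))) == 19


# ---------------------------------------------------------------------------
# GLCM


class TestGLCM:
    def test_constant_roi_degenerate_matrix(self):
        labels = np.ones((4, 4), dtype=np.int64)
        mask = np.ones((4, 4), dtype=bool)
        f = glcm_features(labels, mask, bins=8)
        assert f["contrast"] == 0.0
        assert f["max_probability"] == 1.0
        assert f["entropy"] == 0.0

    def test_checkerboard_contrast_is_one(self):
        labels = np.array([[1, 2], [2, 1]], dtype=np.int64)
        mask = np.ones((2, 2), dtype=bool)
        mat = glcm_matrix(labels, mask, (0, 1), bins=2)
        assert mat[0, 0] == 0.0 and mat[1, 1] == 0.0  # zero diagonal
        f = glcm_features_from_matrix(mat)
        assert f["contrast"] == 1.0

    def test_matrix_is_normalized_probability(self, rng):
        labels = rng.integers(1, 9, size=(12, 12))
        mask = rng.random((12, 12)) > 0.3
        mat = glcm_matrix(labels, mask, (1, -1), bins=8)
        assert mat.min() >= 0 and mat.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("offset", GLCM_DIRECTIONS)
    def test_matches_brute_force_on_random_images(self, offset, rng):
        for _ in range(3):
            labels = rng.integers(1, 7, size=(16, 16))
            mask = rng.random((16, 16)) > 0.25
            got = glcm_matrix(labels, mask, offset, bins=6)
            want = brute_glcm(labels, mask, offset, 6)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_single_pixel_roi_raises(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        with pytest.raises(FeatureExtractionError):
            glcm_features(np.ones((4, 4), dtype=np.int64), mask, bins=8)


# ---------------------------------------------------------------------------
# GLRLM


class TestGLRLM:
    def test_constant_row_long_run_emphasis_is_n_squared(self):
        n = 7
        labels = np.ones((1, n), dtype=np.int64)
        mask = np.ones((1, n), dtype=bool)
        mat = glrlm_matrix(labels, mask, (0, 1), bins=4)
        assert mat.sum() == 1 and mat[0, n - 1] == 1
        from elastomics.features import glrlm_features_from_matrix
        f = glrlm_features_from_matrix(mat, n)
        assert f["long_run_emphasis"] == n ** 2
        assert f["run_percentage"] == pytest.approx(1 / n)

    def test_alternating_row_all_runs_length_one(self):
        labels = np.array([[1, 2] * 5], dtype=np.int64)
        mask = np.ones((1, 10), dtype=bool)
        from elastomics.features import glrlm_features_from_matrix
        f = glrlm_features_from_matrix(glrlm_matrix(labels, mask, (0, 1), 2), 10)
        assert f["run_percentage"] == 1.0
        assert f["short_run_emphasis"] == 1.0 and f["long_run_emphasis"] == 1.0

    @pytest.mark.parametrize("direction", GLRLM_DIRECTIONS)
    def test_runs_match_brute_force_walk(self, direction, rng):
        from elastomics.features import _runs_along
        for _ in range(3):
            labels = rng.integers(1, 5, size=(14, 16))
            mask = rng.random((14, 16)) > 0.3
            assert sorted(_runs_along(labels, mask, direction)) == \
                brute_runs(labels, mask, direction)

    @pytest.mark.parametrize("direction", GLRLM_DIRECTIONS)
    def test_runs_conserve_pixel_count(self, direction, rng):
        labels = rng.integers(1, 5, size=(12, 12))
        mask = rng.random((12, 12)) > 0.4
        mat = glrlm_matrix(labels, mask, direction, bins=4)
        lengths = np.arange(1, mat.shape[1] + 1)
        assert (mat.sum(axis=0) * lengths).sum() == mask.sum()


# ---------------------------------------------------------------------------
# Shape


class TestShape:
    def test_square_area_perimeter_circularity(self):
        m = np.zeros((14, 14), dtype=bool)
        m[2:12, 2:12] = True
        f = shape_features(ROIMask(m))
        assert f["area"] == 100 and f["perimeter"] == 40
        assert f["circularity"] == pytest.approx(4 * np.pi * 100 / 1600)
        assert f["axis_ratio"] == pytest.approx(1.0)

    def test_elongated_rectangle_axis_ratio(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:7, 2:18] = True  # 2 x 16
        f = shape_features(ROIMask(m))
        assert f["axis_ratio"] > 5


# ---------------------------------------------------------------------------
# Bank-level extraction


class TestExtraction:
    def test_bank_size_is_pure_function_of_config(self, random_image,
                                                  center_mask):
        bank = FeatureBankConfig.default()
        vec = extract_direct(random_image, center_mask, bank)
        assert len(vec) == bank.size(1)
        vec3 = extract_rgb3(random_image, center_mask, bank)
        assert len(vec3) == bank.size(3)

    def test_three_times_law_excluding_shape(self, random_image, center_mask):
        bank = FeatureBankConfig(families=("first_order", "glcm", "glrlm"))
        k = len(extract_direct(random_image, center_mask, bank))
        assert len(extract_rgb3(random_image, center_mask, bank)) == 3 * k

    def test_determinism(self, random_image, center_mask):
        bank = FeatureBankConfig.default()
        a = extract_direct(random_image, center_mask, bank)
        b = extract_direct(random_image, center_mask, bank)
        assert a == b

    def test_achromatic_image_channels_agree_and_match_direct(
            self, achromatic_image, center_mask):
        bank = FeatureBankConfig(families=("first_order", "glcm", "glrlm"))
        direct = extract_direct(achromatic_image, center_mask, bank)
        rgb = extract_rgb3(achromatic_image, center_mask, bank)
        for name, value in direct.items():
            stem = name.removeprefix("gray_")
            assert rgb[f"R_{stem}"] == value
            assert rgb[f"G_{stem}"] == value
            assert rgb[f"B_{stem}"] == value

    def test_metameric_pixels_identical_gray_mean_different_red_mean(self):
        # constant-color metamer lesions: (84,110,118) vs (50,130,20)
        a = ColorImage(np.tile(np.array([84, 110, 118], np.uint8), (16, 16, 1)))
        b = ColorImage(np.tile(np.array([50, 130, 20], np.uint8), (16, 16, 1)))
        mask = ROIMask(np.ones((16, 16), dtype=bool))
        bank = FeatureBankConfig.minimal()
        fa, fb = extract_direct(a, mask, bank), extract_direct(b, mask, bank)
        assert fa["gray_original_firstorder_mean"] == \
            fb["gray_original_firstorder_mean"]
        ra = extract_rgb3(a, mask, bank)["R_original_firstorder_mean"]
        rb = extract_rgb3(b, mask, bank)["R_original_firstorder_mean"]
        assert abs(ra - rb) == 34

    def test_filters_change_values_but_not_names_count(self, random_image,
                                                       center_mask):
        bank = FeatureBankConfig(families=("first_order",),
                                 filters=("original", "log-sigma-1.0",
                                          "wavelet-HH"))
        vec = extract_direct(random_image, center_mask, bank)
        assert len(vec) == 3 * 19
        assert vec["gray_original_firstorder_mean"] != \
            vec["gray_wavelet-HH_firstorder_mean"]


class TestPaperSizePreset:
    def test_declared_counts(self):
        bank = FeatureBankConfig.paper_size()
        assert bank.intensity_size() == 5936
        assert bank.size(3) == 3 * 5936 == 17808


class TestFeatureTable:
    def test_csv_round_trip(self, tmp_path):
        t = FeatureTable(["a", "b"], np.array([0, 1]), ["f1", "f2"],
                         np.array([[1.0, 2.0], [3.0, 4.0]]))
        p = tmp_path / "t.csv"
        t.to_csv(p)
        t2 = FeatureTable.from_csv(p)
        assert t2.ids == t.ids and np.array_equal(t2.X, t.X)
        assert t2.feature_names == t.feature_names

    def test_select_preserves_order_and_checks_names(self):
        t = FeatureTable(["a"], np.array([1]), ["f1", "f2", "f3"],
                         np.array([[1.0, 2.0, 3.0]]))
        s = t.select(["f3", "f1"])
        assert s.X.tolist() == [[3.0, 1.0]]
        from elastomics.errors import SchemaError
        with pytest.raises(SchemaError):
            t.select(["nope"])
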