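"""Tests of the 90 statistical texture features against brute-force twins."""

from __future__ import annotations

import numpy as np
import pytest

import oracles
from texent.features import feature_columns, feature_table
from texent.images import RoiImage
from texent.radiomics import (
    GROUP_SIZES,
    _DIRECTIONS,
    _dependence_matrix,
    _glcm_matrix,
    _rlm_matrix,
    _szm_matrix,
    extract_all,
    fos_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    quantize,
)


class TestQuantize:
    def test_constant_maps_to_level_one(self):
        assert np.all(quantize(np.full((4, 4), 9.0), 32) == 1)

    def test_linear_ramp_uses_each_level_once(self):
        ramp = np.arange(32.0).reshape(4, 8)
        levels = quantize(ramp, 32)
        assert sorted(levels.ravel()) == list(range(1, 33))

    def test_single_level(self, noise_image):
        assert np.all(quantize(noise_image, 1) == 1)

    def test_maximum_assigned_to_top_level(self, noise_image):
        levels = quantize(noise_image, 8)
        assert levels.ravel()[noise_image.argmax()] == 8
        assert levels.min() >= 1 and levels.max() <= 8


class TestGroupCounts:
    def test_every_group_emits_its_count(self, noise_image):
        levels = quantize(noise_image, 8)
        assert len(fos_features(noise_image)) == GROUP_SIZES["FOS"]
        assert len(glcm_features(levels, 8)) == GROUP_SIZES["GLCM"]
        assert len(gldm_features(levels, 8)) == GROUP_SIZES["GLDM"]
        assert len(glrlm_features(levels, 8)) == GROUP_SIZES["GLRLM"]
        assert len(glszm_features(levels, 8)) == GROUP_SIZES["GLSZM"]
        assert len(ngtdm_features(levels, 8)) == GROUP_SIZES["NGTDM"]
        assert len(extract_all(noise_image)) == 90

    def test_counts_hold_on_degenerate_input(self):
        const = np.full((6, 6), 3.0)
        assert len(extract_all(const)) == 90


class TestFirstOrder:
    def test_hand_example_3x3(self):
        f = fos_features(np.arange(1.0, 10.0).reshape(3, 3))
        assert f["Mean"] == 5.0
        assert f["Median"] == 5.0
        assert f["Range"] == 8.0
        assert f["Variance"] == pytest.approx(20.0 / 3.0)
        assert f["Minimum"] == 1.0 and f["Maximum"] == 9.0
        assert f["Energy"] == pytest.approx(sum(v**2 for v in range(1, 10)))

    def test_constant_image_nan_policy(self):
        f = fos_features(np.full((4, 4), 5.0))
        assert f["Variance"] == 0.0
        assert f["Range"] == 0.0
        assert f["Skewness"] == 0.0  # undefined -> 0
        assert f["Kurtosis"] == 0.0


class TestGlcm:
    def test_checkerboard_horizontal_direction(self):
        cb = (np.indices((4, 4)).sum(axis=0) % 2 + 1).astype(np.int64)
        p = _glcm_matrix(cb, 2, (0, 1), 1)
        assert p[0, 1] == pytest.approx(0.5)
        assert p[1, 0] == pytest.approx(0.5)
        # contrast 1 and angular second moment 0.5 for this direction
        assert ((np.array([[0, 1], [1, 0]]) ** 2) * p).sum() == pytest.approx(1.0)
        assert (p**2).sum() == pytest.approx(0.5)

    def test_constant_image_zero_contrast_every_direction(self):
        const = np.ones((5, 5), dtype=np.int64)
        assert glcm_features(const, 1)["Contrast"] == 0.0

    def test_matrices_normalized(self, rng):
        levels = quantize(rng.uniform(0, 255, (8, 8)), 4)
        for off in _DIRECTIONS:
            assert _glcm_matrix(levels, 4, off, 1).sum() == pytest.approx(1.0, abs=1e-12)

    def test_matrix_matches_brute_force(self, rng):
        for seed in range(10):
            levels = quantize(np.random.default_rng(seed).uniform(0, 9, (6, 6)), 4)
            for off in _DIRECTIONS:
                assert np.allclose(
                    _glcm_matrix(levels, 4, off, 1),
                    oracles.glcm_matrix_brute(levels, 4, off),
                    atol=1e-12,
                )


class TestGldm:
    def test_constant_5x5_dependence_histogram(self):
        # corners have 3 neighbors, edges 5, interior 8 -> sizes 4, 6, 9
        mat = _dependence_matrix(np.ones((5, 5), dtype=np.int64), 1, 0)
        assert mat[0, 3] == 4  # corners
        assert mat[0, 5] == 12  # edges
        assert mat[0, 8] == 9  # interior
        assert mat.sum() == 25

    def test_all_distinct_values_zero_dependence(self):
        levels = np.arange(1, 17).reshape(4, 4)
        mat = _dependence_matrix(levels, 16, 0)
        assert mat[:, 0].sum() == 16 and mat[:, 1:].sum() == 0

    def test_matrix_matches_brute_force(self):
        for seed in range(10):
            levels = quantize(np.random.default_rng(seed).uniform(0, 9, (6, 6)), 4)
            assert np.array_equal(
                _dependence_matrix(levels, 4, 0), oracles.gldm_matrix_brute(levels, 4, 0)
            )


class TestGlrlm:
    def test_single_row_runs(self):
        mat = _rlm_matrix(np.array([[1, 1, 2, 2, 2]]), 2, (0, 1))
        expected = np.zeros((2, 5))
        expected[0, 1] = 1  # level 1, length 2
        expected[1, 2] = 1  # level 2, length 3
        assert np.array_equal(mat, expected)

    def test_constant_horizontal_single_entry(self):
        mat = _rlm_matrix(np.ones((4, 4), dtype=np.int64), 1, (0, 1))
        assert mat[0, 3] == 4 and mat.sum() == 4

    def test_matches_brute_force_all_directions(self):
        keys = {(0, 1): "h", (-1, 0): "v", (-1, -1): "d", (-1, 1): "a"}
        for seed in range(10):
            levels = quantize(np.random.default_rng(seed).uniform(0, 9, (6, 6)), 4)
            for off, key in keys.items():
                ours = _rlm_matrix(levels, 4, off)
                brute = oracles.rlm_matrix_brute(levels, 4, key)
                # runs are direction-symmetric: compare total run multisets
                assert np.array_equal(ours, brute), (seed, key)


class TestGlszm:
    def test_constant_single_zone(self):
        mat = _szm_matrix(np.ones((4, 5), dtype=np.int64), 1)
        assert mat[0, 19] == 1 and mat.sum() == 1

    def test_two_blobs_hand_example(self):
        levels = np.ones((5, 5), dtype=np.int64)
        levels[0, 0:2] = 2  # one 2-pixel zone
        levels[4, 3:5] = 2  # another 2-pixel zone
        mat = _szm_matrix(levels, 2)
        assert mat[1, 1] == 2  # two zones of level 2, size 2
        assert mat[0, 20] == 1  # background zone of 21 pixels
        assert mat.sum() == 3

    def test_matches_flood_fill_oracle(self):
        for seed in range(10):
            levels = quantize(np.random.default_rng(seed).uniform(0, 9, (6, 6)), 3)
            mat = _szm_matrix(levels, 3)
            ours = sorted(
                (i + 1, j + 1)
                for i in range(mat.shape[0])
                for j in range(mat.shape[1])
                for _ in range(int(mat[i, j]))
            )
            assert ours == oracles.szm_sizes_brute(levels)


class TestNgtdm:
    def test_constant_contrast_zero_coarseness_capped(self):
        f = ngtdm_features(np.ones((5, 5), dtype=np.int64), 1)
        assert f["Contrast"] == 0.0
        assert f["Coarseness"] == 1e6

    def test_two_level_4x4_against_direct_summation(self):
        levels = np.array(
            [[1, 2, 1, 2], [2, 1, 2, 1], [1, 1, 2, 2], [2, 2, 1, 1]], dtype=np.int64
        )
        s, n = oracles.ngtdm_vectors_brute(levels, 2)
        n_pix = 16
        p = n / n_pix
        # direct evaluation of the five definitions
        coarseness = 1.0 / float((p * s).sum())
        contrast = (
            (p[0] * p[1] * 1.0 * 2) / (2 * 1) * (s.sum() / n_pix)
        )
        busy_den = abs(1 * p[0] - 2 * p[1]) * 2
        busyness = float((p * s).sum()) / busy_den
        f = ngtdm_features(levels, 2)
        assert f["Coarseness"] == pytest.approx(coarseness, rel=1e-12)
        assert f["Contrast"] == pytest.approx(contrast, rel=1e-12)
        assert f["Busyness"] == pytest.approx(busyness, rel=1e-12)

    def test_s_vector_matches_oracle(self):
        for seed in range(10):
            levels = quantize(np.random.default_rng(seed).uniform(0, 9, (5, 5)), 4)
            s_brute, n_brute = oracles.ngtdm_vectors_brute(levels, 4)
            f = ngtdm_features(levels, 4)
            # reconstruct coarseness from the oracle accumulators
            p = n_brute / levels.size
            expected = 1.0 / float((p * s_brute).sum()) if (p * s_brute).sum() else 1e6
            assert f["Coarseness"] == pytest.approx(min(expected, 1e6), rel=1e-10)


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_transpose_invariance_all_groups(self, seed):
        x = np.random.default_rng(seed).uniform(0, 255, (8, 8))
        a = extract_all(x, n_levels=4)
        b = extract_all(x.T, n_levels=4)
        for name in a:
            assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-12), name


class TestFeatureTableAssembly:
    def test_set_sizes(self, tiny_cohort):
        images, _ = tiny_cohort
        sub = images[:4]
        stat = feature_table(sub, "statistical")
        ent = feature_table(sub, "entropy")
        comb = feature_table(sub, "combined")
        assert len(feature_columns(stat)) == 90
        assert len(feature_columns(ent)) == 25
        assert len(feature_columns(comb)) == 115

    def test_combined_is_disjoint_union(self, tiny_cohort):
        images, _ = tiny_cohort
        comb = feature_table(images[:2], "combined")
        cols = feature_columns(comb)
        assert len(cols) == len(set(cols))

    def test_metadata_columns_first(self, tiny_cohort):
        images, _ = tiny_cohort
        table = feature_table(images[:2], "entropy")
        assert list(table.columns[:3]) == ["patient_id", "class_label", "image_type"]
        assert table["class_label"].notna().all()

    def test_no_non_finite_values(self, tiny_cohort):
        images, _ = tiny_cohort
        table = feature_table(images[:4], "combined")
        vals = table[feature_columns(table)].to_numpy(dtype=float)
        assert np.all(np.isfinite(vals))
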