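"""Tissue signature co-occurrence matrices and Haralick features."""

import numpy as np
import pytest

from mprad.core import EmptyRegionError
from mprad.tscm import (
    ANGLES_2D,
    CooccurrenceMatrix,
    HARALICK_FEATURE_NAMES,
    build_tscm,
    haralick_features,
    offset_vector,
    signature_pair_glcm,
)

from conftest import make_field

# my angle -> skimage angle giving the same (or negated, hence under
# symmetric accumulation identical) pixel-pair offset
_SKIMAGE_ANGLE = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}


def brute_force_tscm(level_maps, mask, G, off):
    """Independent nested-loop accumulation of Eq.-style pair counts."""
    counts = np.zeros((G, G))
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            i2, j2 = i + off[0], j + off[1]
            if not (0 <= i2 < h and 0 <= j2 < w):
                continue
            if not (mask[i, j] and mask[i2, j2]):
                continue
            for lm in level_maps:  # per-parameter pair counts
                counts[lm[i, j] - 1, lm[i2, j2] - 1] += 1
                counts[lm[i2, j2] - 1, lm[i, j] - 1] += 1  # symmetric
    return counts


class TestSignaturePairGlcm:
    def test_two_entry_signatures(self):
        com = signature_pair_glcm(np.array([1, 2]), np.array([2, 2]), G=3)
        expected = np.zeros((3, 3))
        expected[0, 1] = 1  # r=1: (1,2)
        expected[1, 1] = 1  # r=2: (2,2)
        assert np.array_equal(com.matrix, expected)

    def test_identical_constant_signatures(self):
        com = signature_pair_glcm(np.array([3, 3, 3]), np.array([3, 3, 3]), G=4)
        assert com.matrix[2, 2] == 3
        assert com.matrix.sum() == 3

    def test_matches_per_index_tally(self, rng):
        a = rng.integers(1, 5, size=10)
        b = rng.integers(1, 5, size=10)
        com = signature_pair_glcm(a, b, G=4)
        tally = np.zeros((4, 4))
        for r in range(10):
            tally[a[r] - 1, b[r] - 1] += 1
        assert np.array_equal(com.matrix, tally)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            signature_pair_glcm(np.array([1]), np.array([1, 2]), G=2)


class TestBuildTscm:
    def test_identical_signatures_single_cell(self):
        levels = np.full((2, 4, 4), 2)
        com = build_tscm(make_field(levels, G=3), d=1, theta=0)
        assert com.matrix[1, 1] == pytest.approx(1.0)
        assert com.matrix.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", ANGLES_2D)
    def test_matches_bruteforce_enumeration(self, rng, theta):
        levels = rng.integers(1, 4, size=(2, 6, 6))
        mask = rng.random((6, 6)) > 0.2
        mask[2:4, 2:4] = True
        field = make_field(levels, G=3, mask=mask)
        com = build_tscm(field, d=1, theta=theta)
        off = offset_vector(1, theta)
        brute = brute_force_tscm(levels, mask, 3, off)
        assert np.allclose(com.matrix, brute / brute.sum())

    @pytest.mark.parametrize("theta", ANGLES_2D)
    def test_single_channel_equals_skimage_glcm(self, rng, theta):
        # independent reference implementation for the N = 1 collapse
        from skimage.feature import graycomatrix

        img = rng.integers(1, 9, size=(8, 8))
        field = make_field(img[None], G=8)
        com = build_tscm(field, d=1, theta=theta)
        ref = graycomatrix(
            (img - 1).astype(np.uint8), distances=[1],
            angles=[_SKIMAGE_ANGLE[theta]], levels=8, symmetric=True,
        )[:, :, 0, 0].astype(float)
        assert np.allclose(com.matrix, ref / ref.sum())

    def test_symmetric_accumulation_gives_symmetric_matrix(self, rng):
        levels = rng.integers(1, 5, size=(3, 7, 7))
        com = build_tscm(make_field(levels, G=4), d=1, theta=45)
        assert np.allclose(com.matrix, com.matrix.T)

    def test_total_count_conservation(self, rng):
        # pre-normalization total = N x (valid pairs x 2)
        n, g = 3, 4
        levels = rng.integers(1, g + 1, size=(n, 6, 6))
        mask = np.ones((6, 6), dtype=bool)
        field = make_field(levels, G=g, mask=mask)
        brute = brute_force_tscm(levels, mask, g, (0, 1))
        n_pairs = 6 * 5  # horizontal neighbor pairs in a 6x6 grid
        assert brute.sum() == n * n_pairs * 2

    def test_no_valid_pairs_raises(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        mask[2, 2] = True
        field = make_field(np.ones((1, 4, 4), dtype=int), G=2, mask=mask)
        with pytest.raises(EmptyRegionError, match="no co-occurring pairs"):
            build_tscm(field, d=1, theta=0)


class TestHaralickFeatures:
    def test_returns_all_22_features(self, rng):
        levels = rng.integers(1, 5, size=(2, 6, 6))
        com = build_tscm(make_field(levels, G=4), d=1, theta=0)
        feats = haralick_features(com)
        assert set(feats) == set(HARALICK_FEATURE_NAMES)
        assert all(np.isfinite(v) for v in feats.values())

    def test_single_cell_degenerate(self):
        m = np.zeros((4, 4))
        m[2, 2] = 1.0
        feats = haralick_features(CooccurrenceMatrix(m, 4, normalized=True))
        assert feats["energy"] == 1.0
        assert feats["entropy"] == 0.0
        assert feats["contrast"] == 0.0
        assert feats["maximum_probability"] == 1.0
        assert feats["correlation"] == 0.0  # zero marginal variance rule

    def test_uniform_2x2_hand_computed(self):
        # four cells of 0.25: entropy 2 bits, energy 0.25,
        # contrast sum p (i-j)^2 = 2 * 0.25 = 0.5
        m = np.full((2, 2), 0.25)
        feats = haralick_features(CooccurrenceMatrix(m, 2, normalized=True))
        assert feats["entropy"] == pytest.approx(2.0)
        assert feats["energy"] == pytest.approx(0.25)
        assert feats["contrast"] == pytest.approx(0.5)
        assert feats["dissimilarity"] == pytest.approx(0.5)
        assert feats["correlation"] == pytest.approx(0.0)  # independent marginals

    def test_perfectly_correlated_diagonal(self):
        m = np.diag([0.5, 0.5])
        feats = haralick_features(CooccurrenceMatrix(m, 2, normalized=True))
        assert feats["correlation"] == pytest.approx(1.0)
        assert feats["maximal_correlation_coefficient"] == pytest.approx(1.0)
        assert feats["information_measure_correlation_2"] == pytest.approx(
            np.sqrt(1 - np.exp(-2 * np.log(2))), abs=1e-9
        )

    def test_level_reversal_invariance_of_symmetric_features(self, rng):
        levels = rng.integers(1, 6, size=(2, 7, 7))
        field = make_field(levels, G=5)
        f1 = haralick_features(build_tscm(field, d=1, theta=0))
        field_rev = make_field(6 - levels, G=5)
        f2 = haralick_features(build_tscm(field_rev, d=1, theta=0))
        for name in ("energy", "entropy", "maximum_probability", "contrast"):
            assert f1[name] == pytest.approx(f2[name])

    def test_unnormalized_input_raises(self):
        com = CooccurrenceMatrix(np.ones((2, 2)), 2, normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(com)

    def test_sum_difference_marginals_consistent(self, rng):
        # sum_average relates to the marginal means: sum_avg = mu_x + mu_y
        levels = rng.integers(1, 5, size=(2, 6, 6))
        com = build_tscm(make_field(levels, G=4), d=1, theta=0)
        feats = haralick_features(com)
        p = com.matrix
        lv = np.arange(1, 5)
        mu_x = (lv * p.sum(axis=1)).sum()
        mu_y = (lv * p.sum(axis=0)).sum()
        assert feats["sum_average"] == pytest.approx(mu_x + mu_y)
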