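import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cofrac.features import (CandidatePair, FeatureConfigError, candidate_pairs,
                             featurize, featurize_pairs, intensity_difference,
                             pair_scalars, sliding_window_correlation)
from tests.conftest import gaussian_profile


def brute_force_swc(x, y, q):
    """Window-by-window Pearson over the exact index set, zero-variance -> 0."""
    F = len(x)
    out = np.zeros(F)
    for i in range(F):
        lo = max(0, i - q // 2)
        hi = min(F, i + (q + 1) // 2)
        xs, ys = x[lo:hi], y[lo:hi]
        if xs.std() == 0 or ys.std() == 0:
            out[i] = 0.0
        else:
            out[i] = np.corrcoef(xs, ys)[0, 1]
    return out


class TestCandidatePairs:
    def test_identical_profiles_retained_with_unit_r2(self):
        g = gaussian_profile(30.0)
        mat = pd.DataFrame([g, g], index=["a", "b"])
        out = candidate_pairs(mat, threshold=0.3)
        assert len(out) == 1
        assert out["r_squared"][0] == pytest.approx(1.0)

    def test_disjoint_impulses_excluded(self):
        x = np.zeros(72); x[10] = 1.0
        y = np.zeros(72); y[50] = 1.0
        # two non-overlapping unit impulses over F=72: r = -1/71, r^2 ~ 2e-4
        r = np.corrcoef(x, y)[0, 1]
        assert r ** 2 < 0.3
        mat = pd.DataFrame([x, y], index=["a", "b"])
        assert len(candidate_pairs(mat, threshold=0.3)) == 0

    def test_zero_threshold_keeps_all_pairs(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.random((6, 72)))
        assert len(candidate_pairs(mat, threshold=0.0)) == 15  # C(6,2)

    def test_threshold_filtering_is_monotone(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.random((8, 30)))
        lo = candidate_pairs(mat, threshold=0.05)
        hi = candidate_pairs(mat, threshold=0.2)
        lo_set = set(zip(lo["protein_a"], lo["protein_b"]))
        hi_set = set(zip(hi["protein_a"], hi["protein_b"]))
        assert hi_set <= lo_set

    def test_self_pairs_forbidden(self):
        with pytest.raises(ValueError):
            CandidatePair("a", "a", "ctrl", 1.0)


class TestSlidingWindowCorrelation:
    def test_identical_profiles_give_ones_where_variance_exists(self):
        x = gaussian_profile(30.0, sigma=3.0)
        out = sliding_window_correlation(x, x)
        expected = brute_force_swc(x, x, 6)
        np.testing.assert_allclose(out, expected, atol=1e-10)
        varying = expected != 0
        assert varying.any()
        np.testing.assert_allclose(out[varying], 1.0, atol=1e-9)

    def test_anticorrelated_profiles_give_minus_one(self):
        x = gaussian_profile(30.0, sigma=3.0)
        y = 1.0 - x
        out = sliding_window_correlation(x, y)
        expected = brute_force_swc(x, y, 6)
        np.testing.assert_allclose(out[20:40], expected[20:40], atol=1e-10)
        assert out[29] == pytest.approx(-1.0, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_windowed_oracle_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(40), rng.random(40)
        np.testing.assert_allclose(
            sliding_window_correlation(x, y, q=6),
            brute_force_swc(x, y, 6), atol=1e-10)

    def test_window_larger_than_profile_rejected(self):
        with pytest.raises(FeatureConfigError):
            sliding_window_correlation(np.ones(4), np.ones(4), q=6)


class TestIntensityDifferenceAndScalars:
    def test_identical_profiles_zero_difference(self):
        x = gaussian_profile(25.0)
        np.testing.assert_array_equal(intensity_difference(x, x), np.zeros(72))

    def test_saturated_difference_is_ones(self):
        np.testing.assert_array_equal(
            intensity_difference(np.ones(10), np.zeros(10)), np.ones(10))

    def test_sum_equals_l1_distance(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(72), rng.random(72)
        assert intensity_difference(x, y).sum() == pytest.approx(
            np.abs(x - y).sum(), abs=1e-12)

    def test_identity_pair_scalars(self):
        x = gaussian_profile(30.0)
        np.testing.assert_allclose(pair_scalars(x, x), (0.0, 0.0, 0.0), atol=1e-7)

    def test_orthogonal_profiles_quarter_turn(self):
        x = np.zeros(72); x[10:14] = 1.0
        y = np.zeros(72); y[40:44] = 1.0
        _, _, angle = pair_scalars(x, y)
        assert angle == pytest.approx(np.pi / 2, abs=1e-12)

    def test_gaussian_apexes_give_peak_shift_and_norm(self):
        x = gaussian_profile(20.0)
        y = gaussian_profile(30.0)
        shift, eucl, _ = pair_scalars(x, y)
        assert shift == 10.0
        assert eucl == pytest.approx(np.linalg.norm(x - y), abs=1e-12)

    def test_peakless_profile_gives_zero_shift(self):
        flat = np.zeros(72)
        shift, _, angle = pair_scalars(gaussian_profile(20.0), flat)
        assert shift == 0.0
        assert angle == pytest.approx(np.pi / 2)


class TestFeaturize:
    def test_vector_length_is_147_for_72_fractions(self):
        v = featurize(gaussian_profile(20.0), gaussian_profile(35.0))
        assert v.shape == (147,)
        assert np.isfinite(v).all()

    def test_identical_profiles_layout(self):
        x = gaussian_profile(30.0)
        v = featurize(x, x)
        assert set(np.round(v[:72], 6)) <= {0.0, 1.0}
        np.testing.assert_array_equal(v[72:144], np.zeros(72))
        np.testing.assert_allclose(v[144:], np.zeros(3), atol=1e-7)

    def test_blocks_equal_standalone_operations(self):
        rng = np.random.default_rng(5)
        x, y = rng.random(72), rng.random(72)
        v = featurize(x, y)
        np.testing.assert_allclose(v[:72], sliding_window_correlation(x, y), atol=0)
        np.testing.assert_allclose(v[72:144], intensity_difference(x, y), atol=0)
        np.testing.assert_allclose(v[144:], pair_scalars(x, y), atol=0)

    def test_generalizes_to_other_fraction_counts(self):
        rng = np.random.default_rng(6)
        v = featurize(rng.random(48), rng.random(48))
        assert v.shape == (2 * 48 + 3,)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_symmetric_in_the_two_proteins(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(30), rng.random(30)
        np.testing.assert_allclose(featurize(x, y), featurize(y, x), atol=1e-12)

    def test_batch_featurization_matches_single_pairs(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.random((5, 72)), index=list("abcde"))
        pairs = candidate_pairs(mat, threshold=0.0)
        batch = featurize_pairs(mat, pairs)
        for k, (_, row) in enumerate(pairs.iterrows()):
            single = featurize(mat.loc[row["protein_a"]].to_numpy(),
                               mat.loc[row["protein_b"]].to_numpy())
            np.testing.assert_allclose(batch[k], single, atol=1e-9)

    def test_missing_profile_is_an_error(self):
        mat = pd.DataFrame(np.random.default_rng(8).random((2, 72)), index=["a", "b"])
        pairs = pd.DataFrame({"protein_a": ["a"], "protein_b": ["zz"]})
        with pytest.raises(KeyError, match="zz"):
            featurize_pairs(mat, pairs)
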