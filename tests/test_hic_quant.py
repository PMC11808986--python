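"""Balancing, decay, loop-strength extraction, insulation and quantile normalization."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from loopscape.core_io import ContactMatrix, GenomicInterval, Loop
from loopscape.hic_quant import (
    balance_matrix,
    decay_normalize_counts,
    expected_cis_decay,
    extract_loop_counts,
    insulation_score,
    quantile_normalize,
)

from conftest import random_contact_matrix


def _matrix_from_dense(dense, resolution=5000, chrom="chr1"):
    return ContactMatrix(
        chrom=chrom, resolution=resolution, n_bins=dense.shape[0],
        counts=sp.csr_matrix(np.triu(dense)),
    )


def _uniform_matrix(n=12, value=2.0, resolution=5000):
    return _matrix_from_dense(np.full((n, n), value), resolution)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_loop_strength(dense, loop, resolution, n_bins):
    ci = loop.anchor1.midpoint // resolution
    cj = loop.anchor2.midpoint // resolution
    total = 0.0
    for i in range(max(0, ci - 1), min(n_bins, ci + 2)):
        for j in range(max(0, cj - 1), min(n_bins, cj + 2)):
            v = dense[i, j]
            if np.isfinite(v):
                total += v
    return total


def brute_insulation(dense, w):
    n = dense.shape[0]
    means = np.full(n, np.nan)
    for i in range(w, n - w):
        vals = [
            dense[r, c]
            for r in range(i - w, i)
            for c in range(i + 1, i + w + 1)
            if np.isfinite(dense[r, c])
        ]
        if vals:
            means[i] = np.mean(vals)
    chrom_mean = np.nanmean(means)
    return np.log2(means / chrom_mean)


class TestBalance:
    def test_uniform_matrix_is_fixed_point(self):
        m = balance_matrix(_uniform_matrix())
        w = m.balance_weights
        assert np.allclose(w, w[0])
        marg = np.nansum(m.to_dense(balanced=True), axis=0)
        assert np.allclose(marg, marg[0], rtol=1e-4)

    def test_rank_one_bias_inverted(self):
        # counts c_ij = b_i b_j with b = (4, 1, ..., 1): marginal equalization
        # has the exact fixed point w = 1/b (up to scale), so the biased bin's
        # weight is 1/4 of the others and all weighted marginals agree
        n = 12
        b = np.ones(n)
        b[0] = 4.0
        m = balance_matrix(_matrix_from_dense(np.outer(b, b)))
        w = m.balance_weights
        assert w[0] / w[1] == pytest.approx(0.25, rel=1e-3)
        marg = np.nansum(m.to_dense(balanced=True), axis=0)
        assert np.allclose(marg, marg.mean(), rtol=1e-4)

    def test_zero_coverage_bin_masked(self):
        dense = np.full((5, 5), 3.0)
        dense[2, :] = 0
        dense[:, 2] = 0
        m = balance_matrix(_matrix_from_dense(dense))
        assert 2 in m.masked_bins
        assert np.isnan(m.balance_weights[2])

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="nothing to balance"):
            balance_matrix(_matrix_from_dense(np.zeros((4, 4))))


class TestDecay:
    def test_constant_field(self):
        m = balance_matrix(_uniform_matrix(n=20, value=3.0))
        prof = expected_cis_decay(m, lag_resolution=5000)
        # balancing preserves a constant field up to overall scale
        assert np.allclose(prof.expected, prof.expected[0])

    def test_matches_per_diagonal_average(self):
        n = 30
        dense = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                dense[i, j] = 1000.0 / (abs(i - j) + 1)
        m = _matrix_from_dense(dense)
        m.balance_weights = np.ones(n)  # identity balancing: oracle on raw values
        prof = expected_cis_decay(m, lag_resolution=5000)
        oracle = np.array(
            [np.mean([dense[i, i + d] for i in range(n - d)]) for d in range(n)]
        )
        np.testing.assert_allclose(prof.expected, oracle, rtol=1e-9)

    def test_lag_with_no_unmasked_pixels_is_nan(self):
        dense = np.ones((4, 4))
        m = _matrix_from_dense(dense)
        m.balance_weights = np.array([1.0, np.nan, np.nan, np.nan])
        m.masked_bins = frozenset({1, 2, 3})
        prof = expected_cis_decay(m, lag_resolution=5000)
        assert np.isfinite(prof.expected[0])
        assert np.isnan(prof.expected[1:]).all()

    def test_lag_resolution_must_divide(self):
        m = balance_matrix(_uniform_matrix())
        with pytest.raises(ValueError):
            expected_cis_decay(m, lag_resolution=7001)


class TestLoopCounts:
    def test_zero_field(self, small_loop):
        dense = np.zeros((60, 60))
        m = _matrix_from_dense(dense)
        m.balance_weights = np.ones(60)
        assert extract_loop_counts(m, [small_loop]) == pytest.approx([0.0])

    def test_point_mass(self, small_loop):
        dense = np.zeros((60, 60))
        ci = small_loop.anchor1.midpoint // 5000
        cj = small_loop.anchor2.midpoint // 5000
        dense[ci, cj] = 7.0
        m = _matrix_from_dense(dense)
        m.balance_weights = np.ones(60)
        assert extract_loop_counts(m, [small_loop]) == pytest.approx([7.0])

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(5):
            m = balance_matrix(random_contact_matrix(rng, n_bins=40, density=0.8))
            dense = m.to_dense(balanced=True)
            loops = []
            for k in range(5):
                i = int(rng.integers(0, 20))
                j = int(rng.integers(i + 3, 40))
                loops.append(
                    Loop(f"l{k}",
                         GenomicInterval("chr1", i * 5000, i * 5000 + 5000),
                         GenomicInterval("chr1", j * 5000, j * 5000 + 5000))
                )
            got = extract_loop_counts(m, loops)
            want = [brute_loop_strength(dense, lp, 5000, 40) for lp in loops]
            np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)

    def test_wrong_chromosome_errors(self, small_loop):
        m = balance_matrix(_uniform_matrix(n=60))
        m.chrom = "chr2"
        with pytest.raises(ValueError, match="chr2"):
            extract_loop_counts(m, [small_loop])

    def test_mean_option_is_sum_over_nine(self, rng):
        m = balance_matrix(random_contact_matrix(rng, n_bins=40, density=0.9))
        lp = Loop("l", GenomicInterval("chr1", 50_000, 55_000),
                  GenomicInterval("chr1", 150_000, 155_000))
        s = extract_loop_counts(m, [lp], aggregate="sum")[0]
        mu = extract_loop_counts(m, [lp], aggregate="mean")[0]
        assert mu == pytest.approx(s / 9)


class TestDecayNormalize:
    def _profile(self, values):
        from loopscape.hic_quant import DecayProfile
        return DecayProfile("chr1", 10_000, np.asarray(values, dtype=float))

    def test_identity_ratio(self, small_loop):
        prof = self._profile(np.linspace(10, 1, 30))
        out = decay_normalize_counts(np.array([5.0]), [small_loop], prof, prof)
        assert out == pytest.approx([5.0])

    def test_double_decay_halves_strength(self, small_loop):
        ref = self._profile(np.linspace(10, 1, 30))
        sample = self._profile(2 * np.linspace(10, 1, 30))
        out = decay_normalize_counts(np.array([6.0]), [small_loop], sample, ref)
        assert out == pytest.approx([3.0])

    def test_scale_equivariance(self, rng):
        # multiplying a library's raw counts by k cancels exactly: balanced
        # counts and the decay curve both scale by k, and the ratio undoes it
        from loopscape.core_io import ContactMatrix

        raw = random_contact_matrix(rng, n_bins=40, density=0.9)
        scaled = ContactMatrix(raw.chrom, raw.resolution, raw.n_bins,
                               raw.counts * 7.0)
        loops = [Loop("l", GenomicInterval("chr1", 25_000, 30_000),
                      GenomicInterval("chr1", 120_000, 125_000))]
        ref = balance_matrix(random_contact_matrix(rng, n_bins=40, density=0.9))
        ref_decay = expected_cis_decay(ref, 10_000)
        out = []
        for m in (raw, scaled):
            b = balance_matrix(m)
            decay = expected_cis_decay(b, 10_000)
            s = extract_loop_counts(b, loops)
            out.append(decay_normalize_counts(s, loops, decay, ref_decay))
        np.testing.assert_allclose(out[0], out[1], rtol=1e-6)

    def test_zero_expected_marks_missing(self, small_loop):
        ref = self._profile(np.ones(30))
        sample = self._profile(np.zeros(30))
        out = decay_normalize_counts(np.array([6.0]), [small_loop], sample, ref)
        assert np.isnan(out[0])


class TestInsulation:
    def test_uniform_field_scores_zero(self):
        m = balance_matrix(_uniform_matrix(n=30, value=4.0, resolution=25_000))
        scores = insulation_score(m)
        interior = scores[4:-4]
        assert np.allclose(interior, 0.0, atol=1e-9)
        assert np.isnan(scores[:4]).all() and np.isnan(scores[-4:]).all()

    def test_block_boundary_is_minimum_and_matches_oracle(self):
        n, k = 24, 12
        dense = np.full((n, n), 0.05)
        dense[:k, :k] = 5.0
        dense[k:, k:] = 5.0
        m = _matrix_from_dense(dense, resolution=25_000)
        m.balance_weights = np.ones(n)
        scores = insulation_score(m)
        oracle = brute_insulation(dense, 4)
        np.testing.assert_allclose(scores, oracle, rtol=1e-9)
        # bins k-1 and k both see only cross-block pixels: tied minimum
        assert np.nanargmin(scores) in (k - 1, k)
        assert scores[k] == pytest.approx(np.nanmin(scores))

    def test_short_chromosome_all_undefined(self):
        m = balance_matrix(_uniform_matrix(n=7, resolution=25_000))
        with pytest.warns(UserWarning, match="shorter than twice the window"):
            scores = insulation_score(m)
        assert np.isnan(scores).all()

    def test_matches_bruteforce_on_random_matrix(self, rng):
        m = balance_matrix(
            random_contact_matrix(rng, n_bins=40, resolution=25_000, density=0.9)
        )
        dense = m.to_dense(balanced=True)
        scores = insulation_score(m)
        oracle = brute_insulation(dense, 4)
        np.testing.assert_allclose(scores, oracle, rtol=1e-9)


class TestQuantileNormalize:
    def test_hand_computed_mean_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert list(out["a"]) == expected
        assert list(out["b"]) == expected

    def test_identical_samples_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_sorted_vectors_identical_and_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcde":
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref)
        again = quantile_normalize(out)
        np.testing.assert_allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_rank_preservation_with_missing(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        df.iloc[3, 0] = np.nan
        out = quantile_normalize(df)
        assert np.isnan(out.iloc[3, 0])
        orig_order = df["b"].rank()
        new_order = out["b"].rank()
        pd.testing.assert_series_equal(orig_order, new_order)

    def test_sample_with_too_few_values_excluded(self):
        df = pd.DataFrame({
            "a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0],
            "c": [np.nan, np.nan, 1.0],
        })
        with pytest.warns(UserWarning, match="excluded"):
            out = quantile_normalize(df)
        assert out["c"].isna().all()
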