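"""Rank-normal transform, PCA sample QC, cis scans and permutation calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopscape.core_io import GenomicInterval, GenotypeMatrix
from loopscape.cis_qtl import (
    QTLResult,
    cross_qtl_concordance,
    fit_beta_mle,
    nominal_cis_scan,
    pca_sample_qc,
    permutation_adjusted_pvalues,
    qtl_fdr,
    rank_normal_transform,
)


def _genotypes(rng, n_var=10, n_samples=60, maf=0.3, spacing=20_000):
    dos = rng.binomial(2, maf, size=(n_var, n_samples)).astype(float)
    variants = pd.DataFrame({
        "id": [f"v{k}" for k in range(n_var)], "chrom": "chr1",
        "pos": np.arange(n_var) * spacing + 10_000, "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(variants, [f"S{k}" for k in range(n_samples)], dos)


class TestRankNormal:
    def test_three_value_quantiles(self):
        out = rank_normal_transform([5.0, 1.0, 9.0])
        want = stats.norm.ppf([0.5, 1 / 6, 5 / 6])
        np.testing.assert_allclose(out, want, atol=1e-4)
        assert out[1] == pytest.approx(-0.9674, abs=1e-4)

    def test_tied_minima_share_average_rank(self):
        out = rank_normal_transform([1.0, 1.0, 2.0, 3.0])
        want_min = stats.norm.ppf((1.5 - 0.5) / 4)
        assert out[0] == out[1] == pytest.approx(want_min)

    def test_all_tied_maps_to_zero(self):
        with pytest.warns(UserWarning, match="tied"):
            out = rank_normal_transform([2.0, 2.0, 2.0])
        np.testing.assert_array_equal(out, 0.0)

    def test_monotone_and_near_identity_on_large_normal(self, rng):
        x = rng.normal(size=5000)
        out = rank_normal_transform(x)
        order = np.argsort(x)
        assert (np.diff(out[order]) >= 0).all()
        # near-identity in the bulk; the most extreme order statistics are
        # pulled toward the grid quantiles, so judge the 99th percentile
        assert np.quantile(np.abs(out - x), 0.99) < 0.15


class TestPCASampleQC:
    def test_gross_outlier_removed(self, rng):
        vals = pd.DataFrame(rng.normal(size=(50, 12)),
                            columns=[f"S{k}" for k in range(12)])
        vals["S11"] += 10 * vals.std(axis=1).mean()
        retained, pcs = pca_sample_qc(vals, n_pcs=2, sd_threshold=3.0)
        assert "S11" not in retained
        assert len(retained) == 11 and pcs.shape == (11, 2)

    def test_homogeneous_cohort_no_removals(self, rng):
        vals = pd.DataFrame(rng.normal(size=(50, 10)),
                            columns=[f"S{k}" for k in range(10)])
        retained, _ = pca_sample_qc(vals, n_pcs=3, sd_threshold=3.0)
        assert len(retained) == 10

    def test_pcs_match_eigendecomposition(self, rng):
        vals = pd.DataFrame(rng.normal(size=(20, 10)),
                            columns=[f"S{k}" for k in range(10)])
        _, pcs = pca_sample_qc(vals, n_pcs=3, sd_threshold=10.0)
        X = vals.to_numpy().T
        X = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(evals)[::-1]
        want = X @ evecs[:, order[:3]]
        for j in range(3):
            got = pcs.iloc[:, j].to_numpy()
            assert min(np.abs(got - want[:, j]).max(),
                       np.abs(got + want[:, j]).max()) < 1e-8

    def test_too_many_pcs_rejected(self, rng):
        vals = pd.DataFrame(rng.normal(size=(30, 6)),
                            columns=[f"S{k}" for k in range(6)])
        with pytest.raises(ValueError):
            pca_sample_qc(vals, n_pcs=6)


class TestNominalScan:
    def test_window_contract(self, rng):
        gm = _genotypes(rng, n_var=2, spacing=2_000_000)  # v0 at 10k, v1 at 2.01M
        phen = pd.DataFrame(
            rng.normal(size=(1, 60)), index=["g"], columns=gm.samples
        )
        iv = {"g": GenomicInterval("chr1", 800_000, 800_001)}
        out = nominal_cis_scan(gm, phen, iv)
        # v0 is 790 kb away (tested); v1 is 1.21 Mb away (not tested)
        assert set(out["variant_id"]) == {"v0"}

    def test_slope_recovery(self, rng):
        gm = _genotypes(rng, n_var=1, n_samples=200)
        g = gm.dosages[0]
        phen = pd.DataFrame(
            [0.5 * g + rng.normal(0, 0.1, 200)], index=["g"], columns=gm.samples
        )
        out = nominal_cis_scan(gm, phen, {"g": GenomicInterval("chr1", 10_000, 10_001)})
        assert 0.45 <= out.loc[0, "slope"] <= 0.55

    def test_monomorphic_variant_skipped(self, rng):
        gm = _genotypes(rng, n_var=2)
        gm.dosages[1] = 1.0
        phen = pd.DataFrame(rng.normal(size=(1, 60)), index=["g"], columns=gm.samples)
        out = nominal_cis_scan(gm, phen, {"g": GenomicInterval("chr1", 10_000, 30_001)})
        assert "v1" not in set(out["variant_id"])

    def test_missing_dosages_excluded_pairwise(self, rng):
        gm = _genotypes(rng, n_var=1)
        gm.dosages[0, :5] = np.nan
        phen = pd.DataFrame(rng.normal(size=(1, 60)), index=["g"], columns=gm.samples)
        out = nominal_cis_scan(gm, phen, {"g": GenomicInterval("chr1", 10_000, 10_001)})
        assert out.loc[0, "n"] == 55


class TestPermutationPass:
    def test_beta_mle_recovery(self, rng):
        draws = stats.beta.rvs(1.0, 50.0, size=1000, random_state=rng)
        a, b, ok = fit_beta_mle(draws)
        assert ok
        assert 0.85 <= a <= 1.15
        assert 42 <= b <= 58

    def test_perfect_signal_small_adjusted_p(self, rng):
        gm = _genotypes(rng, n_var=5)
        y = pd.Series(gm.dosages[2], index=gm.samples, name="p")
        res = permutation_adjusted_pvalues(
            gm, y, GenomicInterval("chr1", 50_000, 50_001), n_perm=500, seed=4
        )
        assert res.lead_variant == "v2"
        assert res.p_adjusted < 0.01

    def test_null_adjusted_p_roughly_uniform(self, rng):
        # scaled-down calibration check; the full version runs in acceptance
        gm = _genotypes(rng, n_var=10)
        iv = GenomicInterval("chr1", 100_000, 100_001)
        adj = []
        for k in range(60):
            y = pd.Series(rng.normal(size=60), index=gm.samples, name=f"p{k}")
            r = permutation_adjusted_pvalues(gm, y, iv, n_perm=300, seed=k)
            adj.append(r.p_adjusted)
        assert stats.kstest(adj, "uniform").pvalue > 0.005

    def test_no_cis_variant_returns_none(self, rng):
        gm = _genotypes(rng, n_var=1)
        y = pd.Series(rng.normal(size=60), index=gm.samples, name="p")
        res = permutation_adjusted_pvalues(
            gm, y, GenomicInterval("chr2", 10_000, 10_001)
        )
        assert res is None


class TestQTLFDRAndConcordance:
    def _result(self, pid, var, slope, p_adj):
        return QTLResult(pid, var, slope, p_adj, p_adj, p_adj, 1, 1.0, 1.0, True)

    def test_single_phenotype_q_equals_adjusted(self):
        df = qtl_fdr([self._result("g1", "v1", 1.0, 0.03)])
        assert df.loc[0, "q"] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        res = [self._result(f"g{k}", "v", 1.0, p)
               for k, p in enumerate([0.01, 0.02, 0.03, 0.04])]
        df = qtl_fdr(res)
        np.testing.assert_allclose(df["q"], 0.04)

    def test_all_ones_nothing_significant(self):
        res = [self._result(f"g{k}", "v", 1.0, 1.0) for k in range(5)]
        df = qtl_fdr(res)
        assert not df["significant"].any()

    def test_concordance_identity(self):
        ref = qtl_fdr([self._result("g1", "v1", 1.0, 1e-5),
                       self._result("g2", "v2", -1.0, 1e-5)])
        other = pd.DataFrame({
            "phenotype_id": ["g1", "g2"], "variant_id": ["v1", "v2"],
            "slope": [0.5, -0.5], "p": [1e-4, 1e-4],
        })
        out = cross_qtl_concordance(ref, other)
        assert out["overlap"] == 1.0 and out["sign_concordance"] == 1.0

    def test_concordance_counting(self):
        ref = qtl_fdr([self._result(f"g{k}", f"v{k}", 1.0, 1e-5) for k in range(5)])
        other = pd.DataFrame({
            "phenotype_id": [f"g{k}" for k in range(5)],
            "variant_id": [f"v{k}" for k in range(5)],
            "slope": [1.0] * 5,
            "p": [1e-3, 1e-3, 1e-3, 0.5, 0.5],
        })
        out = cross_qtl_concordance(ref, other, p_threshold=1e-2)
        assert out["overlap"] == pytest.approx(0.6)
        assert out["sign_concordance"] == pytest.approx(1.0)

    def test_concordance_sign_flip(self):
        ref = qtl_fdr([self._result("g1", "v1", 1.0, 1e-5)])
        other = pd.DataFrame({
            "phenotype_id": ["g1"], "variant_id": ["v1"],
            "slope": [-1.0], "p": [1e-4],
        })
        out = cross_qtl_concordance(ref, other)
        assert out["sign_concordance"] == 0.0

    def test_empty_reference_undefined(self):
        out = cross_qtl_concordance(
            qtl_fdr([]), pd.DataFrame(columns=["phenotype_id", "variant_id",
                                               "slope", "p"])
        )
        assert np.isnan(out["overlap"])


class TestCrossModalityConsistency:
    def test_shared_causal_variant_gives_concordant_slopes(self):
        # one variant driving both a peak and its target gene: the estimated
        # eQTL and caQTL slopes share sign for nearly all injected pairs
        from loopscape.synthetic_data import SimulationConfig, simulate_cohort

        n_pairs = 40
        effects = []
        for k in range(n_pairs):
            effects.append((k, f"gene_{k:04d}", 0.5))
            effects.append((k, f"peak_{k:04d}", 0.5))
        cfg = SimulationConfig(
            seed=55, n_samples=60, n_loop_features=5, n_genes=n_pairs,
            n_peaks=n_pairs, n_variants=n_pairs, qtl_effects=effects,
            group_effect_fraction=0.0, sex_effect_fraction=0.0,
        )
        cohort = simulate_cohort(cfg)
        expr = np.log2(cohort.expression + 1)
        acc = np.log2(cohort.accessibility + 1)
        agree = 0
        for k in range(n_pairs):
            g = cohort.genotypes.dosages[k]
            se = stats.linregress(g, expr.loc[f"gene_{k:04d}"]).slope
            sa = stats.linregress(g, acc.loc[f"peak_{k:04d}"]).slope
            agree += np.sign(se) == np.sign(sa)
        assert agree / n_pairs >= 0.95


class TestPowerMonotonicity:
    def test_power_increases_with_slope(self, rng):
        gm = _genotypes(rng, n_var=1, n_samples=60)
        g = gm.dosages[0]
        iv = GenomicInterval("chr1", 10_000, 10_001)
        hits = []
        for slope in [0.0, 0.25, 0.5, 1.0]:
            sig = 0
            for rep in range(20):
                y = pd.Series(slope * g + rng.normal(0, 1, 60),
                              index=gm.samples, name="p")
                r = permutation_adjusted_pvalues(gm, y, iv, n_perm=200,
                                                 seed=1000 + rep)
                sig += r.p_adjusted < 0.1
            hits.append(sig)
        assert hits[0] <= hits[1] <= hits[3]
        assert hits[3] >= 18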