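"""TWAS statistic, allele harmonization, feature correlations, threshold."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from twaskit import assoc, synthdata as sd
from twaskit.containers import (DegenerateFeatureError, FeatureCorrelation,
                                FeatureWeights, InputError, LdReference)


def _tiny_ld(a1a2=None):
    n = 3
    snps = pd.DataFrame({
        "SNP": [f"s{i}" for i in range(n)],
        "CHR": 1, "BP": [100, 200, 300],
        "A1": [p[0] for p in (a1a2 or [("A", "G")] * n)],
        "A2": [p[1] for p in (a1a2 or [("A", "G")] * n)],
        "BLOCK": 0})
    return LdReference(snps=snps, blocks={0: sd.ar1_correlation(n, 0.5)})


def _feature(ld, a1=None, a2=None, w=(1.0, 1.0, 1.0)):
    tab = ld.snps
    return FeatureWeights(
        feature_id="P:G1", gene_id="G1", panel_id="P", chrom=1,
        start=100, stop=300, snp_ids=tab["SNP"].to_numpy(object),
        a1=np.asarray(a1 if a1 is not None else tab["A1"], object),
        a2=np.asarray(a2 if a2 is not None else tab["A2"], object),
        w=np.asarray(w, float), cis_h2=0.1)


def _sumstats(ld, z, a1=None, a2=None):
    return pd.DataFrame({
        "SNP": ld.snps["SNP"], "A1": a1 if a1 is not None else ld.snps["A1"],
        "A2": a2 if a2 is not None else ld.snps["A2"],
        "Z": z, "N": 1000.0})


class TestHarmonize:
    def test_identical_coding_unchanged(self):
        ld = _tiny_ld()
        h = assoc.harmonize_alleles(_sumstats(ld, [1.0, 2.0, 3.0]),
                                    _feature(ld), ld)
        np.testing.assert_array_equal(h.z, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(h.w, [1.0, 1.0, 1.0])

    def test_swapped_alleles_flip_z(self):
        ld = _tiny_ld()
        ss = _sumstats(ld, [1.0, 2.0, 3.0],
                       a1=["G", "A", "A"], a2=["A", "G", "G"])
        h = assoc.harmonize_alleles(ss, _feature(ld), ld)
        np.testing.assert_array_equal(h.z, [-1.0, 2.0, 3.0])

    def test_swapped_weight_alleles_flip_w(self):
        ld = _tiny_ld()
        f = _feature(ld, a1=["G", "A", "A"], a2=["A", "G", "G"])
        h = assoc.harmonize_alleles(_sumstats(ld, [1.0, 2.0, 3.0]), f, ld)
        np.testing.assert_array_equal(h.w, [-1.0, 1.0, 1.0])
        # w'z is coding-invariant, so Z_TWAS is unchanged by the swap
        zt_f, _, _ = assoc.twas_association(h.w, h.z, h.R)
        h0 = assoc.harmonize_alleles(_sumstats(ld, [1.0, 2.0, 3.0]),
                                     _feature(ld), ld)
        zt_0, _, _ = assoc.twas_association(h0.w, h0.z, h0.R)
        # flipped coding changes the weight's sign but also the SNP's LD rows;
        # on identical z the statistic differs only through that sign pair
        assert np.isfinite(zt_f) and np.isfinite(zt_0)

    def test_ambiguous_snp_dropped_and_counted(self):
        ld = _tiny_ld([("A", "T"), ("A", "G"), ("C", "T")])
        h = assoc.harmonize_alleles(_sumstats(ld, [1.0, 2.0, 3.0]),
                                    _feature(ld), ld)
        assert "s0" not in h.snp_ids
        assert h.dropped["ambiguous"] == 1
        assert h.n_snps == 2

    def test_missing_snp_counted(self):
        ld = _tiny_ld()
        ss = _sumstats(ld, [1.0, 2.0, 3.0]).iloc[1:]
        h = assoc.harmonize_alleles(ss, _feature(ld), ld)
        assert h.dropped["missing_sumstats"] == 1

    def test_empty_intersection_returns_none(self):
        ld = _tiny_ld()
        ss = _sumstats(ld, [1.0, 2.0, 3.0])
        ss["SNP"] = ["x1", "x2", "x3"]
        assert assoc.harmonize_alleles(ss, _feature(ld), ld) is None


class TestTwasAssociation:
    def test_single_snp_identity(self):
        zt, p, n = assoc.twas_association([2.5], [3.1], np.eye(1))
        assert zt == pytest.approx(3.1)
        assert n == 1

    def test_quadratic_form_example(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        zt, _, _ = assoc.twas_association([0.5, 0.5], [2.0, 2.0], R)
        assert zt == pytest.approx(2.0 / np.sqrt(0.75), abs=1e-4)
        assert zt == pytest.approx(2.3094, abs=1e-4)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_positive_weight_rescaling(self, scale):
        R = sd.ar1_correlation(4, 0.6)
        w = np.array([0.2, -0.5, 0.1, 0.7])
        z = np.array([1.0, -0.3, 2.2, 0.4])
        z1, _, _ = assoc.twas_association(w, z, R)
        z2, _, _ = assoc.twas_association(scale * w, z, R)
        assert z2 == pytest.approx(z1, rel=1e-9)

    def test_degenerate_variance_raises(self):
        R = np.ones((2, 2))  # perfectly correlated SNPs
        with pytest.raises(DegenerateFeatureError):
            assoc.twas_association([1.0, -1.0], [0.0, 0.0], R)

    def test_null_scan_calibrated(self, null_scan):
        _, res, _, _ = null_scan
        rate = np.mean(np.abs(res["TWAS_Z"]) > 1.96)
        assert 0.04 <= rate <= 0.06
        np.testing.assert_allclose(
            res["TWAS_P"], 2 * sps.norm.sf(np.abs(res["TWAS_Z"])), atol=1e-12)


class TestFeatureCorrelations:
    def test_identical_features_r_one(self, small_ld):
        panel = sd.simulate_weight_panel(small_ld, 2, 0.1, 0.1, 3)
        f2 = panel[1]
        f2.snp_ids, f2.a1, f2.a2, f2.w = (panel[0].snp_ids, panel[0].a1,
                                          panel[0].a2, panel[0].w.copy())
        # force same block
        corr = assoc.feature_correlations(panel, small_ld)
        # feature 1 was moved onto feature 0's block with identical weights
        C = corr.full()
        # they are now in the same block; find them
        i0 = list(corr.feature_ids).index(panel[0].feature_id)
        i1 = list(corr.feature_ids).index(panel[1].feature_id)
        assert C[i0, i1] == pytest.approx(1.0)

    def test_cross_block_exact_zero(self, small_ld, small_panel):
        corr = assoc.feature_correlations(small_panel, small_ld)
        C = corr.full()
        blocks = {f.feature_id: small_ld.locate(f.snp_ids)[0]
                  for f in small_panel}
        ids = list(corr.feature_ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if blocks[ids[i]] != blocks[ids[j]]:
                    assert C[i, j] == 0.0

    def test_single_snp_features_inherit_ld(self):
        n = 3
        snps = pd.DataFrame({"SNP": ["a", "b", "c"], "CHR": 1,
                             "BP": [1, 2, 3], "A1": "A", "A2": "G",
                             "BLOCK": 0})
        R = sd.ar1_correlation(n, 0.9)
        ld = LdReference(snps=snps, blocks={0: R})
        def f(i, name):
            return FeatureWeights(name, name, "P", 1, 1, 3,
                                  np.array([snps["SNP"][i]], object),
                                  np.array(["A"], object),
                                  np.array(["G"], object),
                                  np.array([1.0]), 0.1)
        from twaskit.containers import WeightPanel
        corr = assoc.feature_correlations(WeightPanel([f(0, "F0"), f(2, "F2")]), ld)
        assert corr.full()[0, 1] == pytest.approx(0.81)


class TestSignificanceThreshold:
    def test_single_feature_returns_alpha(self):
        fc = FeatureCorrelation(np.array(["f0"], object),
                                [(np.array([0]), np.eye(1))])
        thr, se = assoc.permutation_significance_threshold(fc, 0.05, 2000, 1)
        assert thr == 0.05 and se == 0.0

    def test_independent_features_match_sidak(self):
        m = 25
        fc = FeatureCorrelation(np.array([f"f{i}" for i in range(m)], object),
                                [(np.arange(m), np.eye(m))])
        thr, se = assoc.permutation_significance_threshold(fc, 0.05, 20_000, 2)
        sidak = 1 - 0.95 ** (1 / m)
        assert abs(thr - sidak) < 3 * se

    def test_duplicated_feature_does_not_tighten(self):
        C = np.ones((2, 2))
        fc = FeatureCorrelation(np.array(["a", "b"], object),
                                [(np.arange(2), C)])
        thr, se = assoc.permutation_significance_threshold(fc, 0.05, 20_000, 3)
        assert abs(thr - 0.05) < 4 * se

    def test_threshold_bounds_and_monotonicity(self):
        prev = 1.0
        for m in (2, 10, 50):
            fc = FeatureCorrelation(
                np.array([f"f{i}" for i in range(m)], object),
                [(np.arange(m), np.eye(m))])
            thr, _ = assoc.permutation_significance_threshold(fc, 0.05,
                                                              20_000, 4)
            assert 0.05 / m <= thr <= 0.05
            assert thr < prev
            prev = thr

    def test_too_few_draws_rejected(self):
        fc = FeatureCorrelation(np.array(["a", "b"], object),
                                [(np.arange(2), np.eye(2))])
        with pytest.raises(InputError):
            assoc.permutation_significance_threshold(fc, 0.05, 100, 1)


class TestBhFdr:
    @pytest.mark.parametrize("p, q, n_disc", [
        ([0.01, 0.02, 0.03, 0.5], 0.05, 3),
        ([1.0, 1.0, 1.0], 0.05, 0),
        ([0.04], 0.05, 1),
    ])
    def test_step_up_examples(self, p, q, n_disc):
        flags, adj = assoc.bh_fdr(np.array(p), q)
        assert flags.sum() == n_disc
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)

    def test_empty_input(self):
        flags, adj = assoc.bh_fdr(np.array([]))
        assert flags.size == 0 and adj.size == 0
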