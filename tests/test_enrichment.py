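"""Mixed-model competitive enrichment: oracle, invariances, power."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twaskit import assoc, enrichment as en, synthdata as sd
from twaskit.containers import InputError


def _identity_rel(n):
    return en.FeatureRelatedness(
        np.array([f"f{i}" for i in range(n)], object),
        [(np.arange(n), np.eye(n))])


class TestAssociationZTransform:
    def test_median_p_maps_to_zero(self):
        assert en.association_z_transform([0.5])[0] == pytest.approx(0.0)

    def test_p_05_maps_to_1_6449(self):
        assert en.association_z_transform([0.05])[0] == pytest.approx(
            1.6449, abs=1e-4)

    def test_boundaries_clamped_finite(self):
        z = en.association_z_transform([0.0, 1.0])
        assert np.all(np.isfinite(z))
        assert z[0] > 8 and z[1] < -8

    def test_monotone_decreasing_in_p(self):
        p = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(en.association_z_transform(p)) < 0)


class TestFeatureRelatedness:
    def test_uncorrelated_features_give_identity(self, small_ld):
        panel = sd.simulate_weight_panel(small_ld, 5, 1 / 40, 0.1, 1)
        corr = assoc.feature_correlations(panel, small_ld)
        K = en.build_feature_relatedness(corr).full()
        # one single-SNP feature per block: off-diagonals all zero
        off = K[~np.eye(len(K), dtype=bool)]
        assert np.abs(off).max() < 0.6  # same-block residual LD only
        np.testing.assert_allclose(np.diag(K), 1.0)

    def test_duplicate_features_give_all_ones_block(self):
        from twaskit.containers import FeatureCorrelation
        C = np.ones((2, 2))
        corr = FeatureCorrelation(np.array(["a", "b"], object),
                                  [(np.arange(2), C)])
        K = en.build_feature_relatedness(corr).full()
        np.testing.assert_allclose(K, 1.0)

    def test_squared_correlations_and_psd(self, small_ld, small_panel):
        corr = assoc.feature_correlations(small_panel, small_ld)
        rel = en.build_feature_relatedness(corr)
        K = rel.full()
        np.testing.assert_allclose(K, corr.full() ** 2, atol=1e-8)
        assert np.linalg.eigvalsh(K).min() > -1e-8
        assert np.all(rel.eigenvalues >= 0)

    def test_subset_preserves_entries(self, small_ld, small_panel):
        corr = assoc.feature_correlations(small_panel, small_ld)
        rel = en.build_feature_relatedness(corr)
        mask = np.zeros(rel.n_features, bool)
        mask[::2] = True
        sub = rel.subset(mask)
        np.testing.assert_allclose(sub.full(), rel.full()[np.ix_(mask, mask)],
                                   atol=1e-12)


class TestCompetitiveSetTest:
    def test_identity_K_matches_ols_oracle(self, rng):
        n = 400
        y = rng.standard_normal(n) + 0.3
        s = (rng.random(n) < 0.25).astype(float)
        r = en.competitive_set_test(y, s, _identity_rel(n))
        X = np.column_stack([np.ones(n), s])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[1, 1])
        p = stats.t.sf(beta[1] / se, n - 2)
        assert r.beta == pytest.approx(beta[1], abs=1e-4)
        assert r.se == pytest.approx(se, abs=1e-4)
        assert r.p == pytest.approx(p, abs=1e-4)

    def test_degenerate_membership_rejected(self):
        with pytest.raises(InputError):
            en.competitive_set_test(np.ones(5), np.ones(5), _identity_rel(5))

    def test_location_shift_changes_only_intercept(self, rng):
        n = 200
        y = rng.standard_normal(n)
        s = (rng.random(n) < 0.3).astype(float)
        rel = _identity_rel(n)
        a = en.competitive_set_test(y, s, rel)
        b = en.competitive_set_test(y + 5.0, s, rel)
        assert b.beta == pytest.approx(a.beta, abs=1e-8)
        assert b.p == pytest.approx(a.p, abs=1e-8)

    def test_reordering_invariance(self, null_scan):
        _, res, _, rel = null_scan
        z = en.association_z_transform(res["TWAS_P"].to_numpy())
        genes = res["GENE_ID"].to_numpy(object)
        members = list(np.unique(genes)[:80])
        s = np.isin(genes, members).astype(float)
        r1 = en.competitive_set_test(z, s, rel)
        perm = np.random.default_rng(0).permutation(len(z))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        blocks = [(inv[idx], Kb) for idx, Kb, _, _ in rel._blocks]
        rel_p = en.FeatureRelatedness(rel.feature_ids[perm], blocks)
        r2 = en.competitive_set_test(z[perm], s[perm], rel_p)
        assert r2.beta == pytest.approx(r1.beta, abs=1e-6)
        assert r2.p == pytest.approx(r1.p, abs=1e-6)

    def test_power_on_enriched_sets(self):
        # enriched member genes carry inflated effects; the one-sided test
        # should detect them in most replicates
        hits = 0
        for seed in range(10):
            cfg = sd.SimConfig(n_blocks=40, snps_per_block=50,
                               n_features=400, weight_sparsity=0.1,
                               cis_h2=0.2, gene_effect_sd=0.005,
                               direct_effect_sd=0.0, n_sets=4, set_size=40,
                               enriched_effect=4e-3, n_enriched=1, seed=seed)
            st = sd.simulate_study(cfg)
            res = assoc.twas_scan(st.sumstats, st.panel, st.ld)
            corr = assoc.feature_correlations(st.panel, st.ld)
            rel = en.build_feature_relatedness(corr)
            res = res.set_index("FEATURE_ID").loc[list(rel.feature_ids)]
            z = en.association_z_transform(res["TWAS_P"].to_numpy())
            enriched_sid = st.truth.sets.loc[st.truth.sets["ENRICHED"],
                                             "SET_ID"].iloc[0]
            tab = en.gene_set_enrichment(z, list(res["GENE_ID"]),
                                         st.gene_sets, rel)
            p = tab.set_index("SET_ID").loc[enriched_sid, "P"]
            hits += p < 0.05
        assert hits >= 8


class TestPropertyGradient:
    def test_perfect_predictor_detected(self, rng):
        n = 300
        y = rng.standard_normal(n)
        scores = pd.DataFrame({"GENE": [f"g{i}" for i in range(n)],
                               "STAGE_1": y, "STAGE_2": rng.standard_normal(n)})
        tab = en.property_gradient_test(y, scores, _identity_rel(n))
        row = tab.set_index("SET_ID").loc["STAGE_1"]
        assert row["BETA"] > 0 and row["P"] < 1e-10
        assert bool(row["BONF_SIG"])

    def test_constant_column_skipped(self, rng):
        n = 50
        scores = pd.DataFrame({"GENE": [f"g{i}" for i in range(n)],
                               "STAGE_1": np.ones(n)})
        tab = en.property_gradient_test(rng.standard_normal(n), scores,
                                        _identity_rel(n))
        assert tab.empty

    def test_null_stages_rarely_bonferroni_significant(self, null_scan):
        _, res, _, rel = null_scan
        st_ = null_scan[0]
        z = en.association_z_transform(res["TWAS_P"].to_numpy())
        props = st_.properties.set_index("GENE").loc[res["GENE_ID"]].reset_index()
        tab = en.property_gradient_test(z, props, rel)
        assert tab["BONF_SIG"].sum() <= 1


class TestWeightSetEnrichment:
    @staticmethod
    def _two_panel_study(seed, inflate):
        ld = sd.simulate_ld_blocks(40, 50, 0.6, seed)
        genes = [f"G{i}" for i in range(200)]
        pa = sd.simulate_weight_panel(ld, 200, 0.1, 0.2, seed + 1,
                                      panel_id="PANEL_A", gene_ids=genes)
        pb = sd.simulate_weight_panel(ld, 200, 0.1, 0.2, seed + 2,
                                      panel_id="PANEL_B", gene_ids=genes)
        from twaskit.containers import WeightPanel
        panel = WeightPanel(pa.features + pb.features)
        rng = np.random.default_rng(seed + 3)
        alpha = np.concatenate([rng.normal(0, 0.012, 200) * inflate,
                                np.zeros(200)])
        ss = sd.simulate_gwas_sumstats(ld, panel, alpha, 0.0, 46_350,
                                       seed + 4)
        return ld, panel, ss

    def test_inflated_panel_gets_positive_beta(self):
        signs = []
        for seed in range(0, 50, 10):
            ld, panel, ss = self._two_panel_study(seed, inflate=1.0)
            res = assoc.twas_scan(ss, panel, ld)
            corr = assoc.feature_correlations(panel, ld)
            rel = en.build_feature_relatedness(corr)
            res = res.set_index("FEATURE_ID").loc[list(rel.feature_ids)]
            z = en.association_z_transform(res["TWAS_P"].to_numpy())
            tab = en.weight_set_enrichment(z, list(res["PANEL"]), rel)
            tab = tab.set_index("SET_ID")
            signs.append(tab.loc["PANEL_A", "BETA"] > 0
                         and tab.loc["PANEL_B", "BETA"] < 0)
        assert sum(signs) >= 4

    def test_restriction_to_single_panel_rejected(self, null_scan):
        _, res, _, rel = null_scan
        z = en.association_z_transform(res["TWAS_P"].to_numpy())
        with pytest.raises(InputError):
            en.weight_set_enrichment(z, list(res["PANEL"]), rel,
                                     restrict_to=["SYNTH"])
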