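import numpy as np
import pytest

from twaskit import assoc, enrichment, synthdata as sd


@pytest.fixture(scope="session")
def small_ld():
    """5 AR(1) blocks of 40 SNPs (rho = 0.7)."""
    return sd.simulate_ld_blocks(n_blocks=5, snps_per_block=40, ar_rho=0.7,
                                 seed=7)


@pytest.fixture(scope="session")
def small_panel(small_ld):
    """20 sparse features (4 weight SNPs each, cis-h2 = 0.1)."""
    return sd.simulate_weight_panel(small_ld, n_features=20,
                                    weight_sparsity=0.1, cis_h2=0.1, seed=8)


@pytest.fixture(scope="session")
def null_study():
    """2,000-feature study with no genetic effects at all (global null)."""
    cfg = sd.SimConfig(n_blocks=100, snps_per_block=100, n_features=2000,
                       weight_sparsity=0.05, cis_h2=0.1, gene_effect_sd=0.0,
                       direct_effect_sd=0.0, n_sets=10, set_size=100, seed=21)
    return sd.simulate_study(cfg)


@pytest.fixture(scope="session")
def null_scan(null_study):
    """TWAS results, correlations and relatedness on the null study, with
    the result rows aligned to the relatedness feature order."""
    st = null_study
    res = assoc.twas_scan(st.sumstats, st.panel, st.ld)
    corr = assoc.feature_correlations(st.panel, st.ld)
    rel = enrichment.build_feature_relatedness(corr)
    res = res.set_index("FEATURE_ID").loc[list(rel.feature_ids)].reset_index()
    return st, res, corr, rel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
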