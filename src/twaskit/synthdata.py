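"""Synthetic study generator with known ground truth.

Everything downstream consumes only summary-level data, so the generator works
directly at the Z-score level: no individual genotypes or phenotypes are ever
simulated.  LD is AR(1) within blocks (closed-form entries, exact oracles) and
exactly zero across blocks.  Gene-mediated GWAS effects enter through weight
vectors rescaled to unit predicted-expression variance, so a feature's effect
``alpha`` is directly the TWAS effect size and ``sqrt(N) * alpha`` its expected
TWAS Z.

Marginal GWAS Z scores follow the standard summary-statistic model

    z = sqrt(N) * R * beta + e,   e ~ MVN(0, R)  per block,

with ``beta`` the per-standardized-genotype causal effects: independent direct
effects plus ``sum_f alpha_f * w_f / sqrt(w_f' R w_f)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureWeights, InputError, LdReference, WeightPanel

# non-ambiguous allele pairs only; strand-ambiguous SNPs are exercised by
# hand-built fixtures, not by the generator
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C"),
                 ("A", "C"), ("C", "A"), ("T", "G"), ("G", "T")]

#: base-pair spacing of SNPs and gap between blocks (blocks far apart so that
#: regional clustering with Mb-scale windows never merges across blocks)
SNP_SPACING_BP = 1_000
BLOCK_STRIDE_BP = 5_000_000


@dataclass
class SimConfig:
    """All knobs of the synthetic study; the seed fully determines the output.

    Defaults emulate a desk-scale case-control GWAS with a single expression
    panel: ~5,000 SNPs in 50 LD blocks, 500 cis-heritable features with sparse
    weights, and a case-control GWAS of ~46,000 individuals.
    """

    n_blocks: int = 50
    snps_per_block: int = 100
    ar_rho: float = 0.7
    n_features: int = 500
    weight_sparsity: float = 0.05
    cis_h2: float = 0.1
    n_gwas: float = 46_350
    gene_effect_sd: float = 0.0
    direct_effect_sd: float = 0.0
    n_sets: int = 20
    set_size: int = 50
    enriched_effect: float = 0.0
    n_enriched: int = 0
    property_corr: float = 0.0
    n_stages: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_blocks", "snps_per_block", "n_features", "n_sets",
                     "set_size", "n_stages"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if not 0 <= self.ar_rho < 1:
            raise InputError("ar_rho must be in [0, 1)")
        if not 0 <= self.cis_h2 <= 1:
            raise InputError("cis_h2 must be in [0, 1]")
        if self.n_gwas <= 0:
            raise InputError("n_gwas must be positive")


@dataclass
class TruthTable:
    """Ground truth of one simulated study.

    ``features`` has one row per feature (FEATURE_ID, GENE_ID, ALPHA);
    ``sets`` one row per gene set (SET_ID, ENRICHED); the h2 fields are the
    generative variance decomposition of the phenotype.
    """

    features: pd.DataFrame
    sets: pd.DataFrame
    h2_mediated: float = 0.0
    h2_direct: float = 0.0


@dataclass
class SimulatedStudy:
    config: SimConfig
    ld: LdReference
    panel: WeightPanel
    sumstats: pd.DataFrame
    gene_sets: dict[str, list[str]]
    properties: pd.DataFrame
    truth: TruthTable


def ar1_correlation(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R[i,j] = rho**|i-j| (positive definite)."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_ld_blocks(n_blocks: int, snps_per_block: int,
                       ar_rho: float | np.ndarray, seed: int) -> LdReference:
    """Build a block-diagonal LD reference with AR(1) within-block LD.

    ``ar_rho`` may be a scalar (same decay everywhere) or one value per block
    (heterogeneous LD, as in a real genome, which spreads out the LD-score
    distribution).  SNPs sit on chromosome 1 at 1-kb spacing; blocks are
    separated by a 5-Mb stride so windows of up to ~2 Mb never straddle
    blocks.
    """
    if n_blocks <= 0 or snps_per_block <= 0:
        raise InputError("n_blocks and snps_per_block must be positive")
    rhos = np.broadcast_to(np.asarray(ar_rho, float), (n_blocks,))
    if np.any((rhos < 0) | (rhos >= 1)):
        raise InputError("ar_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mats = {b: ar1_correlation(snps_per_block, rhos[b])
            for b in range(n_blocks)}
    rows = []
    for b in range(n_blocks):
        start = 1 + b * BLOCK_STRIDE_BP
        pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=snps_per_block)
        for i in range(snps_per_block):
            a1, a2 = _ALLELE_PAIRS[pair_idx[i]]
            rows.append({
                "SNP": f"rs{b}_{i}",
                "CHR": 1,
                "BP": start + i * SNP_SPACING_BP,
                "A1": a1,
                "A2": a2,
                "BLOCK": b,
            })
    snps = pd.DataFrame(rows)
    return LdReference(snps=snps, blocks=mats)


def simulate_weight_panel(ld: LdReference, n_features: int,
                          weight_sparsity: float, cis_h2: float, seed: int,
                          panel_id: str = "SYNTH",
                          gene_ids: list[str] | None = None) -> WeightPanel:
    """Draw sparse cis weight vectors, one feature per gene.

    Each feature lives in one LD block (round-robin over blocks); a random
    subset of ``round(weight_sparsity * block size)`` SNPs (at least one)
    receives Gaussian weights, rescaled so w'Rw equals ``cis_h2`` exactly.
    Gene bounds are the span of the weight SNPs.
    """
    if n_features <= 0:
        raise InputError("n_features must be positive")
    rng = np.random.default_rng(seed)
    block_ids = ld.block_ids()
    features = []
    if gene_ids is None:
        gene_ids = [f"GENE{i:05d}" for i in range(n_features)]
    elif len(gene_ids) != n_features:
        raise InputError("gene_ids length must equal n_features")
    for i in range(n_features):
        bid = block_ids[i % len(block_ids)]
        btab = ld.block_snps(bid)
        m = len(btab)
        nnz = int(round(weight_sparsity * m))
        if nnz < 1:
            raise InputError(
                f"weight_sparsity {weight_sparsity} selects zero SNPs in a "
                f"{m}-SNP block")
        sel = np.sort(rng.choice(m, size=nnz, replace=False))
        w = rng.standard_normal(nnz)
        R_sub = ld.blocks[bid][np.ix_(sel, sel)]
        var = float(w @ R_sub @ w)
        w *= np.sqrt(cis_h2 / var)
        sub = btab.iloc[sel]
        features.append(FeatureWeights(
            feature_id=f"{panel_id}:{gene_ids[i]}",
            gene_id=gene_ids[i],
            panel_id=panel_id,
            chrom=int(sub["CHR"].iloc[0]),
            start=int(sub["BP"].min()),
            stop=int(sub["BP"].max()),
            snp_ids=sub["SNP"].to_numpy(dtype=object),
            a1=sub["A1"].to_numpy(dtype=object),
            a2=sub["A2"].to_numpy(dtype=object),
            w=w,
            cis_h2=cis_h2,
        ))
    return WeightPanel(features)


def simulate_z(R: np.ndarray, beta: np.ndarray, n: float,
               rng: np.random.Generator,
               chol: np.ndarray | None = None) -> np.ndarray:
    """One draw of marginal Z scores for a block: sqrt(n)*R*beta + MVN(0, R)."""
    if chol is None:
        chol = np.linalg.cholesky(R)
    e = chol @ rng.standard_normal(len(beta))
    return np.sqrt(n) * (R @ beta) + e


def _scaled_weight_vectors(ld: LdReference, panel: WeightPanel):
    """Per feature: (block id, indices, w / sqrt(w'Rw)) in LD coordinates."""
    out = []
    for f in panel:
        bid, idx = ld.locate(f.snp_ids)
        R_sub = ld.blocks[bid][np.ix_(idx, idx)]
        var = float(f.w @ R_sub @ f.w)
        out.append((bid, idx, f.w / np.sqrt(var)))
    return out


def simulate_gwas_sumstats(ld: LdReference, panel: WeightPanel | None,
                           alpha_per_feature: np.ndarray | None,
                           direct_effect_sd: float, n_gwas: float,
                           seed: int) -> pd.DataFrame:
    """Simulate a GWAS summary-statistics table with gene-mediated effects.

    ``alpha_per_feature`` (aligned to the panel) are per-SD-of-predicted-
    expression phenotypic effects; direct per-SNP effects are iid
    N(0, direct_effect_sd^2).  Output is in the sumstats dialect
    (SNP, A1, A2, Z, N) with CHR/BP carried along.
    """
    if n_gwas <= 0:
        raise InputError("n_gwas must be positive")
    rng = np.random.default_rng(seed)
    n_snps = ld.n_snps
    beta = np.zeros(n_snps)
    # global row index of each block's SNPs (snps table is block-ordered only
    # by construction, so map explicitly)
    block_rows = {b: np.flatnonzero((ld.snps["BLOCK"] == b).to_numpy())
                  for b in ld.block_ids()}
    if direct_effect_sd > 0:
        beta += rng.normal(0.0, direct_effect_sd, size=n_snps)
    if panel is not None and len(panel) > 0:
        if alpha_per_feature is None or len(alpha_per_feature) != len(panel):
            raise InputError("alpha_per_feature must align with the panel")
        for (bid, idx, w_std), a in zip(_scaled_weight_vectors(ld, panel),
                                        alpha_per_feature):
            if a != 0:
                beta[block_rows[bid][idx]] += a * w_std
    z = np.empty(n_snps)
    for bid in ld.block_ids():
        rows = block_rows[bid]
        R = ld.blocks[bid]
        z[rows] = simulate_z(R, beta[rows], n_gwas, rng)
    out = ld.snps[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    out["Z"] = z
    out["N"] = float(n_gwas)
    return out[["SNP", "A1", "A2", "Z", "N", "CHR", "BP"]]


def simulate_gene_sets_and_properties(
        gene_ids: list[str], n_sets: int, set_size: int,
        enriched_effect: float, seed: int, *,
        gene_effect_sd: float = 0.0, n_enriched: int = 0,
        property_corr: float = 0.0, n_stages: int = 19,
) -> tuple[dict[str, list[str]], pd.DataFrame, TruthTable]:
    """Sample gene sets, draw gene effects, and build property scores.

    Set membership is sampled without replacement.  The first ``n_enriched``
    sets are enriched: their member genes draw alpha from
    N(0, gene_effect_sd^2 + enriched_effect), i.e. an additive shift of
    ``enriched_effect`` on the expected alpha^2.  With ``enriched_effect = 0``
    every set is marked null.  Property scores for each of ``n_stages``
    developmental stages are Gaussian with correlation ``property_corr`` to
    the standardized alpha^2.
    """
    genes = list(gene_ids)
    if set_size >= len(genes):
        raise InputError("set_size must be smaller than the number of genes")
    if n_enriched > n_sets:
        raise InputError("n_enriched cannot exceed n_sets")
    if enriched_effect == 0:
        n_enriched = 0
    rng = np.random.default_rng(seed)
    gene_sets: dict[str, list[str]] = {}
    set_rows = []
    enriched_genes: set[str] = set()
    for s in range(n_sets):
        members = list(rng.choice(genes, size=set_size, replace=False))
        sid = f"SET{s:03d}"
        gene_sets[sid] = members
        is_enr = s < n_enriched
        if is_enr:
            enriched_genes.update(members)
        set_rows.append({"SET_ID": sid, "ENRICHED": bool(is_enr)})
    var = np.full(len(genes), gene_effect_sd ** 2)
    if enriched_genes:
        mask = np.array([g in enriched_genes for g in genes])
        var[mask] += enriched_effect
    alpha = rng.normal(0.0, 1.0, size=len(genes)) * np.sqrt(var)
    a2 = alpha ** 2
    sd = a2.std()
    a2_std = (a2 - a2.mean()) / sd if sd > 0 else np.zeros_like(a2)
    c = float(np.clip(property_corr, -1.0, 1.0))
    scores = (c * a2_std[:, None]
              + np.sqrt(1 - c ** 2) * rng.standard_normal((len(genes), n_stages)))
    props = pd.DataFrame(scores, columns=[f"STAGE_{k + 1}" for k in range(n_stages)])
    props.insert(0, "GENE", genes)
    truth = TruthTable(
        features=pd.DataFrame({"GENE_ID": genes, "ALPHA": alpha}),
        sets=pd.DataFrame(set_rows),
    )
    return gene_sets, props, truth


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run the full generator: LD -> weights -> sets/effects -> sumstats.

    Stage seeds are spawned from ``config.seed`` so the study is a pure
    function of the configuration.
    """
    s_ld, s_panel, s_sets, s_gwas = (
        int(x) for x in np.random.SeedSequence(config.seed).generate_state(4) >> 1)
    ld = simulate_ld_blocks(config.n_blocks, config.snps_per_block,
                            config.ar_rho, s_ld)
    panel = simulate_weight_panel(ld, config.n_features,
                                  config.weight_sparsity, config.cis_h2,
                                  s_panel)
    gene_sets, props, truth = simulate_gene_sets_and_properties(
        panel.gene_ids, config.n_sets, config.set_size,
        config.enriched_effect, s_sets,
        gene_effect_sd=config.gene_effect_sd,
        n_enriched=config.n_enriched,
        property_corr=config.property_corr,
        n_stages=config.n_stages)
    gene_alpha = dict(zip(truth.features["GENE_ID"], truth.features["ALPHA"]))
    alpha = np.array([gene_alpha[g] for g in panel.gene_ids])
    sumstats = simulate_gwas_sumstats(ld, panel, alpha,
                                      config.direct_effect_sd, config.n_gwas,
                                      s_gwas)
    feats = truth.features.copy()
    feats.insert(0, "FEATURE_ID", panel.feature_ids)
    truth.features = feats
    truth.h2_mediated = float(np.sum(alpha ** 2))
    truth.h2_direct = float(config.direct_effect_sd ** 2 * ld.n_snps)
    return SimulatedStudy(config=config, ld=ld, panel=panel,
                          sumstats=sumstats, gene_sets=gene_sets,
                          properties=props, truth=truth)
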