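"""Feature-level TWAS association from GWAS summary statistics.

The association statistic for a feature with weight vector ``w`` over SNPs
with marginal GWAS Z scores ``z`` and reference LD ``R`` is the standardized
imputed score

    Z_TWAS = (w' z) / sqrt(w' R w),

standard normal under the null of no association between the phenotype and
the feature's cis-predicted expression.  The module also computes the
predicted-expression correlation between features (needed by every downstream
stage) and the transcriptome-wide significance threshold that accounts for
those correlations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (AMBIGUOUS_PAIRS, DegenerateFeatureError,
                         FeatureCorrelation, FeatureWeights, InputError,
                         LdReference, WeightPanel)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEGENERATE_VAR_TOL = 1e-10


@dataclass
class HarmonizedFeature:
    """A feature's (w, z, R) triple aligned to the LD reference allele coding."""

    feature: FeatureWeights
    snp_ids: np.ndarray
    w: np.ndarray
    z: np.ndarray
    R: np.ndarray
    block_id: int
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.w)


def _orient(a1, a2, ref_a1, ref_a2) -> int | None:
    """Sign to map an allele coding onto a reference coding.

    +1 same, -1 swapped; strand flips are resolved via complements; ``None``
    for irreconcilable alleles.
    """
    if (a1, a2) == (ref_a1, ref_a2):
        return 1
    if (a1, a2) == (ref_a2, ref_a1):
        return -1
    ca1, ca2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
    if (ca1, ca2) == (ref_a1, ref_a2):
        return 1
    if (ca1, ca2) == (ref_a2, ref_a1):
        return -1
    return None


def harmonize_alleles(sumstats: pd.DataFrame, feature: FeatureWeights,
                      ld: LdReference) -> HarmonizedFeature | None:
    """Align a feature's weights and the GWAS Z scores to the LD coding.

    Weight signs and Z signs are flipped where the respective allele coding is
    swapped relative to the LD reference; strand-ambiguous (A/T, C/G) SNPs and
    SNPs missing from the sumstats or the LD reference are dropped and
    counted.  Returns ``None`` (caller logs and skips the feature) when no SNP
    survives.
    """
    ss = sumstats.set_index("SNP") if sumstats.index.name != "SNP" else sumstats
    dropped = {"missing_ld": 0, "missing_sumstats": 0, "ambiguous": 0,
               "mismatched": 0}
    keep_ids, w_out, z_out = [], [], []
    for k in range(feature.n_snps):
        snp = feature.snp_ids[k]
        fa1, fa2 = feature.a1[k], feature.a2[k]
        if (fa1, fa2) in AMBIGUOUS_PAIRS:
            dropped["ambiguous"] += 1
            continue
        if snp not in ld:
            dropped["missing_ld"] += 1
            continue
        if snp not in ss.index:
            dropped["missing_sumstats"] += 1
            continue
        ld_row = ld.snps.iloc[_ld_row_index(ld, snp)]
        sw = _orient(fa1, fa2, ld_row["A1"], ld_row["A2"])
        row = ss.loc[snp]
        sz = _orient(row["A1"], row["A2"], ld_row["A1"], ld_row["A2"])
        if sw is None or sz is None:
            dropped["mismatched"] += 1
            continue
        keep_ids.append(snp)
        w_out.append(sw * feature.w[k])
        z_out.append(sz * float(row["Z"]))
    if not keep_ids:
        logger.warning("feature %s: no SNPs left after harmonization (%s)",
                       feature.feature_id, dropped)
        return None
    bid, idx = ld.locate(keep_ids)
    R = ld.blocks[bid][np.ix_(idx, idx)]
    return HarmonizedFeature(feature=feature,
                             snp_ids=np.asarray(keep_ids, dtype=object),
                             w=np.asarray(w_out), z=np.asarray(z_out),
                             R=R, block_id=bid, dropped=dropped)


def _ld_row_index(ld: LdReference, snp: str) -> int:
    # positional row of a SNP in ld.snps
    return ld._row[snp]


def twas_association(w: np.ndarray, z: np.ndarray, R: np.ndarray
                     ) -> tuple[float, float, int]:
    """Z_TWAS = w'z / sqrt(w'Rw) with its two-sided normal p.

    Returns (z_twas, p, n_snps_used).  Invariant to rescaling ``w`` by any
    positive constant.
    """
    w = np.asarray(w, float)
    z = np.asarray(z, float)
    var = float(w @ R @ w)
    if var <= DEGENERATE_VAR_TOL:
        raise DegenerateFeatureError(
            f"predicted-expression variance w'Rw = {var:g} <= {DEGENERATE_VAR_TOL}")
    zt = float(w @ z) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zt))
    return zt, p, len(w)


def twas_scan(sumstats: pd.DataFrame, panel: WeightPanel, ld: LdReference,
              fdr_q: float = 0.05,
              significance_p: float | None = None) -> pd.DataFrame:
    """Per-feature TWAS over a whole weight panel.

    Returns a table with PANEL, FEATURE_ID, GENE_ID, CHR, P0, P1, NSNPS,
    TWAS_Z, TWAS_P, FDR_P and, when ``significance_p`` is given, a TW_SIG
    flag.  Features that lose all SNPs in harmonization or are degenerate are
    skipped with a single summary log line.
    """
    rows = []
    n_skipped = 0
    ss = sumstats if sumstats.index.name == "SNP" else sumstats.set_index(
        "SNP", drop=False)
    for f in panel:
        h = harmonize_alleles(ss, f, ld)
        if h is None:
            n_skipped += 1
            continue
        try:
            zt, p, n_used = twas_association(h.w, h.z, h.R)
        except DegenerateFeatureError:
            n_skipped += 1
            continue
        rows.append({"PANEL": f.panel_id, "FEATURE_ID": f.feature_id,
                     "GENE_ID": f.gene_id, "CHR": f.chrom, "P0": f.start,
                     "P1": f.stop, "NSNPS": n_used, "TWAS_Z": zt, "TWAS_P": p})
    if n_skipped:
        logger.info("twas_scan: skipped %d features (no usable SNPs or "
                    "degenerate variance)", n_skipped)
    res = pd.DataFrame(rows)
    if len(res):
        flags, adj = bh_fdr(res["TWAS_P"].to_numpy(), fdr_q)
        res["FDR_P"] = adj
        res["FDR_SIG"] = flags
        if significance_p is not None:
            res["TW_SIG"] = res["TWAS_P"] < significance_p
    return res


def feature_correlations(panel: WeightPanel, ld: LdReference
                         ) -> FeatureCorrelation:
    """Pairwise predicted-expression correlations, computed block by block.

    r_ij = w_i'Rw_j / sqrt(w_i'Rw_i * w_j'Rw_j) for features in the same LD
    block; exactly zero otherwise.  Degenerate features (w'Rw below tolerance)
    are excluded with a log line.
    """
    per_block: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    kept_ids: list[str] = []
    n_dropped = 0
    for f in panel:
        bid, idx = ld.locate(f.snp_ids)
        R_sub = ld.blocks[bid][np.ix_(idx, idx)]
        if float(f.w @ R_sub @ f.w) <= DEGENERATE_VAR_TOL:
            n_dropped += 1
            continue
        per_block.setdefault(bid, []).append((len(kept_ids), idx, f.w))
        kept_ids.append(f.feature_id)
    if n_dropped:
        logger.info("feature_correlations: excluded %d degenerate features",
                    n_dropped)
    blocks = []
    for bid, members in per_block.items():
        R = ld.blocks[bid]
        m = R.shape[0]
        W = np.zeros((m, len(members)))
        order = np.empty(len(members), dtype=int)
        for j, (gidx, idx, w) in enumerate(members):
            W[idx, j] = w
            order[j] = gidx
        G = W.T @ R @ W
        d = np.sqrt(np.diag(G))
        Cb = G / np.outer(d, d)
        np.fill_diagonal(Cb, 1.0)
        blocks.append((order, Cb))
    return FeatureCorrelation(feature_ids=np.asarray(kept_ids, dtype=object),
                              blocks=blocks)


def _block_cholesky(C: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semidefinite blocks."""
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(C)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def permutation_significance_threshold(
        corr: FeatureCorrelation, alpha_fwer: float = 0.05,
        n_draws: int = 50_000, seed: int = 0
) -> tuple[float, float]:
    """Transcriptome-wide significance threshold from the min-p null.

    Draws ``n_draws`` feature-Z vectors from MVN(0, C) (block-wise, C the
    feature correlation structure), records each draw's minimum two-sided p
    over all features, and returns the ``alpha_fwer`` quantile of that
    distribution together with its Monte-Carlo standard error (order-statistic
    spread estimate).  In distribution this equals permuting a null GWAS and
    re-running the scan, at a fraction of the cost.
    """
    if n_draws < 1_000:
        raise InputError("n_draws must be at least 1,000")
    if corr.n_features < 2:
        logger.warning("fewer than 2 features: threshold = alpha_fwer")
        return float(alpha_fwer), 0.0
    rng = np.random.default_rng(seed)
    max_abs = np.zeros(n_draws)
    for idx, Cb in corr.blocks:
        L = _block_cholesky(Cb)
        draws = rng.standard_normal((n_draws, L.shape[1])) @ L.T
        np.maximum(max_abs, np.abs(draws).max(axis=1), out=max_abs)
    minp = np.sort(2.0 * stats.norm.sf(max_abs))
    k = alpha_fwer * n_draws
    thresh = float(minp[int(k)])
    half = np.sqrt(n_draws * alpha_fwer * (1 - alpha_fwer))
    lo = int(max(k - half, 0))
    hi = int(min(k + half, n_draws - 1))
    mc_se = float((minp[hi] - minp[lo]) / 2.0)
    return thresh, mc_se


def bh_fdr(p_values: np.ndarray, q: float = 0.05
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (discovery flags, adjusted p)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adj
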