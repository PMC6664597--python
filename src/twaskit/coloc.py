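"""Approximate-Bayes-factor colocalization of GWAS and expression signals.

For each SNP j and trait, the evidence for a nonzero effect is summarized by
Wakefield's approximate Bayes factor computed from the marginal Z score, the
sampling variance of the standardized effect (v ~ 1/N), and a prior effect
variance W:

    ABF_j = sqrt(1 - r) * exp(z_j^2 * r / 2),   r = W / (W + v).

Under a single-causal-variant assumption per trait, the five hypotheses are

    H0 no association;  H1/H2 one trait only;  H3 two distinct causal SNPs;
    H4 one shared causal SNP,

with posteriors proportional to prior-weighted sums of ABFs over causal
configurations, all evaluated in log space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .containers import InputError, LdReference, WeightPanel
from .assoc import harmonize_alleles

DEFAULT_PRIOR_SD = 0.15     # prior SD of the standardized per-SNP effect
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int

    @property
    def best_model(self) -> int:
        return int(np.argmax([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4]))

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_log_abf(z, v, W: float = DEFAULT_PRIOR_SD ** 2) -> np.ndarray:
    """Natural-log Wakefield ABF; stable for |z| well beyond 40.

    ``v`` is the sampling variance of the standardized effect (1/N when only
    Z and N are known); ``W`` the prior effect variance.  W = 0 gives
    log ABF = 0 (point-null prior carries no evidence either way).
    """
    z = np.asarray(z, float)
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise InputError("sampling variance v must be positive")
    if W < 0:
        raise InputError("prior variance W must be non-negative")
    r = W / (W + v)
    return 0.5 * (np.log1p(-r) + z ** 2 * r)


def coloc_posteriors(labf1: np.ndarray, labf2: np.ndarray,
                     p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                     p12: float = DEFAULT_P12) -> ColocResult:
    """Posterior probabilities of H0-H4 from per-SNP log ABFs of two traits.

    H1/H2 sum single-causal configurations per trait, H3 sums ordered pairs
    of *distinct* SNPs, H4 the shared-SNP configurations; everything uses
    log-sum-exp.  Priors are per-SNP causal probabilities with
    p12 <= min(p1, p2).
    """
    labf1 = np.asarray(labf1, float)
    labf2 = np.asarray(labf2, float)
    if labf1.size == 0 or labf1.shape != labf2.shape:
        raise InputError("labf vectors must be equal-length and non-empty")
    for name, v in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0 < v < 1:
            raise InputError(f"{name} must lie in (0, 1)")
    if p12 > min(p1, p2):
        raise InputError("p12 must not exceed min(p1, p2)")
    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + l1
    lh[2] = np.log(p2) + l2
    # sum over i != j of exp(labf1_i + labf2_j) = exp(l1+l2) - exp(l12)
    diff = l12 - (l1 + l2)
    if diff >= 0:  # single SNP (or numerically saturated): no distinct pair
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + l1 + l2 + np.log1p(-np.exp(diff))
    lh[4] = np.log(p12) + l12
    lh -= logsumexp(lh)
    pp = np.exp(lh)
    return ColocResult(*pp, n_snps=labf1.size)


def implied_eqtl_z(feature_w: np.ndarray, snp_idx: np.ndarray,
                   R: np.ndarray, n_eqtl: float) -> np.ndarray:
    """Expression-side marginal Z implied by a feature's weights.

    The marginal eQTL Z of block SNP j for a feature with (LD-aligned) weight
    vector w is reconstructed as sqrt(N_eqtl) * (R w)_j / sqrt(w'Rw), the
    expected marginal statistic when predicted expression is the trait.
    """
    full_w = np.zeros(R.shape[0])
    full_w[snp_idx] = feature_w
    num = R @ full_w
    return np.sqrt(n_eqtl) * num / np.sqrt(full_w @ num)


def feature_coloc(sumstats, feature, ld: LdReference, n_eqtl: float,
                  p1: float = DEFAULT_P1, p2: float = DEFAULT_P2,
                  p12: float = DEFAULT_P12,
                  prior_sd: float = DEFAULT_PRIOR_SD) -> ColocResult | None:
    """Colocalize the GWAS signal with one feature's expression signal.

    Uses all SNPs of the feature's LD block that are present in the GWAS;
    the expression side comes from :func:`implied_eqtl_z`.  Returns None when
    harmonization leaves no usable SNP.
    """
    h = harmonize_alleles(sumstats, feature, ld)
    if h is None:
        return None
    R = ld.blocks[h.block_id]
    _, f_idx = ld.locate(h.snp_ids)
    z2_full = implied_eqtl_z(h.w, f_idx, R, n_eqtl)
    block_tab = ld.block_snps(h.block_id)
    ss = sumstats if sumstats.index.name == "SNP" else sumstats.set_index(
        "SNP", drop=False)
    keep, z1 = [], []
    for i, snp in enumerate(block_tab["SNP"]):
        if snp in ss.index:
            keep.append(i)
            z1.append(float(ss.loc[snp, "Z"]))
    if not keep:
        return None
    z1 = np.asarray(z1)
    n1 = float(np.median(ss["N"]))
    labf1 = wakefield_log_abf(z1, 1.0 / n1, prior_sd ** 2)
    labf2 = wakefield_log_abf(z2_full[keep], 1.0 / n_eqtl, prior_sd ** 2)
    return coloc_posteriors(labf1, labf2, p1, p2, p12)


def coloc_scan(sumstats, panel: WeightPanel, ld: LdReference, n_eqtl: float,
               **priors):
    """Per-feature colocalization table (FEATURE_ID, NSNPS, PP0..PP4, BEST)."""
    import pandas as pd

    rows = []
    for f in panel:
        res = feature_coloc(sumstats, f, ld, n_eqtl, **priors)
        if res is None:
            continue
        rows.append({"FEATURE_ID": f.feature_id, "NSNPS": res.n_snps,
                     "PP0": res.pp0, "PP1": res.pp1, "PP2": res.pp2,
                     "PP3": res.pp3, "PP4": res.pp4,
                     "BEST_MODEL": res.best_model})
    return pd.DataFrame(rows)
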