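"""SNP heritability and its expression-mediated share via LD score regression.

Standard LD score regression exploits E[chi2_j] = 1 + N * tau * l_j, where
l_j = sum_k r2_jk is SNP j's LD score; the slope recovers the per-SNP effect
variance and M * tau the total SNP heritability.  The expression-mediated
share uses a second LD-score column weighted by predicted expression:

    lE_j = sum_f rho^2(j, f),   rho(j, f) = (R w_f)_j / sqrt(w_f' R w_f),

the squared correlation between SNP j and each feature's predicted
expression.  Under the gene-mediated architecture E[chi2_j] - 1 =
N * (tau_dir * l_j + alpha_var * lE_j), so the lE slope identifies the
per-feature effect variance and (number of features) * slope the mediated
heritability (features are scaled to unit predicted-expression variance).
Standard errors come from a leave-one-out block jackknife over contiguous
SNP blocks; case-control estimates are converted to the liability scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (DegenerateRegressionError, InputError, LdReference,
                         WeightPanel)

DEFAULT_JACKKNIFE_BLOCKS = 200


@dataclass
class H2Result:
    category: str
    h2_obs: float
    se_obs: float
    intercept: float
    h2_liab: float = np.nan
    se_liab: float = np.nan


def ld_scores(ld: LdReference) -> pd.Series:
    """Total LD score per SNP: l_j = sum_k r2_jk within the block
    (self term included), indexed like ``ld.snps``."""
    out = np.empty(ld.n_snps)
    for bid in ld.block_ids():
        rows = np.flatnonzero((ld.snps["BLOCK"] == bid).to_numpy())
        out[rows] = np.sum(ld.blocks[bid] ** 2, axis=1)
    return pd.Series(out, index=ld.snps["SNP"].to_numpy(), name="L2_TOTAL")


def predicted_expression_ld_scores(panel: WeightPanel, ld: LdReference
                                   ) -> pd.Series:
    """Expression-weighted LD score per SNP: lE_j = sum_f rho^2(j, f).

    Additive over features; SNPs in blocks with no feature get 0.
    """
    out = np.zeros(ld.n_snps)
    block_rows = {b: np.flatnonzero((ld.snps["BLOCK"] == b).to_numpy())
                  for b in ld.block_ids()}
    for f in panel:
        bid, idx = ld.locate(f.snp_ids)
        R = ld.blocks[bid]
        full_w = np.zeros(R.shape[0])
        full_w[idx] = f.w
        num = R @ full_w
        rho = num / np.sqrt(full_w @ num)
        out[block_rows[bid]] += rho ** 2
    return pd.Series(out, index=ld.snps["SNP"].to_numpy(), name="L2_EXPR")


def _wls_jackknife(X: np.ndarray, y: np.ndarray, W: np.ndarray,
                   n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """WLS coefficients plus delete-one-block estimates (contiguous blocks)."""
    n, p = X.shape
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    A_blocks = np.empty((n_blocks, p, p))
    b_blocks = np.empty((n_blocks, p))
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        Xw = X[sl] * W[sl, None]
        A_blocks[b] = Xw.T @ X[sl]
        b_blocks[b] = Xw.T @ y[sl]
    A, bvec = A_blocks.sum(0), b_blocks.sum(0)
    coef = np.linalg.solve(A, bvec)
    theta = np.empty((n_blocks, p))
    for b in range(n_blocks):
        theta[b] = np.linalg.solve(A - A_blocks[b], bvec - b_blocks[b])
    return coef, theta


def ldsc_fit(chi2: np.ndarray, ld_score_cols: pd.DataFrame | np.ndarray,
             n_gwas: float, multipliers: dict[str, float] | list[float],
             n_jackknife_blocks: int = DEFAULT_JACKKNIFE_BLOCKS,
             weights: np.ndarray | None = None,
             return_jackknife: bool = False):
    """Weighted LD-score regression with block-jackknife standard errors.

    Fits chi2_j = 1 + N * sum_c tau_c * l_cj with a free intercept by
    weighted least squares.  When ``weights`` is not supplied the fit is
    two-pass: a first pass with weights 1 / max(l, 1) yields fitted mean
    chi-squares, and the second pass adds the heteroskedasticity factor
    1 / (2 * fitted^2) — without it, high-signal SNPs (whose chi2 variance
    grows with the square of their expectation) drown the regression.
    Each category's heritability is multiplier_c * tau_c; the multiplier is
    the number of SNPs for a per-SNP category and the number of features for
    the expression-mediated category.  SEs are delete-one jackknife over
    ``n_jackknife_blocks`` contiguous SNP blocks.
    """
    if isinstance(ld_score_cols, pd.DataFrame):
        names = list(ld_score_cols.columns)
        L = ld_score_cols.to_numpy(float)
    else:
        L = np.atleast_2d(np.asarray(ld_score_cols, float))
        if L.shape[0] != len(chi2):
            L = L.T
        names = [f"cat{i}" for i in range(L.shape[1])]
    if isinstance(multipliers, dict):
        mult = np.array([multipliers[c] for c in names], float)
    else:
        mult = np.asarray(multipliers, float)
    chi2 = np.asarray(chi2, float)
    n_snps, n_cat = L.shape
    if n_jackknife_blocks < 2:
        raise InputError("need at least 2 jackknife blocks")
    for c in range(n_cat):
        if np.ptp(L[:, c]) == 0:
            raise DegenerateRegressionError(
                f"LD score column {names[c]!r} is constant")
    X = np.column_stack([np.ones(n_snps), n_gwas * L])
    y = chi2
    base_w = 1.0 / np.maximum(L[:, 0], 1.0)
    if weights is None:
        coef0, _ = _wls_jackknife(X, y, base_w, 2)
        fitted = np.clip(X @ coef0, 1.0, None)
        W = base_w / (2.0 * fitted ** 2)
    else:
        W = np.asarray(weights, float)
    coef, theta = _wls_jackknife(X, y, W, n_jackknife_blocks)
    nb = n_jackknife_blocks
    se = np.sqrt((nb - 1) / nb * np.sum((theta - theta.mean(0)) ** 2, axis=0))

    results = []
    for c in range(n_cat):
        results.append(H2Result(category=names[c],
                                h2_obs=float(mult[c] * coef[c + 1]),
                                se_obs=float(mult[c] * se[c + 1]),
                                intercept=float(coef[0])))
    if return_jackknife:
        return results, coef, theta, mult
    return results


def liability_scale_transform(h2_obs: float, prevalence: float,
                              sample_prevalence: float) -> float:
    """Observed-scale case-control h2 -> liability scale.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P (1-P) * phi(t)^2), t = Phi^-1(1-K),
    with K the population and P the sample case prevalence.
    """
    K, P = prevalence, sample_prevalence
    if not (0 < K < 1) or not (0 < P < 1):
        raise InputError("prevalences must lie strictly in (0, 1)")
    t = stats.norm.isf(K)
    phi = stats.norm.pdf(t)
    return h2_obs * K ** 2 * (1 - K) ** 2 / (P * (1 - P) * phi ** 2)


def twas_h2_proportion(h2_twas: float, h2_total: float) -> float:
    """Share of SNP heritability mediated by predicted expression, percent."""
    if h2_total <= 0:
        raise InputError("total heritability must be positive")
    pct = 100.0 * h2_twas / h2_total
    if pct > 100:
        import logging
        logging.getLogger(__name__).warning(
            "TWAS heritability exceeds total (%.1f%%)", pct)
    return pct


def expression_mediated_h2(sumstats: pd.DataFrame, panel: WeightPanel,
                           ld: LdReference, prevalence: float | None = None,
                           sample_prevalence: float | None = None,
                           n_jackknife_blocks: int = DEFAULT_JACKKNIFE_BLOCKS
                           ) -> pd.DataFrame:
    """Full heritability report: total, expression-mediated, and their ratio.

    Both quantities come from one two-column stratified fit (total +
    expression-weighted LD scores): the mediated share is (number of
    features) * tau_twas, and the total is the full decomposition
    M * tau_total + (number of features) * tau_twas, so the two are on the
    same footing and their ratio is the mediated proportion.  Jackknife SEs
    are propagated through the linear combinations.  When prevalences are
    given both estimates are converted to the liability scale (the
    conversion cancels in the ratio).  Returns a table with CATEGORY,
    H2_OBS, H2_LIAB, SE, INTERCEPT, PROPORTION_PCT.
    """
    ss = sumstats.set_index("SNP", drop=False) \
        if sumstats.index.name != "SNP" else sumstats
    l_tot = ld_scores(ld)
    l_exp = predicted_expression_ld_scores(panel, ld)
    common = l_tot.index.intersection(ss.index)
    chi2 = ss.loc[common, "Z"].to_numpy(float) ** 2
    n_gwas = float(np.median(ss["N"]))
    M = len(common)
    strat, coef, theta, mult = ldsc_fit(
        chi2, pd.DataFrame({"total": l_tot.loc[common],
                            "twas": l_exp.loc[common]}),
        n_gwas, {"total": M, "twas": len(panel)}, n_jackknife_blocks,
        return_jackknife=True)
    twas = next(r for r in strat if r.category == "twas")
    # total = M * tau_total + n_features * tau_twas, jackknifed jointly
    comb = np.array([0.0, mult[0], mult[1]])
    h2_tot = float(comb @ coef)
    tot_reps = theta @ comb
    nb = len(theta)
    se_tot = float(np.sqrt((nb - 1) / nb * np.sum((tot_reps - tot_reps.mean()) ** 2)))
    total = H2Result(category="total", h2_obs=h2_tot, se_obs=se_tot,
                     intercept=float(coef[0]))
    for r in (total, twas):
        if prevalence is not None and sample_prevalence is not None:
            factor = liability_scale_transform(1.0, prevalence,
                                               sample_prevalence)
            r.h2_liab = r.h2_obs * factor
            r.se_liab = r.se_obs * factor
        else:
            r.h2_liab, r.se_liab = r.h2_obs, r.se_obs
    prop = twas_h2_proportion(twas.h2_liab, total.h2_liab) \
        if total.h2_liab > 0 else np.nan
    return pd.DataFrame([
        {"CATEGORY": r.category, "H2_OBS": r.h2_obs, "H2_LIAB": r.h2_liab,
         "SE": r.se_liab, "INTERCEPT": r.intercept,
         "PROPORTION_PCT": prop if r.category == "twas" else 100.0}
        for r in (total, twas)])
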