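"""Competitive enrichment of TWAS results via a linear mixed model.

Features in LD have correlated TWAS statistics, so a naive regression of
association strength on gene-set membership is anti-conservative.  Here the
dependence is absorbed by a random effect whose covariance is a feature
*relatedness* matrix K built from squared predicted-expression correlations
(squaring because the sign of the expression correlation is irrelevant to the
covariance of association magnitude):

    z_assoc = b0 + b_s * s + (covariates) + g + e,
    g ~ N(0, sg^2 * K),  e ~ N(0, se^2 * I).

The response is the positive-oriented association Z, z_assoc = Phi^-1(1 - p)
from the two-sided TWAS p (so opposite-direction effects cannot cancel).
Variance components come from REML on a one-dimensional profile: K is
eigendecomposed once (block by block), the model rotated into its eigenbasis,
and the ratio sg^2/se^2 optimized by bounded scalar search.  The set test is
one-sided (enrichment only); continuous gene-property tests are two-sided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import FeatureCorrelation, InputError
from .assoc import bh_fdr

logger = logging.getLogger(__name__)

_P_FLOOR = np.finfo(float).tiny


@dataclass
class EnrichmentResult:
    set_id: str
    beta: float
    se: float
    p: float
    n_members: int
    fdr_p: float = np.nan


class FeatureRelatedness:
    """Block-diagonal similarity matrix K of squared feature correlations.

    Negative eigenvalues (possible after squaring entrywise) are clipped to
    zero and the matrix renormalized to unit diagonal, so K is PSD with
    diag(K) = 1.  Stores the eigendecomposition block by block; ``rotate``
    maps a vector into the eigenbasis of K.
    """

    def __init__(self, feature_ids: np.ndarray,
                 blocks: list[tuple[np.ndarray, np.ndarray]]):
        self.feature_ids = np.asarray(feature_ids, dtype=object)
        self._blocks = []
        n = len(self.feature_ids)
        covered = np.zeros(n, bool)
        for idx, K in blocks:
            K = self._clip_psd(K)
            vals, vecs = np.linalg.eigh(K)
            self._blocks.append((np.asarray(idx, int), K,
                                 np.clip(vals, 0.0, None), vecs))
            covered[idx] = True
        # features in no block behave as independent (K entry = identity)
        lone = np.flatnonzero(~covered)
        if lone.size:
            self._blocks.append((lone, np.eye(lone.size),
                                 np.ones(lone.size), np.eye(lone.size)))

    @staticmethod
    def _clip_psd(K: np.ndarray) -> np.ndarray:
        vals, vecs = np.linalg.eigh(K)
        if vals.min() >= -1e-12:
            return K
        K = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
        d = np.sqrt(np.diag(K))
        d[d == 0] = 1.0
        K = K / np.outer(d, d)
        np.fill_diagonal(K, 1.0)
        return K

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def eigenvalues(self) -> np.ndarray:
        out = np.empty(self.n_features)
        for idx, _, vals, _ in self._blocks:
            out[idx] = vals
        return out

    def rotate(self, y: np.ndarray) -> np.ndarray:
        """U' y in the (block-wise) eigenbasis, ordered like eigenvalues."""
        y = np.asarray(y, float)
        out = np.empty_like(y) if y.ndim == 1 else np.empty(y.shape)
        for idx, _, _, vecs in self._blocks:
            out[idx] = vecs.T @ y[idx]
        return out

    def full(self) -> np.ndarray:
        K = np.eye(self.n_features)
        for idx, Kb, _, _ in self._blocks:
            K[np.ix_(idx, idx)] = Kb
        return K

    def subset(self, mask: np.ndarray) -> "FeatureRelatedness":
        mask = np.asarray(mask, bool)
        new_pos = np.cumsum(mask) - 1
        blocks = []
        for idx, Kb, _, _ in self._blocks:
            keep = mask[idx]
            if keep.any():
                blocks.append((new_pos[idx[keep]], Kb[np.ix_(keep, keep)]))
        return FeatureRelatedness(self.feature_ids[mask], blocks)


def association_z_transform(p_two_sided: np.ndarray) -> np.ndarray:
    """Positive-oriented association Z: Phi^-1(1 - p), with p=0 clamped."""
    p = np.asarray(p_two_sided, float)
    if np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("p = 0 clamped to the smallest positive float")
    # clamp both ends so the transform stays finite (p=1 -> ~ -8.1)
    p = np.clip(p, _P_FLOOR, 1.0 - np.finfo(float).eps)
    return stats.norm.isf(p)


def build_feature_relatedness(corr: FeatureCorrelation) -> FeatureRelatedness:
    """K from squared predicted-expression correlations, block-wise."""
    blocks = [(idx, Cb ** 2) for idx, Cb in corr.blocks]
    return FeatureRelatedness(corr.feature_ids, blocks)


def _reml_fit(y: np.ndarray, X: np.ndarray, relatedness: FeatureRelatedness
              ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Profile-REML LMM fit in the eigenbasis of K.

    Returns (beta, cov_beta, residual df, variance ratio sg^2/se^2).
    Falls back to OLS (ratio 0) if the scalar search fails.
    """
    n, p = X.shape
    lam = relatedness.eigenvalues
    yr = relatedness.rotate(y)
    Xr = relatedness.rotate(X)

    def neg2_reml(log_ratio: float) -> float:
        d = np.exp(log_ratio) * lam + 1.0
        Xw = Xr / d[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        resid = yr - Xr @ beta
        rss = float(resid @ (resid / d))
        s2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(XtWX)
        return (n - p) * np.log(s2) + float(np.sum(np.log(d))) + logdet

    try:
        res = optimize.minimize_scalar(neg2_reml, bounds=(-12.0, 12.0),
                                       method="bounded",
                                       options={"xatol": 1e-6})
        ratio = float(np.exp(res.x)) if res.success else 0.0
        if not res.success:
            logger.warning("REML search did not converge; using OLS fallback")
    except Exception:
        logger.warning("REML search failed; using OLS fallback")
        ratio = 0.0
    d = ratio * lam + 1.0
    Xw = Xr / d[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    s2 = float(resid @ (resid / d)) / (n - p)
    cov = s2 * np.linalg.inv(XtWX)
    return beta, cov, float(n - p), ratio


def competitive_set_test(z_assoc: np.ndarray, membership: np.ndarray,
                         relatedness: FeatureRelatedness,
                         covariates: np.ndarray | None = None,
                         set_id: str = "set",
                         one_sided: bool = True) -> EnrichmentResult:
    """Mixed-model competitive test of one gene set (or continuous score).

    ``membership`` is the 0/1 indicator (or a continuous predictor); the
    Wald test uses a t reference with residual degrees of freedom, so with
    K = identity the result is exactly the OLS t test.
    """
    y = np.asarray(z_assoc, float)
    s = np.asarray(membership, float)
    if s.ndim != 1 or len(s) != len(y):
        raise InputError("membership must align with z_assoc")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise InputError(f"{set_id}: degenerate membership (constant)")
    cols = [np.ones_like(y), s]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != len(y):
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    beta, covb, df, _ = _reml_fit(y, X, relatedness)
    b, se = float(beta[1]), float(np.sqrt(covb[1, 1]))
    t = b / se
    p = float(stats.t.sf(t, df)) if one_sided else float(2 * stats.t.sf(abs(t), df))
    n_members = int(np.sum(s != 0)) if set(uniq) <= {0.0, 1.0} else len(y)
    return EnrichmentResult(set_id=set_id, beta=b, se=se, p=p,
                            n_members=n_members)


def gene_set_enrichment(z_assoc: np.ndarray, gene_ids: list[str],
                        gene_sets: dict[str, list[str]],
                        relatedness: FeatureRelatedness,
                        covariates: np.ndarray | None = None,
                        fdr_q: float = 0.05) -> pd.DataFrame:
    """Run the competitive test for every gene set; FDR across sets.

    Set membership is propagated from genes to all their features.  Sets
    whose membership is degenerate (no member feature, or all features) are
    skipped with a log line.
    """
    results = []
    genes = np.asarray(gene_ids, dtype=object)
    for sid, members in gene_sets.items():
        s = np.isin(genes, list(members)).astype(float)
        try:
            r = competitive_set_test(z_assoc, s, relatedness, covariates, sid)
        except InputError:
            logger.info("set %s skipped: degenerate membership", sid)
            continue
        results.append(r)
    df = pd.DataFrame([{"SET_ID": r.set_id, "N_GENES": r.n_members,
                        "BETA": r.beta, "SE": r.se, "P": r.p}
                       for r in results])
    if len(df):
        _, adj = bh_fdr(df["P"].to_numpy(), fdr_q)
        df["FDR_P"] = adj
    return df


def property_gradient_test(z_assoc: np.ndarray, scores: pd.DataFrame,
                           relatedness: FeatureRelatedness,
                           alpha: float = 0.05,
                           covariates: np.ndarray | None = None
                           ) -> pd.DataFrame:
    """Two-sided mixed-model test of each continuous gene property.

    One fit per score column (each centered and scaled first); Bonferroni
    significance at alpha / n_stages.  Constant columns are skipped.
    """
    stage_cols = [c for c in scores.columns if c != "GENE"]
    bonf = alpha / max(len(stage_cols), 1)
    rows = []
    for col in stage_cols:
        x = scores[col].to_numpy(float)
        sd = x.std()
        if not np.isfinite(sd) or sd == 0:
            logger.info("stage %s skipped: constant score", col)
            continue
        x = (x - x.mean()) / sd
        r = competitive_set_test(z_assoc, x, relatedness, covariates,
                                 set_id=col, one_sided=False)
        rows.append({"SET_ID": col, "BETA": r.beta, "SE": r.se, "P": r.p,
                     "BONF_SIG": r.p < bonf})
    return pd.DataFrame(rows)


def weight_set_enrichment(z_assoc: np.ndarray, panel_labels: list[str],
                          relatedness: FeatureRelatedness,
                          restrict_to: list[str] | None = None
                          ) -> pd.DataFrame:
    """Competitive enrichment of each SNP-weight set against the others.

    ``restrict_to`` re-subsets the features (and K) to a panel subset first,
    e.g. the basal-ganglia panels alone; at least two panels must remain.
    """
    labels = np.asarray(panel_labels, dtype=object)
    y = np.asarray(z_assoc, float)
    rel = relatedness
    if restrict_to is not None:
        mask = np.isin(labels, list(restrict_to))
        labels, y = labels[mask], y[mask]
        rel = relatedness.subset(mask)
    panels = sorted(set(labels))
    if len(panels) < 2:
        raise InputError("at least two panels required for panel enrichment")
    rows = []
    for pid in panels:
        s = (labels == pid).astype(float)
        r = competitive_set_test(y, s, rel, set_id=pid)
        rows.append({"SET_ID": pid, "N_GENES": r.n_members, "BETA": r.beta,
                     "SE": r.se, "P": r.p})
    return pd.DataFrame(rows)
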