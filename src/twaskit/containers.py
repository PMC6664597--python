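"""Core in-memory containers shared across the pipeline.

The whole chain runs on summary-level data: per-SNP GWAS Z scores, per-feature
cis SNP weights, and a block-diagonal LD correlation structure from a reference
panel.  A *feature* is one gene x expression-panel unit with its own weight
vector; ``w' R w`` is the variance of its predicted expression.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ("SNP", "A1", "A2", "Z", "N")

#: strand-ambiguous allele pairs (indistinguishable under strand flip)
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class InputError(ValueError):
    """A caller-supplied value violates a precondition."""


class FormatError(ValueError):
    """An on-disk file violates its format contract (CLI exit code 2)."""


class DegenerateFeatureError(InputError):
    """Feature with (near-)zero predicted-expression variance: w'Rw <= tol."""


class DegenerateRegressionError(InputError):
    """LD-score regression with a constant regressor column."""


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a GWAS summary-statistics table (LDSC sumstats dialect).

    Requires columns SNP, A1, A2, Z, N; unique SNP ids; positive N.  Rows with
    non-finite Z are dropped and counted in ``df.attrs['n_dropped_z']``.
    """
    for col in SUMSTATS_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"sumstats missing required column {col!r}")
    if df["SNP"].duplicated().any():
        dup = df.loc[df["SNP"].duplicated(), "SNP"].iloc[0]
        raise FormatError(f"duplicate SNP id in sumstats: {dup!r}")
    z = pd.to_numeric(df["Z"], errors="coerce")
    keep = np.isfinite(z.to_numpy(dtype=float, na_value=np.nan))
    n_dropped = int((~keep).sum())
    out = df.loc[keep].copy()
    out["Z"] = z[keep].astype(float)
    out["N"] = pd.to_numeric(out["N"]).astype(float)
    if (out["N"] <= 0).any():
        raise FormatError("sumstats column N must be positive")
    out = out.reset_index(drop=True)
    out.attrs["n_dropped_z"] = n_dropped
    return out


@dataclass
class LdReference:
    """Block-diagonal SNP correlation structure from a reference panel.

    Parameters
    ----------
    snps
        SNP metadata with columns SNP, CHR, BP, A1, A2, BLOCK (1-based bp).
    blocks
        Mapping block id -> dense correlation matrix, ordered as the block's
        rows appear in ``snps``.
    """

    snps: pd.DataFrame
    blocks: dict[int, np.ndarray]
    _index: dict[str, tuple[int, int]] = field(init=False, repr=False)
    _row: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for bid, R in self.blocks.items():
            n = int((self.snps["BLOCK"] == bid).sum())
            if R.shape != (n, n):
                raise InputError(f"block {bid}: matrix shape {R.shape} != {n} SNPs")
        self._index = {}
        self._row = {}
        counters: dict[int, int] = {}
        for row, (snp, bid) in enumerate(zip(self.snps["SNP"], self.snps["BLOCK"])):
            i = counters.get(bid, 0)
            self._index[str(snp)] = (int(bid), i)
            self._row[str(snp)] = row
            counters[bid] = i + 1

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def block_ids(self) -> list[int]:
        return sorted(self.blocks)

    def block_snps(self, block_id: int) -> pd.DataFrame:
        return self.snps[self.snps["BLOCK"] == block_id]

    def locate(self, snp_ids) -> tuple[int, np.ndarray]:
        """Map SNP ids to (block id, within-block indices).

        All SNPs must live in a single block: cross-block correlations are
        exactly zero, so a feature spanning blocks is an input error.
        """
        found = [self._index[s] for s in snp_ids if s in self._index]
        if not found:
            raise InputError("none of the requested SNPs are in the LD reference")
        bids = {b for b, _ in found}
        if len(bids) > 1:
            raise InputError(f"SNPs span multiple LD blocks: {sorted(bids)}")
        bid = bids.pop()
        return bid, np.array([i for _, i in found], dtype=int)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index


@dataclass
class FeatureWeights:
    """cis SNP weights predicting one feature's expression.

    ``w`` is the weight vector over ``snp_ids``; ``cis_h2`` is the fraction of
    expression variance explained by the cis SNPs (the target of w'Rw).
    """

    feature_id: str
    gene_id: str
    panel_id: str
    chrom: int
    start: int
    stop: int
    snp_ids: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    w: np.ndarray
    cis_h2: float

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.w = np.asarray(self.w, dtype=float)
        if not np.any(self.w != 0):
            raise InputError(f"{self.feature_id}: all weights are zero")
        if self.start > self.stop:
            raise InputError(f"{self.feature_id}: start > stop")

    @property
    def n_snps(self) -> int:
        return len(self.w)


@dataclass
class WeightPanel:
    """An ordered collection of features (one or more SNP-weight sets)."""

    features: list[FeatureWeights]

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, key):
        if isinstance(key, str):
            for f in self.features:
                if f.feature_id == key:
                    return f
            raise KeyError(key)
        return self.features[key]

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def gene_ids(self) -> list[str]:
        return [f.gene_id for f in self.features]

    @property
    def panel_ids(self) -> list[str]:
        return [f.panel_id for f in self.features]

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "PANEL": f.panel_id,
                "FEATURE_ID": f.feature_id,
                "GENE_ID": f.gene_id,
                "CHR": f.chrom,
                "P0": f.start,
                "P1": f.stop,
                "CIS_H2": f.cis_h2,
            }
            for f in self.features
        ]
        return pd.DataFrame(rows)


@dataclass
class FeatureCorrelation:
    """Predicted-expression correlations between features, block by block.

    r_ij = (w_i' R w_j) / sqrt((w_i'Rw_i)(w_j'Rw_j)); exactly zero across LD
    blocks.  ``blocks`` holds (feature index array into ``feature_ids``,
    within-block correlation matrix) pairs.
    """

    feature_ids: np.ndarray
    blocks: list[tuple[np.ndarray, np.ndarray]]

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def full(self) -> np.ndarray:
        """Dense feature-by-feature correlation matrix (zeros across blocks)."""
        C = np.zeros((self.n_features, self.n_features))
        for idx, Cb in self.blocks:
            C[np.ix_(idx, idx)] = Cb
        return C

    def submatrix(self, feature_ids) -> np.ndarray:
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        sel = np.array([pos[f] for f in feature_ids], dtype=int)
        return self.full()[np.ix_(sel, sel)]
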