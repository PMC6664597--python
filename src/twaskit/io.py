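"""Readers and writers for the plain-text on-disk formats.

All formats are tab-separated text: sumstats (LDSC dialect: SNP, A1, A2, Z,
N), a weight bundle (manifest + one TSV per feature), an LD bundle (SNP table
+ one dense matrix per block), GMT gene sets, and a gene-property table.
Coordinates are 1-based inclusive base pairs throughout.  Writers use a fixed
float format so identical inputs produce byte-identical files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (FeatureWeights, FormatError, LdReference,
                         WeightPanel, validate_sumstats)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_sumstats(path) -> pd.DataFrame:
    """Read and validate a sumstats TSV; see :func:`validate_sumstats`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    out = validate_sumstats(df)
    if out.attrs.get("n_dropped_z"):
        logger.info("load_sumstats: dropped %d rows with non-finite Z",
                    out.attrs["n_dropped_z"])
    return out


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    _write_tsv(sumstats, path)


def write_ld_bundle(ld: LdReference, directory) -> None:
    """SNP table (snps.tsv) plus one dense matrix file per block."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_tsv(ld.snps, d / "snps.tsv")
    for bid, R in ld.blocks.items():
        np.savetxt(d / f"block_{bid}.ld.tsv", R, delimiter="\t",
                   fmt=_FLOAT_FMT)


def load_ld_bundle(directory) -> LdReference:
    d = Path(directory)
    snps = pd.read_csv(d / "snps.tsv", sep="\t")
    blocks = {}
    for bid in snps["BLOCK"].unique():
        path = d / f"block_{int(bid)}.ld.tsv"
        if not path.exists():
            raise FormatError(f"missing LD matrix file {path.name}")
        blocks[int(bid)] = np.atleast_2d(
            np.loadtxt(path, delimiter="\t", ndmin=2))
    return LdReference(snps=snps, blocks=blocks)


def write_weight_bundle(panel: WeightPanel, directory) -> None:
    """Manifest (PANEL, FEATURE_ID, GENE_ID, CHR, P0, P1, CIS_H2, FILE) plus
    one per-feature TSV (SNP, A1, A2, WEIGHT)."""
    d = Path(directory)
    (d / "weights").mkdir(parents=True, exist_ok=True)
    man = panel.manifest()
    files = []
    for f in panel:
        fname = f"weights/{f.feature_id.replace(':', '_')}.wgt.tsv"
        files.append(fname)
        _write_tsv(pd.DataFrame({"SNP": f.snp_ids, "A1": f.a1, "A2": f.a2,
                                 "WEIGHT": f.w}), d / fname)
    man["FILE"] = files
    _write_tsv(man, d / "manifest.tsv")


def load_weight_bundle(directory) -> WeightPanel:
    d = Path(directory)
    man = pd.read_csv(d / "manifest.tsv", sep="\t")
    required = {"PANEL", "FEATURE_ID", "GENE_ID", "CHR", "P0", "P1", "FILE"}
    missing = required - set(man.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    features = []
    for _, row in man.iterrows():
        wt = pd.read_csv(d / row["FILE"], sep="\t")
        features.append(FeatureWeights(
            feature_id=row["FEATURE_ID"], gene_id=row["GENE_ID"],
            panel_id=row["PANEL"], chrom=int(row["CHR"]),
            start=int(row["P0"]), stop=int(row["P1"]),
            snp_ids=wt["SNP"].to_numpy(dtype=object),
            a1=wt["A1"].to_numpy(dtype=object),
            a2=wt["A2"].to_numpy(dtype=object),
            w=wt["WEIGHT"].to_numpy(float),
            cis_h2=float(row.get("CIS_H2", np.nan)),
        ))
    return WeightPanel(features)


def parse_gmt(path) -> dict[str, list[str]]:
    """Standard GMT: set name, description, then >=1 tab-separated genes.

    Duplicate genes within a set are dropped (order-preserving) with a
    warning; an empty gene list is a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g for g in parts[2:]):
                raise FormatError(f"{path}:{ln}: GMT line with no genes")
            name = parts[0]
            genes = [g for g in parts[2:] if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("%s: duplicate gene %s in set %s",
                                   path, g, name)
                seen.setdefault(g)
            sets[name] = list(seen)
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_properties(path) -> pd.DataFrame:
    """Gene-property table: GENE plus one numeric column per stage."""
    df = pd.read_csv(path, sep="\t")
    if "GENE" not in df.columns:
        raise FormatError("property table must have a GENE column")
    return df


def write_properties(props: pd.DataFrame, path) -> None:
    _write_tsv(props, path)


def write_results(df: pd.DataFrame, path) -> None:
    """Generic results-table writer (TWAS, coloc, enrichment, h2 reports)."""
    _write_tsv(df, path)


@dataclass
class RunConfig:
    """Structured configuration for CLI runs (YAML-loadable)."""

    sumstats: str | None = None
    weights: str | None = None
    ld: str | None = None
    gmt: str | None = None
    properties: str | None = None
    out_dir: str = "."
    fwer_alpha: float = 0.05
    fdr_q: float = 0.05
    joint_window_bp: int = 500_000
    region_test_window_kb: float = 10.0
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    coloc_prior_sd: float = 0.15
    prevalence: float | None = None
    sample_prevalence: float | None = None
    jackknife_blocks: int = 200
    threshold_draws: int = 50_000
    seed: int = 0
    extra: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return RunConfig(**kwargs, extra=extra)
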