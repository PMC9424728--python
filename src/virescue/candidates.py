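"""Candidate-SNP screening inside a mapped region and DEG intersection.

The screening conditions mirror map-based candidate identification in a
recessive F2 design: a causal SNP should be heterozygous in the wild-type
(green) pool, homozygous non-reference in the mutant (yellow) pool, and have
a protein-affecting annotation (nonsynonymous, splice site, or in-frame
indel).  Because pooled "genotypes" are really allele frequencies, zygosity
is called from frequency bands rather than hard genotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bsa import RegionCall

logger = logging.getLogger(__name__)

DAMAGING_EFFECTS = frozenset({"nonsynonymous", "splice_site", "inframe_indel"})

EFFECT_CLASSES = DAMAGING_EFFECTS | {
    "synonymous",
    "intergenic",
    "upstream",
    "other",
}

__all__ = [
    "PoolZygosity",
    "GeneModel",
    "ZygosityConfig",
    "call_pool_zygosity",
    "filter_candidate_snps",
    "deg_intersection",
    "promoter_scan",
]


@dataclass(frozen=True)
class ZygosityConfig:
    """Frequency bands for pooled zygosity calls."""

    het_low: float = 0.2
    het_high: float = 0.8
    hom_alt_min: float = 0.9
    min_depth: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.het_low <= self.het_high <= 1):
            raise ValueError("require 0 <= het_low <= het_high <= 1")
        if not (0.5 < self.hom_alt_min <= 1):
            raise ValueError("hom_alt_min must be in (0.5, 1]")
        if self.het_low < 1 - self.hom_alt_min or self.het_high > self.hom_alt_min:
            raise ValueError(
                "het band overlaps the homozygous bands: require "
                "1 - hom_alt_min <= het_low and het_high <= hom_alt_min"
            )


@dataclass(frozen=True)
class PoolZygosity:
    call: str  # hom_ref | het | hom_alt | ambiguous
    f: float
    depth: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("gene start must be <= end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


def call_pool_zygosity(
    f: float, depth: int, config: ZygosityConfig = ZygosityConfig()
) -> PoolZygosity:
    """Call a pool's zygosity from its alt-allele frequency and depth.

    Order of the rules: insufficient depth is always ambiguous; then the
    homozygous bands, then the het band; anything between bands is ambiguous.
    """
    if not (0 <= f <= 1):
        raise ValueError("frequency must be in [0, 1]")
    if depth < config.min_depth:
        call = "ambiguous"
    elif f >= config.hom_alt_min:
        call = "hom_alt"
    elif f <= 1 - config.hom_alt_min:
        call = "hom_ref"
    elif config.het_low <= f <= config.het_high:
        call = "het"
    else:
        call = "ambiguous"
    return PoolZygosity(call, float(f), int(depth))


def _zygosity_column(
    table: pd.DataFrame, tag: str, config: ZygosityConfig
) -> pd.Series:
    depth = table[f"{tag}_ref"] + table[f"{tag}_alt"]
    f = np.where(depth > 0, table[f"{tag}_alt"] / depth.replace(0, 1), 0.0)
    calls = []
    for fi, di in zip(f, depth):
        calls.append(call_pool_zygosity(float(fi), int(di), config).call)
    return pd.Series(calls, index=table.index)


def filter_candidate_snps(
    variants: pd.DataFrame,
    region: RegionCall,
    config: ZygosityConfig = ZygosityConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Apply the four screening conditions; return survivors and drop counts.

    Conditions: (i) inside the mapped region, (ii) green pool heterozygous,
    (iii) yellow pool homozygous for the non-reference allele, (iv) effect in
    ``{nonsynonymous, splice_site, inframe_indel}``.  Each criterion's drop
    count is tallied independently, so one variant can appear in several
    counts.  The retained set is independent of input order and shrinks (or
    stays equal) as criteria are added.
    """
    required = {"chrom", "pos", "g_ref", "g_alt", "y_ref", "y_alt", "effect"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    v = variants
    in_region = (v["chrom"] == region.chrom) & v["pos"].between(
        region.start, region.end
    )
    g_het = _zygosity_column(v, "g", config) == "het"
    y_hom_alt = _zygosity_column(v, "y", config) == "hom_alt"
    damaging = v["effect"].isin(DAMAGING_EFFECTS)
    keep = in_region & g_het & y_hom_alt & damaging
    report = {
        "n_input": int(len(v)),
        "drop_outside_region": int((~in_region).sum()),
        "drop_g_not_het": int((~g_het).sum()),
        "drop_y_not_hom_alt": int((~y_hom_alt).sum()),
        "drop_effect": int((~damaging).sum()),
        "n_retained": int(keep.sum()),
    }
    out = v.loc[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return out, report


def deg_intersection(
    candidate_genes,
    degs: pd.DataFrame,
    fc_min: float = 1.5,
    q_max: float = 0.05,
) -> list[str]:
    """Candidate genes that are differentially expressed.

    A gene qualifies when its DEG record has ``q_value < q_max`` (strict) and
    ``fold_change > fc_min`` (strict) in either direction; duplicated gene ids
    in the DEG table keep the smallest q with a warning.
    """
    required = {"gene_id", "fold_change", "q_value"}
    missing = required - set(degs.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    if degs["gene_id"].duplicated().any():
        logger.warning("duplicate gene ids in DEG table; keeping smallest q")
        degs = degs.sort_values("q_value", kind="mergesort").drop_duplicates(
            "gene_id", keep="first"
        )
    passing = degs.loc[
        (degs["q_value"] < q_max) & (degs["fold_change"] > fc_min), "gene_id"
    ]
    return sorted(set(candidate_genes) & set(passing))


def promoter_scan(
    variants: pd.DataFrame,
    gene: GeneModel,
    upstream_bp: int = 2000,
) -> pd.DataFrame:
    """Variants in the gene's upstream (promoter-side) window.

    For a + strand gene the window is ``[start - upstream_bp, start - 1]``;
    for a - strand gene it is ``[end + 1, end + upstream_bp]`` (both 1-based
    inclusive).  Intended to be run on the screening-condition-passing set to
    check whether differential expression could be promoter-driven.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if gene.strand == "+":
        lo, hi = gene.start - upstream_bp, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + upstream_bp
    mask = (variants["chrom"] == gene.chrom) & variants["pos"].between(lo, hi)
    return variants.loc[mask].reset_index(drop=True)
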