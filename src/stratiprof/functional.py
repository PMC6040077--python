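"""Glycoside-hydrolase rate statistics and z-scored category matrices.

EQ is the number of GH genes per 1000 genes analyzed for a taxon/sample
group; NORM weights EQ by the taxon's 16S-based community share, giving
its community-level contribution.  Functional category matrices are
row-standardized (z-scores) for heatmap display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default photic-zone sample groups (depth in m -> group)
DEFAULT_SAMPLE_GROUPS: dict[str, tuple[float, ...]] = {
    "UP": (15.0, 30.0),
    "DCM": (45.0, 60.0),
    "LP": (75.0, 90.0),
    "MIX": (20.0, 80.0),
}


def group_of_depth(depth_m: float, season: str = "stratified",
                   groups: dict | None = None) -> str:
    groups = groups or DEFAULT_SAMPLE_GROUPS
    if season == "mixed":
        return "MIX"
    for name, depths in groups.items():
        if name != "MIX" and depth_m in depths:
            return name
    raise ValueError(f"depth {depth_m} not in any sample group")


def gh_rate(gh_gene_count: float, n_genes: int) -> float:
    """EQ: GH genes per 1000 genes analyzed."""
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    return 1000.0 * gh_gene_count / n_genes


def gh_norm(eq: float, taxon_16s_percent: float, mode: str = "multiply") -> float:
    """NORM: EQ weighted by the taxon's 16S community share (percent).

    ``mode='multiply'`` (default) treats NORM as the community-level GH
    contribution; ``mode='divide'`` is exposed for the alternative
    reading of per-capita normalization.
    """
    if not 0.0 <= taxon_16s_percent <= 100.0:
        raise ValueError("taxon_16s_percent must be in [0, 100]")
    if mode == "multiply":
        return eq * taxon_16s_percent / 100.0
    if mode == "divide":
        if taxon_16s_percent == 0:
            raise ValueError("cannot divide by a 0% community share")
        return eq / (taxon_16s_percent / 100.0)
    raise ValueError("mode must be 'multiply' or 'divide'")


@dataclass(frozen=True)
class GHProfile:
    taxon: str
    sample_group: str
    gh_count: int
    n_genes_analyzed: int
    eq: float
    norm: float


def gh_family_matrix(
    gene_table: pd.DataFrame,
    known_taxa: list[str] | None = None,
    min_contig_length: int = 5_000,
) -> pd.DataFrame:
    """GH counts cross-tabulated by taxon x sample group x family.

    ``gene_table`` columns: contig_id, contig_length, taxon, sample_group,
    role, family.  Genes on contigs shorter than ``min_contig_length`` are
    excluded; taxa outside ``known_taxa`` (when given) are bucketed as
    "other" with a warning.
    """
    need = {"contig_id", "contig_length", "taxon", "sample_group", "role", "family"}
    missing = need - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df = gene_table[
        (gene_table["role"] == "GH")
        & (gene_table["contig_length"] >= min_contig_length)
    ].copy()
    if known_taxa is not None:
        unknown = set(df["taxon"]) - set(known_taxa)
        if unknown:
            warnings.warn(f"unknown taxa bucketed as 'other': {sorted(unknown)}")
            df.loc[df["taxon"].isin(unknown), "taxon"] = "other"
    if df.empty:
        return pd.DataFrame()
    return (
        df.groupby(["taxon", "sample_group", "family"])
        .size()
        .unstack("family", fill_value=0)
    )


def gh_profiles(
    gene_table: pd.DataFrame,
    taxon_16s_percent: pd.DataFrame,
    known_taxa: list[str] | None = None,
    min_contig_length: int = 5_000,
    norm_mode: str = "multiply",
) -> list[GHProfile]:
    """EQ and NORM per taxon and sample group.

    ``taxon_16s_percent``: taxa x sample groups, percent of 16S fragments.
    n_genes_analyzed counts every annotated gene of the taxon's contigs
    (>= min length) in the group; EQ counts role == "GH" among them.
    """
    df = gene_table[gene_table["contig_length"] >= min_contig_length]
    out = []
    for (taxon, group), sub in df.groupby(["taxon", "sample_group"]):
        n_genes = len(sub)
        gh = int((sub["role"] == "GH").sum())
        eq = gh_rate(gh, n_genes)
        pct = 0.0
        if taxon in taxon_16s_percent.index and group in taxon_16s_percent.columns:
            pct = float(taxon_16s_percent.loc[taxon, group])
        out.append(GHProfile(taxon, group, gh, n_genes, eq, gh_norm(eq, pct, norm_mode)))
    return out


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize a category matrix: (x - mean) / sd with ddof=1.

    Zero-variance rows become NA (flagged with a warning).  Requires at
    least two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-scoring needs >= 2 columns")
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    flat = sds == 0
    if flat.any():
        warnings.warn(f"zero-variance rows set to NA: {list(matrix.index[flat])}")
    z = matrix.sub(means, axis=0).div(sds.where(~flat), axis=0)
    return z
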