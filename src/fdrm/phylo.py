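"""Transcriptome age/divergence indices and modification-by-stratum profiles.

TAI/TDI are expression-weighted mean strata per stage, computed on linear
(TMM-normalized CPM, replicate-averaged) expression. The relative value
(RV) rescales any per-stage series to [0, 1].
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from fdrm.core_io.models import GeneModel
from fdrm.errors import FdrmError


def _weighted_stratum_index(expression: pd.DataFrame, strata: pd.Series) -> pd.Series:
    strata = strata.dropna()
    common = expression.index.intersection(strata.index)
    if common.empty:
        raise FdrmError("no genes shared between expression matrix and strata map")
    expr = expression.loc[common]
    ps = strata.loc[common].astype(float)
    totals = expr.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise FdrmError(f"stages with all-zero expression: {bad}")
    return expr.mul(ps, axis=0).sum(axis=0) / totals


def compute_tai(expression: pd.DataFrame, phylostrata: pd.Series) -> pd.Series:
    """Expression-weighted mean phylostratum per stage (gene x stage input)."""
    out = _weighted_stratum_index(expression, phylostrata)
    out.name = "TAI"
    return out


def compute_tdi(expression: pd.DataFrame, divergence_strata: pd.Series) -> pd.Series:
    """Expression-weighted mean divergence stratum per stage."""
    out = _weighted_stratum_index(expression, divergence_strata)
    out.name = "TDI"
    return out


def relative_value(series: pd.Series) -> pd.Series:
    """Min-max rescale to [0, 1]; constant series map to all zeros."""
    lo, hi = series.min(), series.max()
    if hi == lo:
        return pd.Series(0.0, index=series.index, name=series.name)
    return (series - lo) / (hi - lo)


def profile_table(
    tai: pd.Series,
    tdi: pd.Series,
    as_intensity: pd.Series,
    re_intensity: pd.Series,
) -> pd.DataFrame:
    """Stage x category table of raw values and their RV normalizations."""
    df = pd.DataFrame({"TAI": tai, "TDI": tdi, "AS": as_intensity, "RE": re_intensity})
    for col in list(df.columns):
        df[f"RV_{col}"] = relative_value(df[col])
    return df


def modification_by_phylostratum(
    as_genes: set[str],
    re_genes: set[str],
    gene_models: list[GeneModel],
) -> pd.DataFrame:
    """Per-phylostratum enrichment of modified genes over the genome background.

    ratio = (modified genes in PS / all modified genes)
          / (genes in PS / all genes); NaN for empty strata.
    """
    ps = {m.gene_id: m.phylostratum for m in gene_models if m.phylostratum is not None}
    if not ps:
        raise FdrmError("no phylostratum labels on the gene models")
    strata = sorted(set(ps.values()))
    n_genes = len(ps)
    rows = []
    for stratum in strata:
        genes_in_ps = {g for g, p in ps.items() if p == stratum}
        bg_frac = len(genes_in_ps) / n_genes
        row = {"phylostratum": stratum, "n_genes": len(genes_in_ps)}
        for label, mod in (("AS", as_genes), ("RE", re_genes)):
            mod = {g for g in mod if g in ps}
            if not mod or bg_frac == 0:
                row[label] = np.nan
            else:
                row[label] = (len(mod & genes_in_ps) / len(mod)) / bg_frac
        rows.append(row)
    return pd.DataFrame(rows).set_index("phylostratum")
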