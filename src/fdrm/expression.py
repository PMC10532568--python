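"""Expression filtering, normalization, differential expression, clustering.

Counts come in as a gene x sample integer matrix. Between-sample scaling
uses the trimmed mean of M-values (TMM): 30% trim on M, 5% trim on A,
reference sample chosen by the upper-quartile rule, precision weights from
the delta method. Differential expression uses a negative-binomial exact
test with a single common dispersion estimated by method of moments —
the simplest published variant of the count-based exact test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from fdrm.core_io.config import ExpressionConfig
from fdrm.core_io.design import StageDesign
from fdrm.errors import DesignError, FdrmError

# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame, tmm_factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; optionally on TMM-corrected effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise FdrmError("sample with zero total counts")
    if tmm_factors is not None:
        lib = lib * tmm_factors
    return counts / lib * 1e6


def _rank(values: np.ndarray) -> np.ndarray:
    """1-based average ranks (matches R's rank())."""
    return stats.rankdata(values, method="average")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference sample."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method asymptotic variance of M
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rm, ra = _rank(m), _rank(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalize(counts: pd.DataFrame) -> pd.Series:
    """TMM scaling factor per sample; the reference sample gets factor 1."""
    if counts.shape[1] < 2:
        raise FdrmError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise FdrmError(f"samples with zero library size: {zero}")
    nonzero = counts.loc[counts.sum(axis=1) > 0]
    scaled = nonzero / lib
    uq = scaled.apply(lambda col: np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = nonzero[ref_sample].to_numpy()
    factors = {}
    for sample in counts.columns:
        if sample == ref_sample:
            factors[sample] = 1.0
        else:
            factors[sample] = _tmm_pair(
                nonzero[sample].to_numpy(), ref, lib[sample], lib[ref_sample]
            )
    return pd.Series(factors, name="tmm_factor")


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame
    design: StageDesign
    tmm_factors: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [s for s in self.design.samples if s not in self.counts.columns]
        if missing:
            raise DesignError(f"count matrix missing samples {missing}")
        if self.tmm_factors is None:
            self.tmm_factors = tmm_normalize(self.counts)

    @property
    def cpm_raw(self) -> pd.DataFrame:
        return cpm(self.counts)

    @property
    def cpm_tmm(self) -> pd.DataFrame:
        return cpm(self.counts, self.tmm_factors)


# ---------------------------------------------------------------------------
# expressed-gene filter and relative expression
# ---------------------------------------------------------------------------


def filter_expressed(
    cpm_matrix: pd.DataFrame,
    design: StageDesign,
    threshold: float = 1.0,
    min_reps: int = 2,
) -> tuple[list[str], dict[str, list[str]]]:
    """Genes with CPM > threshold in >= min_reps replicates of some stage.

    Returns (expressed genes, per-stage expressed gene lists).
    """
    per_stage: dict[str, list[str]] = {}
    expressed: set[str] = set()
    for stage in design.stages:
        reps = design.replicates[stage]
        passing = (cpm_matrix[reps] > threshold).sum(axis=1) >= min_reps
        genes = list(cpm_matrix.index[passing])
        per_stage[stage] = genes
        expressed.update(genes)
    return sorted(expressed), per_stage


def relative_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Per-gene min-max scaling to [0, 1]; constant genes map to all zeros."""
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    span = hi - lo
    re = values.sub(lo, axis=0).div(span.replace(0.0, np.nan), axis=0)
    return re.fillna(0.0)


def log2_tmm(expr: ExpressionMatrix, pseudo_count: float = 1.0) -> pd.DataFrame:
    return np.log2(expr.cpm_tmm + pseudo_count)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


@dataclass
class DifferentialExpressionResult:
    gene: str
    log2fc: float
    pvalue: float
    adj_pvalue: float = float("nan")
    is_deg: bool = False


def estimate_common_dispersion(norm_counts: pd.DataFrame, groups: list[list[str]]) -> float:
    """Method-of-moments common NB dispersion on normalized counts.

    Per gene, pooled within-group moments give phi = (s2 - mu) / mu^2;
    the common value is the median over genes with positive mean.
    """
    phis = []
    for _, row in norm_counts.iterrows():
        num = den = 0.0
        for g in groups:
            vals = row[g].to_numpy(dtype=float)
            if len(vals) < 2:
                continue
            mu = vals.mean()
            if mu <= 0:
                continue
            s2 = vals.var(ddof=1)
            num += s2 - mu
            den += mu ** 2
        if den > 0:
            phis.append(max(num / den, 0.0))
    if not phis:
        return 0.0
    return float(np.median(phis))


def _nb_sum_pmf(k: np.ndarray, mean: float, phi: float, n_reps: int) -> np.ndarray:
    """pmf of a sum of n_reps iid NB(mean, phi) variables (Poisson when phi=0)."""
    total_mean = mean * n_reps
    if phi <= 0:
        return stats.poisson.pmf(k, total_mean)
    size = n_reps / phi
    p = size / (size + total_mean)
    return stats.nbinom.pmf(k, size, p)


def nb_exact_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact test on group sums under a shared NB mean.

    Conditional on the total, sums all splits whose probability does not
    exceed that of the observed split.
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    k = np.arange(total + 1)
    pa = _nb_sum_pmf(k, mu, phi, n_a)
    pb = _nb_sum_pmf(total - k, mu, phi, n_b)
    probs = pa * pb
    denom = probs.sum()
    if denom <= 0:
        return 1.0
    p_obs = probs[sum_a]
    pval = probs[probs <= p_obs * (1 + 1e-10)].sum() / denom
    return float(min(pval, 1.0))


def differential_expression(
    expr: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    config: ExpressionConfig | None = None,
) -> list[DifferentialExpressionResult]:
    """Exact-test DE between two stages; DEG iff |log2FC| > 2 and BH p < 0.05."""
    config = config or ExpressionConfig()
    design = expr.design
    design.check_stage(stage_a)
    design.check_stage(stage_b)
    reps_a, reps_b = design.replicates[stage_a], design.replicates[stage_b]
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise DesignError("need >= 2 replicates per stage")
    eff_lib = expr.counts.sum(axis=0).astype(float) * expr.tmm_factors
    common = stats.gmean(eff_lib[reps_a + reps_b])
    # pseudo-counts on a common library scale so group sums are comparable
    pseudo = expr.counts[reps_a + reps_b] / eff_lib[reps_a + reps_b] * common
    tested = pseudo.loc[pseudo.sum(axis=1) > 0]
    phi = estimate_common_dispersion(tested, [reps_a, reps_b])
    results = []
    for gene, row in tested.iterrows():
        sa = int(round(row[reps_a].sum()))
        sb = int(round(row[reps_b].sum()))
        mu_a = row[reps_a].mean()
        mu_b = row[reps_b].mean()
        lfc = math.log2((mu_b + 0.5) / (mu_a + 0.5))
        pval = nb_exact_pvalue(sa, sb, len(reps_a), len(reps_b), phi)
        results.append(DifferentialExpressionResult(gene=str(gene), log2fc=lfc, pvalue=pval))
    if results:
        adj = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.adj_pvalue = float(q)
            r.is_deg = abs(r.log2fc) > config.lfc_threshold and r.adj_pvalue < config.alpha
    return results


def de_table(results: list[DifferentialExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": r.gene, "log2fc": r.log2fc, "pvalue": r.pvalue,
             "adj_pvalue": r.adj_pvalue, "is_deg": r.is_deg}
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------


def stage_mean(values: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {stage: values[design.replicates[stage]].mean(axis=1) for stage in design.stages}
    )


def cluster_profiles(re_matrix: pd.DataFrame, design: StageDesign, k: int = 6) -> pd.Series:
    """Ward/Euclidean hierarchical clustering of per-stage mean RE, cut at k.

    Input rows are sorted lexicographically by gene id so the result is
    independent of input order. Cluster labels are renumbered 1..k in
    order of first appearance.
    """
    if k > re_matrix.shape[0]:
        raise FdrmError(f"k={k} exceeds number of genes {re_matrix.shape[0]}")
    profile = stage_mean(re_matrix, design).sort_index(key=lambda idx: idx.astype(str))
    z = linkage(profile.to_numpy(), method="ward", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels.append(remap[lab])
    return pd.Series(labels, index=profile.index, name="cluster")
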