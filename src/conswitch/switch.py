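"""Switch detection and classification.

The central question: does gene expression change abruptly at a single
postnatal day?  The tools here are (i) sample-sample Pearson
correlation, (ii) PCA over the day time course with days as
observations and genes as variables, (iii) pre/post window fold
changes, (iv) a native NB likelihood-ratio differential test, and
(v) class labels: switch_on (log2 FC >= 1, FDR < 5%), switch_off
(log2 FC <= -1, FDR < 5%), constant (|log2 FC| < 0.01), other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import nb_lrt_test  # re-exported; shared with the ATAC stage
from .expression import ExpressionMatrix
from .io import CountMatrix, GeneAnnotation

__all__ = [
    "PCAResult", "sample_correlations", "pca_timecourse", "fold_changes",
    "nb_lrt_test", "nb_lrt_by_day_window", "classify",
    "normalized_timecourse", "chromosome_distribution_test",
    "switch_fraction_percent",
    "PRE_DAYS", "POST_DAYS",
]

PRE_DAYS = tuple(range(0, 6))    # P0..P5; the switch day itself (P6)
POST_DAYS = tuple(range(7, 13))  # P7..P12; belongs to neither window

FC_THRESHOLD = 1.0
CONSTANT_THRESHOLD = 0.01
FDR_THRESHOLD = 0.05


@dataclass
class PCAResult:
    """Day scores and variance fractions of the expression time course."""

    component_scores: np.ndarray   # days x components
    variance_fraction: np.ndarray  # per component, sums to 1
    loadings: np.ndarray           # components x genes
    days: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Centered data matrix from scores x loadings."""
        return self.component_scores @ self.loadings


def sample_correlations(em: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between all column pairs of a log matrix."""
    values = em.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = em.columns[sd == 0][0]
        raise ValueError(f"zero-variance sample: {bad!r}")
    corr = np.corrcoef(values.T)
    return pd.DataFrame(corr, index=em.columns, columns=em.columns)


def pca_timecourse(em: ExpressionMatrix) -> PCAResult:
    """PCA with days as observations and genes as variables.

    Each gene is centered across days, then SVD.  Sign convention: each
    component is flipped if needed so its score at the earliest day
    is <= 0 (a switch-on-dominated component therefore rises).
    """
    em._require_stage("log2", "day_mean")
    X = em.values.T  # days x genes
    if X.shape[0] < 3:
        raise ValueError("need at least 3 days for a time-course PCA")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * s[None, :]
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    flip = np.where(scores[0, :] > 0, -1.0, 1.0)
    scores = scores * flip[None, :]
    Vt = Vt * flip[:, None]
    return PCAResult(scores, frac, Vt, np.asarray(em.columns))


def fold_changes(em: ExpressionMatrix,
                 pre_days=PRE_DAYS, post_days=POST_DAYS) -> pd.Series:
    """Per-gene log2 fold change: mean log2 expression over the post
    window minus the pre window (the switch day is in neither)."""
    em._require_stage("log2")
    pre_days, post_days = set(pre_days), set(post_days)
    if not pre_days or not post_days:
        raise ValueError("both day windows must be non-empty")
    if pre_days & post_days:
        raise ValueError(f"overlapping windows: {sorted(pre_days & post_days)}")
    days = np.asarray(em.columns)
    pre_cols = np.isin(days, list(pre_days))
    post_cols = np.isin(days, list(post_days))
    if not pre_cols.any() or not post_cols.any():
        raise ValueError("windows select no days present in the matrix")
    fc = em.values[:, post_cols].mean(axis=1) - em.values[:, pre_cols].mean(axis=1)
    return pd.Series(fc, index=em.gene_ids, name="log2_fc")


def nb_lrt_by_day_window(cm: CountMatrix, pre_days=PRE_DAYS,
                         post_days=POST_DAYS,
                         gene_ids=None) -> pd.DataFrame:
    """NB LRT on raw counts, pre vs post samples (switch-day samples
    excluded); optionally restricted to a gene subset."""
    counts = cm.counts
    gidx = cm.gene_ids
    if gene_ids is not None:
        keep = pd.Index(cm.gene_ids).get_indexer(gene_ids)
        if np.any(keep < 0):
            raise KeyError("gene ids missing from the count matrix")
        counts = counts[keep]
        gidx = cm.gene_ids[keep]
    use = np.isin(cm.day, list(pre_days)) | np.isin(cm.day, list(post_days))
    labels = np.where(np.isin(cm.day[use], list(pre_days)), "pre", "post")
    res = nb_lrt_test(counts[:, use], labels)
    return pd.DataFrame({"lrt_stat": res["stat"], "p_value": res["p_value"],
                         "fdr": res["fdr"], "all_zero": res["all_zero"]},
                        index=gidx)


def classify(log2_fc: pd.Series, fdr: pd.Series) -> pd.DataFrame:
    """SwitchTable: class labels from fold change and FDR.

    switch_on: log2_fc >= 1 and fdr < 0.05; switch_off mirrored;
    constant: |log2_fc| < 0.01; everything else: other.  Also flags the
    |log2_fc| > 2 subset used for the fine time-course plots.
    """
    log2_fc, fdr = log2_fc.align(fdr, join="inner")
    cls = np.full(len(log2_fc), "other", dtype=object)
    on = (log2_fc.values >= FC_THRESHOLD) & (fdr.values < FDR_THRESHOLD)
    off = (log2_fc.values <= -FC_THRESHOLD) & (fdr.values < FDR_THRESHOLD)
    const = np.abs(log2_fc.values) < CONSTANT_THRESHOLD
    cls[const] = "constant"
    cls[on] = "switch_on"
    cls[off] = "switch_off"
    return pd.DataFrame({
        "log2_fc": log2_fc.values,
        "fdr": fdr.values,
        "class": cls,
        "strong": np.abs(log2_fc.values) > 2.0,
    }, index=log2_fc.index)


def normalized_timecourse(em: ExpressionMatrix, gene_set,
                          reference: str = "pre",
                          pre_days=PRE_DAYS, post_days=POST_DAYS) -> pd.Series:
    """Mean time course of a gene set, each gene shifted so its
    reference-window mean is zero (log2 space)."""
    em._require_stage("log2")
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    idx = pd.Index(em.gene_ids).get_indexer(gene_set)
    if np.any(idx < 0):
        missing = [g for g, i in zip(gene_set, idx) if i < 0]
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    values = em.values[idx]
    days = np.asarray(em.columns)
    ref_days = pre_days if reference == "pre" else post_days
    ref_cols = np.isin(days, list(ref_days))
    shifted = values - values[:, ref_cols].mean(axis=1, keepdims=True)
    return pd.Series(shifted.mean(axis=0), index=days, name="normalized_log2")


def chromosome_distribution_test(switch_genes, all_genes,
                                 annotation: GeneAnnotation,
                                 min_expected: float = 5.0,
                                 ) -> tuple[float, float]:
    """Chi-square test of whether switch genes are distributed across
    chromosomes like all expressed genes.

    Chromosomes with expected switch-gene count below ``min_expected``
    are pooled into one category.
    """
    switch_genes = list(switch_genes)
    all_genes = list(all_genes)
    if not switch_genes:
        raise ValueError("empty switch gene set")
    chrom = annotation.table["chromosome"]
    all_counts = chrom.loc[all_genes].value_counts()
    sw_counts = chrom.loc[switch_genes].value_counts()
    frac = all_counts / all_counts.sum()
    expected = frac * len(switch_genes)
    observed = sw_counts.reindex(expected.index, fill_value=0)

    small = expected < min_expected
    if small.any():
        pooled_exp = expected[small].sum()
        pooled_obs = observed[small].sum()
        expected = expected[~small]
        observed = observed[~small]
        if pooled_exp > 0:
            expected = pd.concat([expected, pd.Series({"pooled": pooled_exp})])
            observed = pd.concat([observed, pd.Series({"pooled": pooled_obs})])
    if len(expected) < 2:
        raise ValueError("fewer than 2 chromosome categories after pooling")
    stat, p = stats.chisquare(observed.to_numpy(dtype=float),
                              expected.to_numpy(dtype=float))
    return float(stat), float(p)


def switch_fraction_percent(n_on: int, n_off: int, n_expressed: int) -> float:
    """Percentage of expressed genes that switched."""
    if n_expressed <= 0:
        raise ValueError("n_expressed must be positive")
    return 100.0 * (n_on + n_off) / n_expressed
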