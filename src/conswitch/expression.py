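"""Expression preprocessing: RPKM, per-gene outlier masking, day means,
noise-threshold selection by skewness, and log2 transform with a
jittered pseudocount for zeros.

Stages are order-enforced: rpkm -> outlier_removed -> day_mean ->
thresholded -> log2.  Each operation checks that its input is at the
stage it expects, so e.g. log-transforming before thresholding raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

STAGES = ("rpkm", "outlier_removed", "day_mean", "thresholded", "log2")

DEFAULT_THRESHOLD_GRID = np.round(np.arange(0.0, 5.0 + 1e-9, 0.005), 6)
#: skewness-optimal threshold found on the original cone time-course data;
#: a reasonable default when no threshold scan is run on the data at hand
REFERENCE_THRESHOLD_RPKM = 1.645


@dataclass
class ExpressionMatrix:
    """Gene x column expression values at a tagged pipeline stage.

    Columns are samples up to the outlier_removed stage and postnatal
    days from day_mean on.  Missing values (masked outliers) are NaN.
    """

    gene_ids: np.ndarray
    columns: np.ndarray      # sample ids, or day labels from day_mean on
    values: np.ndarray       # float, NaN = masked
    stage: str
    day: np.ndarray | None = None        # per-column day (sample stages)
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.columns = np.asarray(self.columns)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError("values shape does not match labels")

    def _require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise ValueError(
                f"operation requires stage in {allowed}, got {self.stage!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.columns)


@dataclass
class ThresholdScan:
    """Result of the skewness scan over candidate expression thresholds."""

    thresholds: np.ndarray
    skewness: np.ndarray          # NaN where the candidate was skipped
    chosen_threshold: float
    n_retained: np.ndarray = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "skewness": self.skewness,
                             "n_retained": self.n_retained})


def rpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million library reads.

    value = count * 1e9 / (gene_length_bp * library_size), with library
    size the column sum of counts.
    """
    lib = cm.library_sizes().astype(float)
    zero = lib == 0
    if zero.any():
        raise ValueError(
            f"zero library size for sample {cm.sample_ids[zero][0]!r}")
    values = cm.counts * 1e9 / (cm.gene_length_bp[:, None] * lib[None, :])
    return ExpressionMatrix(cm.gene_ids, cm.sample_ids, values, "rpkm",
                            day=cm.day, replicate=cm.replicate)


def remove_gene_outlier(em: ExpressionMatrix) -> ExpressionMatrix:
    """Mask each gene's single highest value across all samples.

    Ties are broken toward the first sample in column order.  Masking
    (rather than dropping the gene) keeps the full day design; the day
    containing the masked value averages over the remaining replicates.
    """
    em._require_stage("rpkm")
    if em.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to mask an outlier")
    values = em.values.copy()
    top = np.argmax(values, axis=1)  # first max on ties
    values[np.arange(values.shape[0]), top] = np.nan
    return ExpressionMatrix(em.gene_ids, em.columns, values,
                            "outlier_removed", day=em.day,
                            replicate=em.replicate)


def day_means(em: ExpressionMatrix) -> ExpressionMatrix:
    """Mean over non-missing replicates per gene per day."""
    em._require_stage("outlier_removed", "rpkm")
    if em.day is None:
        raise ValueError("day labels required")
    days = np.unique(em.day)
    out = np.empty((em.values.shape[0], len(days)))
    for j, d in enumerate(days):
        cols = em.values[:, em.day == d]
        n_ok = np.sum(~np.isnan(cols), axis=1)
        if np.any(n_ok == 0):
            g = em.gene_ids[np.argmax(n_ok == 0)]
            raise ValueError(f"gene {g!r} has no values on day {d}")
        out[:, j] = np.nanmean(cols, axis=1)
    return ExpressionMatrix(em.gene_ids, days, out, "day_mean")


def _sample_skewness(x: np.ndarray) -> float:
    """Biased moment estimator g1 = m3 / m2^(3/2)."""
    return float(stats.skew(x, bias=True))


def select_threshold(em: ExpressionMatrix,
                     grid: np.ndarray = DEFAULT_THRESHOLD_GRID,
                     min_genes: int = 10) -> ThresholdScan:
    """Choose the expression threshold whose retained-gene log2 mean
    expression is least skewed.

    For each candidate t, genes whose *maximum* day-mean is >= t are
    retained (a gene counts as expressed if it ever exceeds t, so genes
    expressed only before or only after a switch are kept).  The sample
    skewness g1 of log2(mean day-mean expression) over retained genes is
    computed; the chosen threshold minimizes |g1|, ties to the smallest t.
    Candidates retaining fewer than ``min_genes`` genes are skipped.
    """
    em._require_stage("day_mean")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    gene_max = em.values.max(axis=1)
    gene_mean = em.values.mean(axis=1)

    # suffix cumulants over genes sorted by max day-mean give every
    # candidate's skewness in one pass (all-zero genes never enter the
    # skew, which is over log2 of positive means)
    order = np.argsort(gene_max, kind="stable")
    gmax_sorted = gene_max[order]
    pos = gene_mean[order] > 0
    x = np.log2(gene_mean[order][pos])
    gmax_pos = gmax_sorted[pos]
    s1 = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    s2 = np.concatenate([np.cumsum((x ** 2)[::-1])[::-1], [0.0]])
    s3 = np.concatenate([np.cumsum((x ** 3)[::-1])[::-1], [0.0]])

    first = np.searchsorted(gmax_pos, grid, side="left")
    n = (len(x) - first).astype(float)
    n_kept = len(gmax_sorted) - np.searchsorted(gmax_sorted, grid, "left")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1[first] / n
        m2 = s2[first] / n - mean ** 2
        m3 = s3[first] / n - 3 * mean * s2[first] / n + 2 * mean ** 3
        skews = m3 / m2 ** 1.5
    skews[(n < min_genes) | (m2 <= 0)] = np.nan
    if np.all(np.isnan(skews)):
        raise ValueError("no candidate threshold retained enough genes")
    best = np.nanargmin(np.abs(skews))
    return ThresholdScan(grid, skews, float(grid[best]),
                         n_kept.astype(int))


def apply_threshold(em: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep genes whose maximum day-mean reaches the threshold."""
    em._require_stage("day_mean")
    keep = em.values.max(axis=1) >= threshold
    return ExpressionMatrix(em.gene_ids[keep], em.columns,
                            em.values[keep], "thresholded")


def log2_with_jittered_pseudocount(em: ExpressionMatrix,
                                   seed: int) -> ExpressionMatrix:
    """log2-transform, replacing zeros by the global minimum nonzero
    value plus a random integer 1..10 divided by 1e6 (drawn per zero
    cell from the seeded generator) so the result is finite everywhere.
    """
    em._require_stage("thresholded")
    values = em.values.copy()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero matrix cannot be log-transformed")
    zeros = values == 0
    if zeros.any():
        rng = np.random.default_rng(seed)
        jitter = rng.integers(1, 11, size=int(zeros.sum())) / 1e6
        values[zeros] = nonzero.min() + jitter
    return ExpressionMatrix(em.gene_ids, em.columns, np.log2(values), "log2")


def auto_threshold_grid(em: ExpressionMatrix, step: float = 0.005,
                        quantile: float = 95.0) -> np.ndarray:
    """Candidate grid from 0 to the given percentile of per-gene maximum
    day-mean expression.

    The RPKM identity (sum of rpkm * length = 1e9 per sample) pins the
    overall expression scale to the size of the gene panel, so a fixed
    upper bound cannot bracket the abundance valley for every data set;
    this grid adapts to the observed scale.
    """
    upper = max(5.0, float(np.percentile(em.values.max(axis=1), quantile)))
    return np.round(np.arange(0.0, upper + step, step), 6)


def prepare(cm: CountMatrix, threshold: float | str = "auto",
            seed: int = 0,
            grid: np.ndarray | None = None,
            ) -> tuple[ExpressionMatrix, ThresholdScan | None]:
    """Full preprocessing chain; returns the log2 day-mean matrix and,
    when threshold='auto', the threshold scan."""
    em = day_means(remove_gene_outlier(rpkm(cm)))
    scan = None
    if threshold == "auto":
        if grid is None:
            grid = auto_threshold_grid(em)
        scan = select_threshold(em, grid=grid)
        threshold = scan.chosen_threshold
    em = apply_threshold(em, float(threshold))
    return log2_with_jittered_pseudocount(em, seed), scan
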