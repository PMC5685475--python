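"""Chromatin-accessibility change analysis.

Peaks (regions of open chromatin) carry per-sample read counts at
several timepoints.  Changes between two timepoints are summarized by
log2 fold change on mean counts (+1 to avoid -inf) with significance
from the NB LRT on the raw counts; gained / lost regions require
|log2 FC| > 1 at FDR < 0.01.  Peaks are then stratified by distance to
the nearest TSS, by width, and by predicted CTCF-site content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg, nb_lrt_test
from .io import GeneAnnotation, GenomicInterval
from .pwm import DEFAULT_CUTOFF, PWMModel, count_hits

ATAC_FDR = 0.01
ATAC_FC = 1.0
DEFAULT_TOP_PEAKS_REMOVED = 10


def peak_table(intervals: list[GenomicInterval]) -> pd.DataFrame:
    """Base peak table (chromosome, start, end, width) from intervals."""
    return pd.DataFrame({
        "chromosome": [iv.chromosome for iv in intervals],
        "start_bp": [iv.start_bp for iv in intervals],
        "end_bp": [iv.end_bp for iv in intervals],
        "name": [iv.name for iv in intervals],
        "width_bp": [iv.width for iv in intervals],
    })


def remove_top_peaks(peaks: pd.DataFrame, counts: np.ndarray,
                     k: int = DEFAULT_TOP_PEAKS_REMOVED,
                     ) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop the k peaks with the highest total counts (outliers).

    Ties are broken by genomic order (chromosome, start), so the
    surviving set does not depend on input row order.
    """
    if k >= len(peaks):
        raise ValueError(f"k = {k} >= number of peaks {len(peaks)}")
    if k == 0:
        return peaks, counts
    totals = counts.sum(axis=1)
    order = np.lexsort((
        peaks["start_bp"].to_numpy(),
        peaks["chromosome"].to_numpy(),
        -totals,
    ))
    drop = np.zeros(len(peaks), dtype=bool)
    drop[order[:k]] = True
    return peaks[~drop].reset_index(drop=True), counts[~drop]


def peak_change(peaks: pd.DataFrame, counts: np.ndarray,
                day: np.ndarray, timepoint_a: int, timepoint_b: int,
                ) -> pd.DataFrame:
    """log2 FC, p, FDR and gained/lost/stable class for one comparison.

    log2_fc = log2(mean_b + 1) - log2(mean_a + 1) on per-timepoint mean
    counts; p/FDR from the NB LRT on the raw replicate counts.  Peaks
    with zero counts everywhere are stable by convention and flagged.
    """
    day = np.asarray(day)
    in_a = day == timepoint_a
    in_b = day == timepoint_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need >= 2 replicates per timepoint")
    mean_a = counts[:, in_a].mean(axis=1)
    mean_b = counts[:, in_b].mean(axis=1)
    log2_fc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)

    use = in_a | in_b
    res = nb_lrt_test(counts[:, use], day[use])
    fdr = res["fdr"]
    out = peaks.copy()
    out["log2_fc"] = log2_fc
    out["p_value"] = res["p_value"]
    out["fdr"] = fdr
    out["all_zero"] = res["all_zero"]
    cls = np.full(len(out), "stable", dtype=object)
    cls[(log2_fc > ATAC_FC) & (fdr < ATAC_FDR)] = "gained"
    cls[(log2_fc < -ATAC_FC) & (fdr < ATAC_FDR)] = "lost"
    cls[res["all_zero"]] = "stable"
    out["change_class"] = cls
    return out


def nearest_tss_distance(peaks: pd.DataFrame,
                         annotation: GeneAnnotation) -> pd.Series:
    """Distance from each peak midpoint to the nearest TSS on its
    chromosome (strand-agnostic).  Peaks on chromosomes without any TSS
    get NaN (excluded with a warning)."""
    tss = annotation.tss_by_chromosome()
    mid = (peaks["start_bp"].to_numpy() + peaks["end_bp"].to_numpy()) // 2
    out = np.full(len(peaks), np.nan)
    for chrom, sub_idx in peaks.groupby("chromosome").indices.items():
        positions = tss.get(str(chrom))
        if positions is None or positions.size == 0:
            continue
        m = mid[sub_idx]
        j = np.searchsorted(positions, m)
        left = positions[np.clip(j - 1, 0, positions.size - 1)]
        right = positions[np.clip(j, 0, positions.size - 1)]
        out[sub_idx] = np.minimum(np.abs(m - left), np.abs(m - right))
    if np.isnan(out).any():
        import warnings
        warnings.warn(f"{int(np.isnan(out).sum())} peaks on chromosomes "
                      "without a TSS were excluded", stacklevel=2)
    return pd.Series(out, index=peaks.index, name="tss_distance_bp")


def change_by_distance_density(table: pd.DataFrame,
                               distance_bins: np.ndarray | int = 40,
                               fc_bins: np.ndarray | int = 40,
                               proximal_bp: float = 1000.0) -> dict:
    """2-D density of peaks over (log10 TSS distance, log2 FC), plus the
    distal-vs-proximal mean |log2 FC| contrast."""
    if len(table) == 0:
        raise ValueError("empty peak table")
    dist = table["tss_distance_bp"].to_numpy(dtype=float)
    fc = table["log2_fc"].to_numpy(dtype=float)
    ok = ~np.isnan(dist)
    dist, fc = dist[ok], fc[ok]
    hist, d_edges, f_edges = np.histogram2d(
        np.log10(dist + 1.0), fc, bins=[distance_bins, fc_bins])
    density = hist / hist.sum()
    distal = dist > proximal_bp
    return {
        "density": density,
        "log10_distance_edges": d_edges,
        "log2_fc_edges": f_edges,
        "mean_abs_fc_distal": float(np.abs(fc[distal]).mean())
        if distal.any() else np.nan,
        "mean_abs_fc_proximal": float(np.abs(fc[~distal]).mean())
        if (~distal).any() else np.nan,
    }


def extract_peak_sequences(peaks: pd.DataFrame,
                           genome: dict[str, str]) -> list[str]:
    seqs = []
    for chrom, start, end in zip(peaks["chromosome"], peaks["start_bp"],
                                 peaks["end_bp"]):
        try:
            seqs.append(genome[chrom][start:end])
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None
    return seqs


def count_ctcf_sites(peaks: pd.DataFrame, genome: dict[str, str],
                     ctcf_pwm: PWMModel,
                     cutoff: float = DEFAULT_CUTOFF) -> pd.Series:
    """Predicted CTCF sites per peak: log2-odds hits on both strands at
    cutoff min(10.0, max attainable score), overlaps allowed."""
    seqs = extract_peak_sequences(peaks, genome)
    hits = [count_hits(s, ctcf_pwm, cutoff) for s in seqs]
    return pd.Series(hits, index=peaks.index, name="ctcf_sites")


def ctcf_stratified_change(table: pd.DataFrame,
                           fc_bins: np.ndarray | int = 50,
                           loss_fc: float = -1.0) -> pd.DataFrame:
    """Per CTCF-site group (0, 1, 2, >=3): log2 FC density summary and
    the fraction of peaks with log2_fc below ``loss_fc``."""
    sites = table["ctcf_sites"].to_numpy()
    fc = table["log2_fc"].to_numpy(dtype=float)
    groups = {"0": sites == 0, "1": sites == 1, "2": sites == 2,
              ">=3": sites >= 3}
    rows = []
    for name, mask in groups.items():
        n = int(mask.sum())
        rows.append({
            "group": name,
            "n_peaks": n,
            "loss_fraction": float((fc[mask] < loss_fc).mean()) if n else np.nan,
            "mean_log2_fc": float(fc[mask].mean()) if n else np.nan,
        })
    return pd.DataFrame(rows)


def change_by_width(table: pd.DataFrame,
                    width_bins: np.ndarray | int = 10) -> dict:
    """Binned mean |log2 FC| by peak width plus the Spearman trend."""
    width = table["width_bp"].to_numpy(dtype=float)
    abs_fc = np.abs(table["log2_fc"].to_numpy(dtype=float))
    if np.unique(width).size == 1:
        return {"bin_edges": np.array([width[0], width[0]]),
                "mean_abs_fc": np.array([abs_fc.mean()]),
                "spearman_rho": np.nan, "spearman_p": np.nan}
    edges = np.histogram_bin_edges(width, bins=width_bins)
    which = np.clip(np.digitize(width, edges) - 1, 0, len(edges) - 2)
    means = np.array([abs_fc[which == i].mean() if (which == i).any()
                      else np.nan for i in range(len(edges) - 1)])
    rho = stats.spearmanr(width, abs_fc)
    return {"bin_edges": edges, "mean_abs_fc": means,
            "spearman_rho": float(rho.statistic),
            "spearman_p": float(rho.pvalue)}
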