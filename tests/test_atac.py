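"""Accessibility change, TSS distances, CTCF stratification."""

import numpy as np
import pandas as pd
import pytest

from conswitch import atac
from conswitch.io import GeneAnnotation, GenomicInterval
from conswitch.pwm import PWMModel


def _peaks(n, width=200, chrom="chr1", spacing=1000):
    ivs = [GenomicInterval(chrom, i * spacing, i * spacing + width,
                           f"p{i}") for i in range(n)]
    return atac.peak_table(ivs)


def _tss_ann(positions, chrom="chr1"):
    return GeneAnnotation(pd.DataFrame({
        "chromosome": chrom, "tss_bp": positions, "strand": "+",
        "is_tf": False, "is_cone_specific": False,
        "pathways": [set() for _ in positions],
    }, index=[f"t{i}" for i in range(len(positions))]))


class TestPeakChange:
    def test_identical_timepoints_zero_fc(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(20, 3))
        counts = np.hstack([counts, counts])
        table = atac.peak_change(_peaks(20), counts,
                                 np.array([3, 3, 3, 6, 6, 6]), 3, 6)
        np.testing.assert_allclose(table["log2_fc"], 0.0)
        assert (table["change_class"] == "stable").all()

    def test_definitional_fc_with_plus_one(self):
        # mean 3 vs mean 15 -> log2(16/4) = 2
        counts = np.array([[3, 3, 3, 15, 15, 15]])
        table = atac.peak_change(_peaks(1), counts,
                                 np.array([3, 3, 3, 6, 6, 6]), 3, 6)
        assert table["log2_fc"].iloc[0] == pytest.approx(2.0)

    def test_null_peaks_fdr_controlled(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(30, 120, 2000)[:, None]
        counts = rng.poisson(np.broadcast_to(mu, (2000, 6)))
        table = atac.peak_change(_peaks(2000), counts,
                                 np.array([3, 3, 3, 6, 6, 6]), 3, 6)
        n_called = (table["change_class"] != "stable").sum()
        assert n_called <= 0.01 * 2000 + 5

    def test_all_zero_peak_is_stable_and_flagged(self):
        counts = np.array([[0, 0, 0, 0, 0, 0], [9, 8, 7, 30, 35, 28]])
        table = atac.peak_change(_peaks(2), counts,
                                 np.array([3, 3, 3, 6, 6, 6]), 3, 6)
        assert table["change_class"].iloc[0] == "stable"
        assert bool(table["all_zero"].iloc[0])


class TestRemoveTopPeaks:
    def test_keeps_smallest_totals(self):
        peaks = _peaks(12)
        counts = np.arange(12)[:, None] * np.ones((1, 4))
        kept, kept_counts = atac.remove_top_peaks(peaks, counts, k=10)
        assert len(kept) == 2
        assert kept_counts.sum(axis=1).max() == 4  # totals 0 and 4 remain

    def test_k_zero_is_identity(self):
        peaks = _peaks(5)
        counts = np.ones((5, 2))
        kept, _ = atac.remove_top_peaks(peaks, counts, k=0)
        assert len(kept) == 5

    def test_surviving_set_invariant_to_row_order(self):
        rng = np.random.default_rng(2)
        peaks = _peaks(30)
        counts = rng.poisson(60, size=(30, 4)).astype(float)
        kept1, _ = atac.remove_top_peaks(peaks, counts, k=10)
        perm = rng.permutation(30)
        kept2, _ = atac.remove_top_peaks(
            peaks.iloc[perm].reset_index(drop=True), counts[perm], k=10)
        assert set(kept1["name"]) == set(kept2["name"])

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            atac.remove_top_peaks(_peaks(3), np.ones((3, 2)), k=3)


class TestNearestTss:
    def test_tss_inside_peak_distance_zero(self):
        peaks = atac.peak_table([GenomicInterval("chr1", 100, 200)])
        d = atac.nearest_tss_distance(peaks, _tss_ann([150]))
        assert d.iloc[0] == 0

    def test_min_rule(self):
        peaks = atac.peak_table([GenomicInterval("chr1", 0, 100)])
        d = atac.nearest_tss_distance(peaks, _tss_ann([1050, 5000]))
        assert d.iloc[0] == 1000

    def test_adding_tss_never_increases_distance(self):
        rng = np.random.default_rng(1)
        peaks = _peaks(50, spacing=5000)
        base = sorted(rng.integers(0, 250_000, 10).tolist())
        d1 = atac.nearest_tss_distance(peaks, _tss_ann(base))
        d2 = atac.nearest_tss_distance(peaks, _tss_ann(
            sorted(base + [123_456])))
        assert (d2 <= d1).all()

    def test_chromosome_without_tss_warns_nan(self):
        peaks = atac.peak_table([GenomicInterval("chrX", 0, 100)])
        with pytest.warns(UserWarning, match="without a TSS"):
            d = atac.nearest_tss_distance(peaks, _tss_ann([50]))
        assert np.isnan(d.iloc[0])


class TestDensities:
    def _table(self, dist, fc, width=None):
        t = _peaks(len(dist))
        t["tss_distance_bp"] = dist
        t["log2_fc"] = fc
        if width is not None:
            t["width_bp"] = width
        return t

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.uniform(10, 1e5, 400), rng.normal(size=400))
        out = atac.change_by_distance_density(t)
        assert out["density"].sum() == pytest.approx(1.0)

    def test_identical_peaks_single_cell(self):
        t = self._table(np.full(30, 500.0), np.full(30, -1.2))
        out = atac.change_by_distance_density(t, distance_bins=5, fc_bins=5)
        assert (out["density"] == 1.0).sum() == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            atac.change_by_distance_density(self._table([], []))

    def test_single_width_single_bin(self):
        t = self._table(np.full(10, 100.0), np.ones(10),
                        width=np.full(10, 300))
        out = atac.change_by_width(t)
        assert len(out["mean_abs_fc"]) == 1

    def test_uncoupled_width_has_null_spearman(self):
        rng = np.random.default_rng(3)
        t = self._table(np.full(800, 100.0), rng.normal(size=800),
                        width=rng.integers(150, 2000, 800))
        out = atac.change_by_width(t)
        assert abs(out["spearman_rho"]) < 0.1


class TestCtcfCounting:
    def test_planted_consensus_counted(self):
        pwm = PWMModel("m", np.array([[90.0, 1, 1], [1, 90, 1],
                                      [1, 1, 90], [1, 1, 1]]) * 1.0)
        genome = {"c": "TTTT" + pwm.consensus + "TTTT"}
        peaks = atac.peak_table([GenomicInterval("c", 0, len(genome["c"]))])
        n = atac.count_ctcf_sites(peaks, genome, pwm)
        assert n.iloc[0] >= 1

    def test_peak_shorter_than_motif_zero(self):
        pwm = PWMModel("m", np.ones((4, 10)))
        genome = {"c": "ACGTA"}
        peaks = atac.peak_table([GenomicInterval("c", 0, 5)])
        assert atac.count_ctcf_sites(peaks, genome, pwm).iloc[0] == 0


class TestStratification:
    def test_group_sizes_partition_peaks(self, peak_sim):
        _cfg, sim = peak_sim
        t = atac.peak_table(sim.intervals)
        t["log2_fc"] = np.zeros(len(t))
        t["ctcf_sites"] = sim.truth.peaks["ctcf_sites"].to_numpy()
        strat = atac.ctcf_stratified_change(t)
        assert strat["n_peaks"].sum() == len(t)

    def test_protective_coupling_orders_loss_fractions(self, peak_sim):
        _cfg, sim = peak_sim
        t = atac.peak_table(sim.intervals)
        table = atac.peak_change(t, sim.counts, sim.day, 3, 6)
        table["ctcf_sites"] = sim.truth.peaks["ctcf_sites"].to_numpy()
        strat = atac.ctcf_stratified_change(table)
        lf = strat["loss_fraction"].to_numpy()
        assert lf[0] > lf[1] > lf[2]
        assert lf[0] > lf[3]

    def test_no_coupling_equalizes_groups(self):
        rng = np.random.default_rng(0)
        t = _peaks(4000)
        t["log2_fc"] = rng.normal(scale=0.3, size=4000)
        t["ctcf_sites"] = rng.poisson(1.0, 4000)
        strat = atac.ctcf_stratified_change(t)
        lf = strat["loss_fraction"].dropna()
        assert lf.max() - lf.min() < 0.02


def test_scanner_generator_agreement(peak_sim):
    """Planted CTCF truth equals a fresh scan of the emitted genome."""
    _cfg, sim = peak_sim
    t = atac.peak_table(sim.intervals)
    counted = atac.count_ctcf_sites(t, sim.genome, sim.motif_library[0])
    np.testing.assert_array_equal(counted.to_numpy(),
                                  sim.truth.peaks["ctcf_sites"].to_numpy())
    assert (counted.to_numpy() >=
            sim.truth.peaks["ctcf_planted"].to_numpy() - 0).any()


def test_asymmetric_change_recovery(peak_sim):
    """Losses dominate gains before the switch; almost nothing changes
    after it."""
    _cfg, sim = peak_sim
    t = atac.peak_table(sim.intervals)
    t36 = atac.peak_change(t, sim.counts, sim.day, 3, 6)
    t610 = atac.peak_change(t, sim.counts, sim.day, 6, 10)
    n36 = t36["change_class"].value_counts()
    n610 = t610["change_class"].value_counts()
    assert n36.get("lost", 0) > 3 * n36.get("gained", 0) > 0
    assert (n610.get("lost", 0) + n610.get("gained", 0)) < 0.01 * len(t)


def test_distal_peaks_change_more(peak_sim):
    _cfg, sim = peak_sim
    t = atac.peak_table(sim.intervals)
    table = atac.peak_change(t, sim.counts, sim.day, 3, 6)
    table["tss_distance_bp"] = atac.nearest_tss_distance(
        table, sim.tss_annotation)
    out = atac.change_by_distance_density(table)
    assert out["mean_abs_fc_distal"] > out["mean_abs_fc_proximal"]


def test_short_peaks_change_more(peak_sim):
    _cfg, sim = peak_sim
    t = atac.peak_table(sim.intervals)
    table = atac.peak_change(t, sim.counts, sim.day, 3, 6)
    out = atac.change_by_width(table)
    assert out["spearman_rho"] < -0.02
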