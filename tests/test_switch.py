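"""Switch detection: correlations, PCA, fold changes, classification."""

import numpy as np
import pandas as pd
import pytest

from conswitch import expression as ep
from conswitch import switch as sw


def _log_em(values, columns=None):
    values = np.asarray(values, dtype=float)
    cols = np.arange(values.shape[1]) if columns is None else columns
    return ep.ExpressionMatrix(
        np.array([f"g{i}" for i in range(values.shape[0])], dtype=object),
        np.asarray(cols), values, "log2")


class TestSampleCorrelations:
    def test_duplicate_sample_correlates_perfectly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        em = _log_em(np.column_stack([x, x, rng.normal(size=50)]))
        corr = sw.sample_correlations(em)
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_negated_sample_anticorrelates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        em = _log_em(np.column_stack([x, -x]))
        assert sw.sample_correlations(em).iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_sample_is_named(self):
        em = _log_em(np.column_stack([np.ones(10), np.arange(10.0)]),
                     columns=np.array(["flat", "ok"]))
        with pytest.raises(ValueError, match="flat"):
            sw.sample_correlations(em)

    def test_within_phase_exceeds_cross_phase_on_switch_data(
            self, default_sim):
        _cfg, cm, _ann, _truth = default_sim
        em = ep.rpkm(cm)
        logv = _log_em(np.log2(em.values + 1.0),
                       columns=em.columns)
        corr = sw.sample_correlations(logv).to_numpy()
        pre = em.day <= 5
        post = em.day >= 7
        within = np.concatenate([corr[np.ix_(pre, pre)].ravel(),
                                 corr[np.ix_(post, post)].ravel()])
        cross = corr[np.ix_(pre, post)].ravel()
        assert within.mean() > cross.mean() + 0.02


class TestPca:
    def test_rank_one_matrix_has_all_variance_on_pc1(self):
        days = np.arange(5)
        pattern = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        values = np.outer(np.array([1.0, 2.0, 3.0]), pattern)  # genes x days
        em = _log_em(values, columns=days)
        res = sw.pca_timecourse(em)
        assert res.variance_fraction[0] == pytest.approx(1.0)
        assert res.variance_fraction[1:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_gene_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(40, 7))
        em = sw.pca_timecourse(_log_em(values, columns=np.arange(7)))
        perm = sw.pca_timecourse(
            _log_em(values[rng.permutation(40)], columns=np.arange(7)))
        np.testing.assert_allclose(em.component_scores, perm.component_scores,
                                   atol=1e-9)

    def test_reconstruction_recovers_centered_matrix(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(30, 6))
        res = sw.pca_timecourse(_log_em(values, columns=np.arange(6)))
        centered = values.T - values.T.mean(axis=0, keepdims=True)
        np.testing.assert_allclose(res.reconstruct(), centered, atol=1e-8)

    def test_sign_convention_first_day_nonpositive(self):
        rng = np.random.default_rng(2)
        res = sw.pca_timecourse(_log_em(rng.normal(size=(30, 6)),
                                        columns=np.arange(6)))
        assert (res.component_scores[0, :] <= 1e-12).all()

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="3 days"):
            sw.pca_timecourse(_log_em(np.ones((5, 2)), columns=[0, 1]))


class TestFoldChanges:
    def _em13(self, row):
        return _log_em(np.asarray(row)[None, :], columns=np.arange(13))

    def test_constant_gene_is_zero(self):
        fc = sw.fold_changes(self._em13([3.0] * 13))
        assert fc.iloc[0] == 0.0

    def test_188_fold_change(self):
        # 4 RPKM pre, 4*188 post in log2 space -> log2(188) ~ 7.554
        pre, post = np.log2(4.0), np.log2(4.0 * 188)
        row = [pre] * 6 + [0.0] + [post] * 6
        fc = sw.fold_changes(self._em13(row))
        assert fc.iloc[0] == pytest.approx(np.log2(188), abs=1e-12)
        fc_off = sw.fold_changes(self._em13(row[::-1]))
        assert fc_off.iloc[0] == pytest.approx(-np.log2(188), abs=1e-12)

    def test_swapping_windows_negates(self):
        rng = np.random.default_rng(0)
        em = _log_em(rng.normal(size=(20, 13)), columns=np.arange(13))
        a = sw.fold_changes(em)
        b = sw.fold_changes(em, pre_days=sw.POST_DAYS,
                            post_days=sw.PRE_DAYS)
        np.testing.assert_allclose(a.values, -b.values)

    def test_overlapping_windows_rejected(self):
        em = _log_em(np.ones((2, 13)), columns=np.arange(13))
        with pytest.raises(ValueError, match="overlap"):
            sw.fold_changes(em, pre_days={0, 1, 2}, post_days={2, 3})

    def test_switch_day_belongs_to_neither_window(self):
        row = [0.0] * 6 + [99.0] + [1.0] * 6  # huge day-6 spike
        fc = sw.fold_changes(self._em13(row))
        assert fc.iloc[0] == pytest.approx(1.0)


class TestClassify:
    def test_rule_table(self):
        fc = pd.Series([1.5, 1.5, 0.005, -1.2, -0.5],
                       index=list("abcde"))
        fdr = pd.Series([0.01, 0.2, 0.9, 0.001, 0.01],
                        index=list("abcde"))
        table = sw.classify(fc, fdr)
        assert table.loc["a", "class"] == "switch_on"
        assert table.loc["b", "class"] == "other"
        assert table.loc["c", "class"] == "constant"
        assert table.loc["d", "class"] == "switch_off"
        assert table.loc["e", "class"] == "other"

    def test_idempotent_and_input_only(self):
        rng = np.random.default_rng(0)
        fc = pd.Series(rng.normal(scale=2, size=100))
        fdr = pd.Series(rng.uniform(size=100))
        t1 = sw.classify(fc, fdr)
        t2 = sw.classify(t1["log2_fc"], t1["fdr"])
        assert (t1["class"] == t2["class"]).all()

    def test_strong_subset_flag(self):
        fc = pd.Series([2.5, 1.5], index=["a", "b"])
        fdr = pd.Series([0.01, 0.01], index=["a", "b"])
        table = sw.classify(fc, fdr)
        assert bool(table.loc["a", "strong"]) and not table.loc["b", "strong"]


class TestNormalizedTimecourse:
    def test_constant_set_is_flat_zero(self):
        em = _log_em(np.full((3, 13), 2.0), columns=np.arange(13))
        curve = sw.normalized_timecourse(em, ["g0", "g1"], "pre")
        np.testing.assert_allclose(curve.values, 0.0)

    def test_reference_switch_moves_the_zero_plateau(self):
        row = [0.0] * 6 + [1.5] + [3.0] * 6
        em = _log_em(np.array([row]), columns=np.arange(13))
        pre_ref = sw.normalized_timecourse(em, ["g0"], "pre")
        post_ref = sw.normalized_timecourse(em, ["g0"], "post")
        np.testing.assert_allclose(pre_ref.values[:6], 0.0)
        np.testing.assert_allclose(post_ref.values[7:], 0.0)
        np.testing.assert_allclose(pre_ref.values - post_ref.values, 3.0)

    def test_empty_set_rejected(self):
        em = _log_em(np.ones((2, 13)), columns=np.arange(13))
        with pytest.raises(ValueError, match="empty"):
            sw.normalized_timecourse(em, [], "pre")


class TestChromosomeDistribution:
    def test_exact_proportions_give_stat_zero(self, small_annotation):
        ann = small_annotation
        stat, p = sw.chromosome_distribution_test(
            ["gA", "gC"], ["gA", "gB", "gC", "gD"], ann, min_expected=0.0)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_concentrated_switch_genes_reject(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(2000)]
        chroms = [f"chr{(i % 20) + 1}" for i in range(2000)]
        ann = _annotation(genes, chroms)
        chr1 = [g for g, c in zip(genes, chroms) if c == "chr1"]
        rest = [g for g in genes if g not in set(chr1)]
        switch = chr1 + list(rng.choice(rest, size=60, replace=False))
        _stat, p = sw.chromosome_distribution_test(switch, genes, ann)
        assert p < 1e-6

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(1500)]
        chroms = [f"chr{c}" for c in rng.integers(1, 20, 1500)]
        ann = _annotation(genes, chroms)
        ps = []
        for _ in range(200):
            switch = list(rng.choice(genes, size=150, replace=False))
            ps.append(sw.chromosome_distribution_test(switch, genes, ann)[1])
        ps = np.array(ps)
        # chi-square null: p below alpha about alpha of the time
        assert 0.005 < (ps < 0.05).mean() < 0.12
        assert (ps < 0.5).mean() == pytest.approx(0.5, abs=0.12)

    def test_empty_switch_set_rejected(self, small_annotation):
        with pytest.raises(ValueError, match="empty"):
            sw.chromosome_distribution_test([], ["gA"], small_annotation)


def _annotation(genes, chroms):
    from conswitch.io import GeneAnnotation
    return GeneAnnotation(pd.DataFrame({
        "chromosome": chroms,
        "tss_bp": np.zeros(len(genes), dtype=int),
        "strand": "+",
        "is_tf": False,
        "is_cone_specific": False,
        "pathways": [set() for _ in genes],
    }, index=genes))


def test_switch_fraction_percent():
    assert sw.switch_fraction_percent(10, 20, 300) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        sw.switch_fraction_percent(1, 1, 0)
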