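import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mrdflow as mf


def _calls(n, positives):
    return ["positive"] * positives + ["negative"] * (n - positives)


def _confusion_from_counts(n, ref_pos, fp, fn):
    """Build call vectors realizing given error counts."""
    tp = ref_pos - fn
    tn = n - ref_pos - fp
    ref = ["positive"] * ref_pos + ["negative"] * (n - ref_pos)
    mfc = (
        ["positive"] * tp + ["negative"] * fn
        + ["positive"] * fp + ["negative"] * tn
    )
    return mf.confusion(mfc, ref)


class TestConfusion:
    def test_published_dfn_discordance_counts(self):
        s = _confusion_from_counts(n=125, ref_pos=85, fp=19, fn=11)
        assert s.concordance_pct == pytest.approx(76.0)
        assert s.sensitivity_pct == pytest.approx(87.1, abs=0.05)
        assert s.specificity_pct == pytest.approx(52.5)

    def test_published_laip_discordance_counts(self):
        s = _confusion_from_counts(n=125, ref_pos=85, fp=31, fn=3)
        assert s.concordance_pct == pytest.approx(72.8)

    def test_perfect_agreement(self):
        s = mf.confusion(_calls(10, 4), _calls(10, 4))
        assert s.concordance_pct == 100.0
        assert s.fp == s.fn == 0

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            mf.confusion(_calls(5, 2), _calls(6, 2))

    def test_unknown_call_value_rejected(self):
        with pytest.raises(ValueError):
            mf.confusion(["positive", "excluded"], ["negative", "negative"])

    @given(
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
        st.integers(min_value=0, max_value=30),
    )
    @settings(max_examples=60, deadline=None)
    def test_concordance_identity(self, tp, fp, tn, fn):
        s = mf.ConfusionSummary(tp=tp, fp=fp, tn=tn, fn=fn)
        if s.n:
            assert s.concordance_pct + s.false_pos_pct + s.false_neg_pct == pytest.approx(100.0)


class TestCompareMethods:
    def test_identical_summaries_give_zero_statistic(self):
        s = _confusion_from_counts(100, 60, 10, 5)
        cmp = mf.compare_methods(s, s)
        assert cmp.chi2_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_matches_closed_form_pearson_value(self):
        a = _confusion_from_counts(125, 85, 19, 11)   # 95 concordant
        b = _confusion_from_counts(125, 85, 31, 3)    # 91 concordant
        cmp = mf.compare_methods(a, b)
        # hand-computed Pearson chi-square on [[95, 30], [91, 34]]
        t = np.array([[95, 30], [91, 34]], float)
        n = t.sum()
        expected = np.outer(t.sum(1), t.sum(0)) / n
        hand = ((t - expected) ** 2 / expected).sum()
        assert cmp.table == ((95, 30), (91, 34))
        assert cmp.chi2_statistic == pytest.approx(hand)

    def test_statistic_is_nonnegative(self):
        a = _confusion_from_counts(50, 25, 2, 3)
        b = _confusion_from_counts(50, 25, 10, 1)
        assert mf.compare_methods(a, b).chi2_statistic >= 0

    def test_degenerate_table_warns_and_returns_zero(self):
        a = mf.ConfusionSummary(tp=0, fp=5, tn=0, fn=5)   # zero concordant
        b = mf.ConfusionSummary(tp=0, fp=8, tn=0, fn=2)
        with pytest.warns(UserWarning):
            cmp = mf.compare_methods(a, b)
        assert cmp.chi2_statistic == 0.0


def _brute_force_auc(values, labels):
    """Mann-Whitney pair counting: P(pos > neg) + 0.5 P(tie)."""
    pos = values[labels]
    neg = values[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        values = np.array([0.0, 0.01, 0.02, 1.0, 2.0, 3.0])
        labels = values > 0.5
        roc = mf.roc_analysis(values, labels)
        assert roc.auc == 1.0
        assert 0.02 <= roc.optimal_cutoff < 1.0
        assert roc.optimal_sens_pct == 100.0
        assert roc.optimal_spec_pct == 100.0

    def test_uninformative_values_give_half_auc(self):
        rng = np.random.default_rng(5)
        values = rng.random(2_000)
        labels = rng.random(2_000) < 0.5
        roc = mf.roc_analysis(values, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.05)
        assert roc.p_value > 0.01

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        values = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = np.zeros(n, bool)
        labels[: max(1, n // 3)] = True
        values[labels] += rng.normal(0.2, 0.3)
        roc = mf.roc_analysis(values, labels)
        assert roc.auc == pytest.approx(_brute_force_auc(values, labels))

    @pytest.mark.parametrize("seed", range(4))
    def test_auc_matches_sklearn(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(100 + seed)
        values = rng.random(200)
        labels = rng.random(200) < 0.4
        roc = mf.roc_analysis(values, labels)
        assert roc.auc == pytest.approx(sklearn_metrics.roc_auc_score(labels, values))

    def test_optimal_cutoff_is_an_observed_value(self):
        rng = np.random.default_rng(9)
        values = rng.random(60)
        labels = values + rng.normal(0, 0.3, 60) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = mf.roc_analysis(values, labels)
        assert roc.optimal_cutoff in values

    def test_single_class_is_undefined(self):
        with pytest.raises(ValueError):
            mf.roc_analysis([0.1, 0.2, 0.3], [True, True, True])

    def test_youden_cutoff_recovers_generative_separation_point(self):
        # positives ~ N(1, 0.25), negatives ~ N(0, 0.25): optimal split at 0.5
        rng = np.random.default_rng(14)
        n = 500
        labels = np.arange(n) < n // 2
        values = np.where(labels, rng.normal(1.0, 0.25, n), rng.normal(0.0, 0.25, n))
        roc = mf.roc_analysis(values, labels)
        assert roc.optimal_cutoff == pytest.approx(0.5, abs=0.15)

    def test_hanley_mcneil_se_for_moderate_auc(self):
        # SE formula sanity: grows as classes shrink, zero at AUC extremes
        rng = np.random.default_rng(15)
        small = mf.roc_analysis(
            np.concatenate([rng.normal(1, 1, 10), rng.normal(0, 1, 10)]),
            np.arange(20) < 10,
        )
        large = mf.roc_analysis(
            np.concatenate([rng.normal(1, 1, 200), rng.normal(0, 1, 200)]),
            np.arange(400) < 200,
        )
        assert small.auc_se > large.auc_se
        assert large.auc_ci95[0] <= large.auc <= large.auc_ci95[1]


class TestStratifiedValidation:
    def _results(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        ref = rng.random(n) < 0.6
        values = np.where(ref, rng.lognormal(-1, 1, n), rng.lognormal(-3.5, 1, n))
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "method": ["LAIP_DfN"] * n,
                "therapy": rng.choice(["post_CHT", "post_VenHMA"], n),
                "tracking_marker": rng.choice(["CD7", "CD4"], n),
                "mrd_pct": values,
                "mfc_call": np.where(values > 0.035, "positive", "negative"),
                "molecular_call": np.where(ref, "positive", "negative"),
                "npm1_ratio_pct": np.where(ref, 0.5, 0.001),
                "total_blast_pct": rng.uniform(0, 3, n),
            }
        )

    def test_therapy_strata_sizes_sum_to_cohort(self):
        res = self._results()
        report = mf.stratified_validation(res, "therapy")
        total = sum(blk["LAIP_DfN"]["n"] for blk in report.values())
        assert total == len(res)

    def test_therapy_mix_splits_samples_binomially(self):
        res = self._results(seed=3, n=60)
        report = mf.stratified_validation(res, "therapy")
        n_cht = report["post_CHT"]["LAIP_DfN"]["n"]
        assert abs(n_cht - 30) < 3 * np.sqrt(60 * 0.25)

    def test_empty_stratum_is_handled(self):
        res = self._results()
        res["total_blast_pct"] = 2.0  # nobody below 1%
        report = mf.stratified_validation(res, "blast_lt_1pct")
        assert "blast_lt_1pct" not in report
        assert report["blast_ge_1pct"]["LAIP_DfN"]["n"] == len(res)

    def test_single_reference_class_skips_roc(self):
        res = self._results()
        res["molecular_call"] = "positive"
        report = mf.stratified_validation(res, "therapy")
        for blk in report.values():
            assert blk["LAIP_DfN"]["roc"] is None

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError):
            mf.stratified_validation(self._results(), "zodiac_sign")
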