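"""Wilcoxon screening, sequential backward selection and frequency ranking."""

import numpy as np
import pandas as pd
import pytest

from cesmcad.selection import (
    _cv_accuracy,
    _nb_fold_logliks,
    _stratified_folds,
    null_frequency_test,
    rank_sum_pvalue,
    sbs_round,
    selection_frequencies,
    wilcoxon_filter,
)


def planted_dataset(seed, n=60, p=10, k=1, shift=2.0):
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n // 2)
    X = rng.normal(size=(n, p))
    X[y == "b", :k] += shift
    return pd.DataFrame(X, columns=[f"F{i:03d}" for i in range(p)]), y


class TestRankSum:
    def test_identical_groups_p_one(self):
        assert rank_sum_pvalue(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == 1.0

    def test_small_groups_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: U = 0, two-sided p = 2/20 = 0.1
        p = rank_sum_pvalue(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert p == pytest.approx(0.1)

    def test_separated_large_groups_significant(self):
        a = np.arange(20.0)
        b = np.arange(20.0) + 100
        assert rank_sum_pvalue(a, b) < 1e-6

    def test_constant_feature_p_one(self):
        assert rank_sum_pvalue(np.full(15, 2.0), np.full(12, 2.0)) == 1.0


class TestWilcoxonFilter:
    def test_keeps_separating_and_drops_constant(self):
        X, y = planted_dataset(0, n=40, p=5, k=1, shift=3.0)
        X["constant"] = 1.0
        retained, pvalues = wilcoxon_filter(X, y)
        assert "F000" in retained
        assert "constant" not in retained
        assert pvalues["constant"] == 1.0

    def test_borderline_not_retained_at_alpha(self):
        X = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        retained, pvalues = wilcoxon_filter(X, ["a"] * 3 + ["b"] * 3, alpha=0.05)
        assert pvalues["f"] == pytest.approx(0.1)
        assert retained == []


class TestNaiveBayesEvaluator:
    def test_matches_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 8))
        y = np.repeat([0, 1], 30)
        X[y == 1, 0] += 1.5
        folds = _stratified_folds(y, 10, 42)
        fold_data = _nb_fold_logliks(X, y, folds)
        totals = [lp[None, :] + L.sum(axis=2) for L, lp, _ in fold_data]
        mine = _cv_accuracy(totals, fold_data)
        ref = np.mean([
            (GaussianNB(var_smoothing=1e-9).fit(X[tr], y[tr])
             .predict(X[te]) == y[te]).mean()
            for tr, te in folds])
        assert mine == pytest.approx(float(ref), abs=1e-12)


class TestSbsRound:
    def test_single_feature_returned_unchanged(self):
        X, y = planted_dataset(1, p=1)
        assert sbs_round(X, y, seed=0) == ["F000"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separating_feature_survives(self, seed):
        X, y = planted_dataset(seed, n=60, p=10, k=1, shift=2.0)
        subset = sbs_round(X, y, seed=seed)
        assert "F000" in subset
        assert len(subset) < 10  # noise gets pruned

    def test_too_few_samples_rejected(self):
        X, y = planted_dataset(0, n=8)
        with pytest.raises(ValueError):
            sbs_round(X, y, seed=0)


class TestSelectionFrequencies:
    def test_frequencies_are_percentages_of_rounds(self):
        X, y = planted_dataset(2, n=60, p=8, k=1, shift=2.5)
        res = selection_frequencies(X, y, rounds=10, seed=3)
        assert res.frequencies.between(0, 100).all()
        assert sorted(res.order) == sorted(res.retained_after_filter)
        assert res.frequencies["F000"] >= 80.0

    def test_order_sorted_descending_with_alphabetical_ties(self):
        X, y = planted_dataset(3, n=60, p=8)
        res = selection_frequencies(X, y, rounds=5, seed=0)
        freqs = [res.frequencies[c] for c in res.order]
        assert freqs == sorted(freqs, reverse=True)
        for a, b in zip(res.order, res.order[1:]):
            if res.frequencies[a] == res.frequencies[b]:
                assert a < b

    def test_report_mirrors_frequency_table_layout(self):
        X, y = planted_dataset(4, n=60, p=6)
        X.columns = [f"STAT:Variance_RC", "STAT:Mean_LE", "COUNT:SIFT_LE",
                     "HAAR:Variance_LL2_RC", "GRAD:Mean_Gmag_LE",
                     "GLCM:Contrast_HL1_0_RC"]
        res = selection_frequencies(X, y, rounds=3, seed=0)
        report = res.report()
        assert list(report.columns) == ["Feature Set", "Feature", "ROI Type",
                                        "Frequency (%)"]
        assert set(report["ROI Type"]) <= {"LE", "RC"}

    def test_row_shuffling_leaves_ranking_stable(self):
        X, y = planted_dataset(5, n=60, p=12, k=3, shift=1.5)
        perm = np.random.default_rng(9).permutation(len(y))
        def averaged_top3(Xa, ya):
            freq = sum(
                selection_frequencies(Xa, ya, rounds=5, seed=s).frequencies
                for s in range(8))
            return set(freq.sort_values(ascending=False).index[:3])
        assert len(averaged_top3(X, y)
                   & averaged_top3(X.iloc[perm].reset_index(drop=True),
                                   y[perm])) >= 2


class TestNullFrequencyTest:
    def test_never_selected_feature_has_p_one(self):
        X, y = planted_dataset(6, n=40, p=6, k=1, shift=3.0)
        res = selection_frequencies(X, y, rounds=5, seed=1)
        pvalues = null_frequency_test(res, X, y, permutations=20, seed=1,
                                      rounds=3)
        never = res.frequencies[res.frequencies == 0].index
        assert (pvalues[never] == 1.0).all()

    def test_separating_feature_flagged(self):
        # the null needs a realistically wide feature pool: under a lucky
        # label permutation the spuriously best-correlated feature survives
        # every SBS round, so a specific feature's null frequency reaches
        # 100% with probability on the order of subset-size / pool-size
        X, y = planted_dataset(7, n=60, p=120, k=1, shift=2.5)
        res = selection_frequencies(X, y, rounds=10, seed=2)
        pvalues = null_frequency_test(res, X, y, permutations=50, seed=2,
                                      rounds=3)
        assert res.frequencies["F000"] == 100.0
        assert pvalues["F000"] < 0.05

    def test_noise_calibration_flags_few(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(40, 20)),
                         columns=[f"F{i:02d}" for i in range(20)])
        y = np.repeat(["a", "b"], 20)
        res = selection_frequencies(X, y, rounds=5, seed=7)
        pvalues = null_frequency_test(res, X, y, permutations=20, seed=7,
                                      rounds=3)
        assert (pvalues < 0.05).mean() <= 0.2

    def test_too_few_permutations_rejected(self):
        X, y = planted_dataset(8, n=40, p=4)
        res = selection_frequencies(X, y, rounds=2, seed=0)
        with pytest.raises(ValueError):
            null_frequency_test(res, X, y, permutations=5, seed=0)
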