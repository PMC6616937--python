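"""Random-Forest CV protocol, Youden thresholding and confusion metrics."""

import numpy as np
import pandas as pd
import pytest

from cesmcad.model_eval import (
    ConfusionCounts,
    accuracy_vs_nfeatures,
    confusion_metrics,
    evaluate_cv,
    rf_fit_predict,
    roc_auc,
    undersample,
    youden_threshold,
)
from oracles import rank_auc


class TestUndersample:
    def test_24_vs_34_keeps_48(self):
        y = np.array(["benign"] * 24 + ["malignant"] * 34)
        idx = undersample(y, seed=0)
        assert len(idx) == 48
        kept = y[idx]
        assert (kept == "benign").sum() == (kept == "malignant").sum() == 24

    def test_balanced_input_is_identity(self):
        y = np.array(["a", "b"] * 10)
        np.testing.assert_array_equal(undersample(y, seed=3), np.arange(20))

    def test_different_seeds_draw_different_subsets(self):
        y = np.array(["a"] * 10 + ["b"] * 40)
        a = undersample(y, seed=0)
        b = undersample(y, seed=1)
        assert len(a) == len(b) == 20
        assert not np.array_equal(a, b)


class TestRfFitPredict:
    def test_deterministic_and_in_unit_interval(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.repeat([0, 1], 15)
        s1 = rf_fit_predict(X, y, X, seed=7)
        s2 = rf_fit_predict(X, y, X, seed=7)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= 0) & (s1 <= 1))

    def test_single_tree_votes_are_binary(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        s = rf_fit_predict(X, y, X, n_trees=1, seed=0)
        assert set(np.unique(s)) <= {0.0, 1.0}

    def test_separable_positive_scores_high(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)),
                       rng.normal(5, 0.1, (20, 2))])
        y = np.repeat([0, 1], 20)
        s = rf_fit_predict(X, y, X[y == 1], seed=0)
        assert np.all(s >= 0.9)

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            rf_fit_predict(X, np.zeros(10), X)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_hand_enumerated_pairs(self):
        # 4 pos-neg pairs: 3 concordant, 1 discordant -> 0.75
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_rank_oracle(self, rng):
        scores = np.round(rng.uniform(size=40), 2)  # force some ties
        y = rng.integers(0, 2, 40)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_auc(scores, y) == pytest.approx(rank_auc(scores, y),
                                                   abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestYoudenThreshold:
    def test_separated_scores_midpoint_of_gap(self):
        thr = youden_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)

    def test_tie_broken_toward_sensitivity(self):
        # J = 0.5 both at TP=2,FP=1 (cut 0.225) and TP=1,FP=0 (cut 0.6);
        # the sensitivity tie-break selects the lower cut
        thr = youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert thr == pytest.approx(0.225)

    def test_argmax_contract_on_random_scores(self, rng):
        scores = rng.uniform(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        thr = youden_threshold(scores, y)

        def j(cut):
            pred = scores >= cut
            sens = (pred & (y == 1)).sum() / (y == 1).sum()
            spec = (~pred & (y == 0)).sum() / (y == 0).sum()
            return sens + spec - 1

        assert all(j(thr) >= j(s) - 1e-12 for s in scores)


class TestConfusionMetrics:
    def test_reader_le_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=31, fp=7, tn=16, fn=3))
        assert m["sensitivity"] == pytest.approx(0.912, abs=5e-4)
        assert m["specificity"] == pytest.approx(0.696, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.825, abs=5e-4)
        assert m["mcc"] == pytest.approx(0.63, abs=5e-3)

    def test_reader_cesm_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=34, fp=4, tn=20, fn=0))
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(0.833, abs=5e-4)
        assert m["accuracy"] == pytest.approx(0.931, abs=5e-4)
        assert m["mcc"] == pytest.approx(0.86, abs=5e-3)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity",
                                         "accuracy", "mcc"))

    def test_mcc_equals_pearson_correlation(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = rng.integers(1, 30, 4)
            c = ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
            truth = np.r_[np.ones(tp + fn), np.zeros(tn + fp)]
            pred = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
            ref = np.corrcoef(truth, pred)[0, 1]
            assert confusion_metrics(c)["mcc"] == pytest.approx(ref, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestEvaluateCv:
    def test_separable_data_perfect_metrics(self, rng):
        y = np.repeat(["a", "b"], 24)
        X = pd.DataFrame({"f0": (y == "b") + 0.01 * rng.normal(size=48)})
        ev = evaluate_cv(X, y, rounds=5, folds=10, seed=0)
        assert ev.median("auc") == 1.0
        assert ev.median("accuracy") == 1.0

    def test_random_labels_stay_at_chance(self, rng):
        X = pd.DataFrame(rng.normal(size=(48, 10)),
                         columns=[f"n{i}" for i in range(10)])
        y = rng.permutation(np.repeat(["a", "b"], 24))
        ev = evaluate_cv(X, y, rounds=20, folds=10, seed=3)
        assert 0.4 <= ev.median("auc") <= 0.6
        assert (ev.per_round["auc"] > 0.7).mean() <= 0.10

    def test_summary_layout_and_bounds(self, rng):
        y = np.repeat(["a", "b"], 12)
        X = pd.DataFrame(rng.normal(size=(24, 3)), columns=list("xyz"))
        groups = np.array((["I"] * 6 + ["II"] * 6) * 2)
        ev = evaluate_cv(X, y, rounds=4, folds=6, seed=1, groups=groups)
        assert set(ev.per_group) == {"I", "II"}
        for metric in ("auc", "accuracy", "sensitivity", "specificity"):
            assert ev.summary.loc[metric, "iqr_low"] <= \
                ev.summary.loc[metric, "median"] <= \
                ev.summary.loc[metric, "iqr_high"]
            assert 0 <= ev.summary.loc[metric, "median"] <= 1
        assert -1 <= ev.summary.loc["mcc", "median"] <= 1

    def test_noise_columns_do_not_inflate_inside_selection(self):
        # leakage guard: screening runs on the training partition only, so
        # appending pure-noise columns must not raise the test AUC
        rng = np.random.default_rng(5)
        y = np.repeat(["a", "b"], 24)
        X = pd.DataFrame(rng.normal(size=(48, 5)),
                         columns=[f"s{i}" for i in range(5)])
        for c in X.columns:
            X[c] += 0.9 * (y == "b")
        sel = {"mode": "inside", "top_k": 5}
        base = evaluate_cv(X, y, rounds=5, folds=10, seed=5, selection=sel)
        noise = pd.DataFrame(rng.normal(size=(48, 200)),
                             columns=[f"z{i:03d}" for i in range(200)])
        big = evaluate_cv(pd.concat([X, noise], axis=1), y, rounds=5,
                          folds=10, seed=5, selection=sel)
        assert big.median("auc") <= base.median("auc") + 0.05


class TestAccuracyVsNFeatures:
    def test_full_set_row_reproduces_evaluate_cv(self, rng):
        y = np.repeat(["a", "b"], 24)
        X = pd.DataFrame(rng.normal(size=(48, 5)),
                         columns=[f"s{i}" for i in range(5)])
        for c in X.columns:
            X[c] += 0.8 * (y == "b")
        order = list(X.columns)
        curve = accuracy_vs_nfeatures(X, y, order, [2, 5], rounds=5,
                                      folds=10, seed=7)
        full = evaluate_cv(X[order], y, rounds=5, folds=10, seed=7)
        row = curve[curve.n_features == 5].iloc[0]
        assert row["auc_median"] == full.median("auc")
        assert {"accuracy_median", "accuracy_iqr_low", "accuracy_iqr_high",
                "p_vs_reference"} <= set(curve.columns)
        assert curve[curve.n_features == 2].iloc[0]["p_vs_reference"] == 1.0

    def test_n_capped_at_available_features(self, rng):
        y = np.repeat(["a", "b"], 12)
        X = pd.DataFrame(rng.normal(size=(24, 3)), columns=list("abc"))
        curve = accuracy_vs_nfeatures(X, y, list("abc"), [2, 99], rounds=2,
                                      folds=6, seed=0)
        assert curve["n_features"].tolist() == [2, 3]
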