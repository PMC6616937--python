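"""Random-Forest evaluation under repeated stratified cross-validation.

Protocol: per round, a stratified 10-fold split is drawn; out-of-fold
positive-class scores (fraction of trees voting positive) are pooled over
the folds; the pooled ROC AUC is computed, an operating threshold is chosen
by maximizing Youden's index J = sensitivity + specificity - 1, and the
thresholded confusion matrix yields accuracy, sensitivity, specificity and
the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined 0 when any denominator factor vanishes.  Round-level metrics are
summarized as median and interquartile range, optionally per BPE class
(one shared model and threshold; subgroup metrics come from the same pooled
thresholded predictions).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from cesmcad.selection import _encode_labels, wilcoxon_filter

logger = logging.getLogger(__name__)

METRICS = ("auc", "accuracy", "sensitivity", "specificity", "mcc")


# ---------------------------------------------------------------------------
# elementary pieces

def undersample(labels, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset: the majority class is randomly
    subsampled (without replacement) down to the minority size."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("undersampling requires exactly 2 classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(y == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


def rf_fit_predict(X_train: np.ndarray, y_train, X_test: np.ndarray,
                   n_trees: int = 100, m_split: int = 20,
                   seed: int = 0) -> np.ndarray:
    """Train a Random Forest and return the fraction of trees voting for
    the positive class on each test sample.

    ``m_split`` is capped at the number of available features (a forest on
    4 features cannot draw 20 candidates per split).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y = _encode_labels(y_train)
    if n_trees < 1:
        raise ValueError("need at least one tree")
    m = min(m_split, X_train.shape[1])
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features=m, random_state=int(seed),
    ).fit(X_train, y)
    votes = np.zeros(len(X_test))
    for tree in forest.estimators_:
        votes += (tree.predict(X_test) == 1)
    return votes / n_trees


def roc_auc(scores, labels) -> float:
    """Area under the empirical ROC curve (rank formulation, ties get
    half credit)."""
    y = _encode_labels(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def youden_threshold(scores, labels) -> float:
    """Score cut maximizing J = sensitivity + specificity - 1.

    Candidate cuts are the midpoints between consecutive distinct observed
    scores plus one cut below the minimum and one above the maximum
    (predict everything / nothing positive); prediction is positive when
    score >= cut.  Ties in J are broken toward higher sensitivity, i.e. the
    lower cut.
    """
    scores = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    s = np.unique(scores)
    cuts = np.concatenate([[s[0] - 1.0], (s[:-1] + s[1:]) / 2.0, [s[-1] + 1.0]])
    n_pos, n_neg = y.sum(), (1 - y).sum()
    best = (-np.inf, -np.inf, np.nan)
    for cut in cuts:
        pred = scores >= cut
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if (j, sens) > best[:2]:
            best = (j, sens, cut)
    return float(best[2])


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")

    @classmethod
    def from_predictions(cls, pred: np.ndarray, y: np.ndarray) -> "ConfusionCounts":
        pred = np.asarray(pred, dtype=bool)
        y = np.asarray(y, dtype=bool)
        return cls(tp=int((pred & y).sum()), tn=int((~pred & ~y).sum()),
                   fp=int((pred & ~y).sum()), fn=int((~pred & y).sum()))


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy and MCC of a confusion matrix.

    Sensitivity/specificity are NaN when their class is absent.  MCC is 0
    whenever a denominator factor is 0.  (MCC ranges over [-1, 1]; claims
    that it lives in [0, 1] describe only the useful-classifier half.)
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
    spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "sensitivity": float(sens),
        "specificity": float(spec),
        "accuracy": (tp + tn) / total,
        "mcc": float(mcc),
    }


# ---------------------------------------------------------------------------
# repeated cross-validation

@dataclasses.dataclass
class CvEvaluation:
    """Round-level metrics, their median/IQR summaries and optional
    per-BPE-class summaries."""

    per_round: pd.DataFrame
    summary: pd.DataFrame
    per_group: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)

    def median(self, metric: str) -> float:
        return float(self.summary.loc[metric, "median"])


def _summarize(df: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for metric in METRICS:
        vals = df[metric].to_numpy(dtype=float)
        rows[metric] = {
            "median": np.nanmedian(vals),
            "iqr_low": np.nanpercentile(vals, 25),
            "iqr_high": np.nanpercentile(vals, 75),
        }
    return pd.DataFrame(rows).T


def _round_metrics(scores: np.ndarray, y: np.ndarray) -> tuple[dict, float]:
    auc = roc_auc(scores, y)
    thr = youden_threshold(scores, y)
    m = confusion_metrics(ConfusionCounts.from_predictions(scores >= thr, y == 1))
    m["auc"] = auc
    return m, thr


def evaluate_cv(X: pd.DataFrame, labels, rounds: int = 100, folds: int = 10,
                n_trees: int = 100, m_split: int = 20, seed: int = 0,
                groups=None, selection: dict | None = None) -> CvEvaluation:
    """Repeated stratified k-fold evaluation of the Random Forest.

    ``selection``, if given, runs feature screening *inside* each training
    partition (no leakage): ``{"mode": "inside", "top_k": k, "alpha": a}``
    keeps the ``top_k`` smallest Wilcoxon p-values of the training data.
    With ``selection=None`` the model uses the columns of ``X`` as passed
    (the caller is then responsible for where those columns came from).
    """
    y = _encode_labels(labels)
    Xv = X.to_numpy(dtype=float)
    if np.bincount(y).min() < folds:
        folds = int(np.bincount(y).min())
        logger.info("fold count reduced to %d", folds)
    groups = None if groups is None else np.asarray(groups)
    records = []
    group_records: dict[str, list[dict]] = {}
    round_seeds = np.random.SeedSequence(seed).generate_state(rounds) % (2 ** 31)
    for r, rseed in enumerate(round_seeds):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rseed))
        scores = np.full(len(y), np.nan)
        fold_seeds = np.random.SeedSequence([seed, int(rseed)]) \
            .generate_state(folds) % (2 ** 31)
        for f, (train, test) in enumerate(skf.split(Xv, y)):
            col_idx = np.arange(Xv.shape[1])
            if selection is not None and selection.get("mode") == "inside":
                retained, pvals = wilcoxon_filter(
                    X.iloc[train], y[train], alpha=selection.get("alpha", 0.05))
                pool = retained if retained else list(X.columns)
                top_k = selection.get("top_k")
                ranked = sorted(pool, key=lambda c: (pvals[c], c))
                chosen = ranked[:top_k] if top_k else ranked
                col_idx = np.array([X.columns.get_loc(c) for c in chosen])
            scores[test] = rf_fit_predict(
                Xv[np.ix_(train, col_idx)], y[train], Xv[np.ix_(test, col_idx)],
                n_trees=n_trees, m_split=m_split, seed=int(fold_seeds[f]),
            )
        assert not np.isnan(scores).any(), "every sample must be scored once"
        metrics, thr = _round_metrics(scores, y)
        records.append({"round": r, "youden_threshold": thr, **metrics})
        if groups is not None:
            pred = scores >= thr
            for g in np.unique(groups):
                sel = groups == g
                counts = ConfusionCounts.from_predictions(pred[sel], y[sel] == 1)
                gm = confusion_metrics(counts)
                try:
                    gm["auc"] = roc_auc(scores[sel], y[sel])
                except ValueError:
                    gm["auc"] = float("nan")
                group_records.setdefault(str(g), []).append({"round": r, **gm})
    per_round = pd.DataFrame(records)
    per_group = {g: _summarize(pd.DataFrame(rec))
                 for g, rec in group_records.items()}
    return CvEvaluation(per_round=per_round, summary=_summarize(per_round),
                        per_group=per_group)


def accuracy_vs_nfeatures(X: pd.DataFrame, labels, order: list[str],
                          n_values, rounds: int = 100, folds: int = 10,
                          n_trees: int = 100, m_split: int = 20,
                          seed: int = 0, reference_n: int = 2) -> pd.DataFrame:
    """Summary metrics for models on the top-n ranked features.

    One row per n with median/IQR columns per metric, plus the two-sided
    rank-sum p-value comparing each model's per-round accuracies with the
    ``reference_n``-feature model.
    """
    p = len(order)
    rows = []
    per_round_acc: dict[int, np.ndarray] = {}
    for n in n_values:
        if n > p:
            logger.warning("n=%d exceeds %d ranked features; capped", n, p)
            n = p
        ev = evaluate_cv(X[order[:n]], labels, rounds=rounds, folds=folds,
                         n_trees=n_trees, m_split=m_split, seed=seed)
        per_round_acc[n] = ev.per_round["accuracy"].to_numpy()
        row: dict[str, float] = {"n_features": n}
        for metric in METRICS:
            row[f"{metric}_median"] = ev.summary.loc[metric, "median"]
            row[f"{metric}_iqr_low"] = ev.summary.loc[metric, "iqr_low"]
            row[f"{metric}_iqr_high"] = ev.summary.loc[metric, "iqr_high"]
        rows.append(row)
    ref_n = reference_n if reference_n in per_round_acc else min(per_round_acc)
    ref = per_round_acc[ref_n]
    for row in rows:
        acc = per_round_acc[row["n_features"]]
        if row["n_features"] == ref_n:
            row["p_vs_reference"] = 1.0
        else:
            row["p_vs_reference"] = float(sps.ranksums(acc, ref).pvalue)
    return pd.DataFrame(rows)
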