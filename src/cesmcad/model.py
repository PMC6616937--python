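"""Model/Results facade over the selection and evaluation machinery.

``CadxModel`` holds a feature table with binary labels (and optional BPE
grouping); ``fit()`` runs the full protocol — optional class balancing by
under-sampling, Wilcoxon screening, repeated sequential backward selection,
then repeated stratified CV of a Random Forest on the top-ranked features —
and returns a ``CadxResults`` carrying the feature ranking, the per-round
metrics, their median/IQR summaries and a printable summary table.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from cesmcad.io_roi import METADATA_COLUMNS
from cesmcad.model_eval import (
    CvEvaluation,
    METRICS,
    accuracy_vs_nfeatures,
    evaluate_cv,
    undersample,
)
from cesmcad.selection import SelectionResult, selection_frequencies


class CadxModel:
    """Binary ROI classification model on a radiomic feature table.

    Parameters
    ----------
    features : DataFrame of shape (n_samples, n_features)
        Numeric feature columns only.
    labels : array-like of length n_samples
        Two classes (e.g. benign/malignant or normal/abnormal); the
        lexicographically larger one is treated as positive.
    groups : array-like, optional
        Per-sample BPE class for subgroup reporting.
    """

    def __init__(self, features: pd.DataFrame, labels, groups=None):
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels)
        self.groups = None if groups is None else np.asarray(groups)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels disagree in length")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, label_col: str = "label",
                       group_col: str | None = "bpe_class") -> "CadxModel":
        """Build from a feature table carrying metadata columns."""
        drop = [c for c in METADATA_COLUMNS + [label_col] if c in table.columns]
        groups = table[group_col].to_numpy() if group_col in table.columns else None
        return cls(table.drop(columns=drop), table[label_col].to_numpy(), groups)

    @classmethod
    def from_pairs(cls, pairs) -> "CadxModel":
        """Extract the 464-feature table from ROI pairs and build the model."""
        from cesmcad.features import extract_table

        return cls.from_dataframe(extract_table(pairs))

    def fit(self, n_features: int = 4, selection_rounds: int = 20,
            cv_rounds: int = 20, folds: int = 10, n_trees: int = 100,
            m_split: int = 20, alpha: float = 0.05, balance: bool = True,
            seed: int = 0) -> "CadxResults":
        """Run selection and repeated-CV evaluation; returns the results."""
        X, y = self.features, self.labels
        groups = self.groups
        if balance:
            idx = undersample(y, seed=seed)
            X, y = X.iloc[idx].reset_index(drop=True), y[idx]
            groups = None if groups is None else groups[idx]
        sel = selection_frequencies(X, y, rounds=selection_rounds, seed=seed,
                                    alpha=alpha, folds=folds)
        top = sel.order[: min(n_features, len(sel.order))]
        cv = evaluate_cv(X[top], y, rounds=cv_rounds, folds=folds,
                         n_trees=n_trees, m_split=m_split, seed=seed,
                         groups=groups)
        return CadxResults(model=self, selection=sel, cv=cv,
                           selected_features=list(top), balanced_X=X,
                           balanced_y=y, balanced_groups=groups, seed=seed,
                           cv_config={"rounds": cv_rounds, "folds": folds,
                                      "n_trees": n_trees, "m_split": m_split})


@dataclasses.dataclass
class CadxResults:
    """Fitted-pipeline results: feature ranking plus CV performance."""

    model: CadxModel
    selection: SelectionResult
    cv: CvEvaluation
    selected_features: list[str]
    balanced_X: pd.DataFrame
    balanced_y: np.ndarray
    balanced_groups: np.ndarray | None
    seed: int
    cv_config: dict

    def median(self, metric: str) -> float:
        return self.cv.median(metric)

    def summary_frame(self) -> pd.DataFrame:
        return self.cv.summary

    def accuracy_curve(self, n_values) -> pd.DataFrame:
        """Metrics of models on the top-n ranked features, for each n."""
        return accuracy_vs_nfeatures(
            self.balanced_X, self.balanced_y, self.selection.order, n_values,
            seed=self.seed, **self.cv_config)

    def plot_accuracy_curve(self, curve: pd.DataFrame, ax=None):
        """Accuracy (median, IQR band) against the number of ranked features."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = curve["n_features"]
        ax.plot(n, 100 * curve["accuracy_median"], "o-", label="median accuracy")
        ax.fill_between(n, 100 * curve["accuracy_iqr_low"],
                        100 * curve["accuracy_iqr_high"], alpha=0.3,
                        label="IQR")
        ax.set_xlabel("number of top-ranked features")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = ["CESM CADx pipeline results",
                 "=" * 60,
                 f"samples: {len(self.balanced_y)}   "
                 f"CV: {self.cv_config['rounds']} rounds x "
                 f"{self.cv_config['folds']}-fold   "
                 f"RF: {self.cv_config['n_trees']} trees",
                 f"selected features (top {len(self.selected_features)} "
                 f"of {len(self.selection.order)} ranked):"]
        for name in self.selected_features:
            lines.append(f"  {name}  "
                         f"({self.selection.frequencies[name]:.1f}% of rounds)")
        lines.append("-" * 60)
        lines.append(f"{'metric':<14}{'median':>10}{'IQR':>20}")
        for metric in METRICS:
            med = self.cv.summary.loc[metric, "median"]
            lo = self.cv.summary.loc[metric, "iqr_low"]
            hi = self.cv.summary.loc[metric, "iqr_high"]
            if metric == "mcc":
                lines.append(f"{metric:<14}{med:>10.2f}{f'({lo:.2f}-{hi:.2f})':>20}")
            else:
                lines.append(
                    f"{metric:<14}{100 * med:>9.1f}%"
                    f"{f'({100 * lo:.1f}-{100 * hi:.1f}%)':>20}")
        for group, summ in sorted(self.cv.per_group.items()):
            lines.append(f"BPE {group}: accuracy "
                         f"{100 * summ.loc['accuracy', 'median']:.1f}%, "
                         f"MCC {summ.loc['mcc', 'median']:.2f}")
        return "\n".join(lines)
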