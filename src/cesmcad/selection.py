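"""Frequency-ranked feature selection.

The protocol has three stages:

1. a univariate pre-screen: a two-sided Wilcoxon-Mann-Whitney rank-sum test
   per feature, keeping features whose class medians differ at ``alpha``
   (no multiple-testing correction — the wrapper does the real selection);
2. sequential backward selection (SBS) wrapped around a Gaussian Naive
   Bayes classifier: starting from the full filtered set, the single
   feature whose removal most increases mean stratified 10-fold CV accuracy
   is removed; removal continues while the criterion does not get worse
   (ties included — on a discrete CV-accuracy criterion plateaus are the
   norm, and pruning through them is what produces the small per-round
   subsets whose occurrence frequencies carry the ranking information) and
   stops when every remaining removal strictly lowers the accuracy;
3. the SBS round is repeated R times with re-randomized folds; features are
   ranked by the percentage of rounds in which they survive to the final
   subset, with alphabetical tie-break.

Because Gaussian NB log-posteriors are sums of per-feature log-likelihoods,
the CV accuracy of every single-feature removal can be scored exactly by
subtracting that feature's precomputed log-likelihood contribution — the
wrapper criterion is identical to refitting the classifier, at a fraction
of the cost.

Significance of an observed selection frequency is judged against a null
model obtained by rerunning the whole protocol on label-permuted data.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney pre-screen

def rank_sum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value; exact enumeration for small tie-free
    groups, normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def wilcoxon_filter(X: pd.DataFrame, labels, alpha: float = 0.05
                    ) -> tuple[list[str], pd.Series]:
    """Retain features whose two-class distributions differ at ``alpha``.

    Returns the retained column names and the per-feature p-values.
    """
    y = _encode_labels(labels)
    mask0, mask1 = y == 0, y == 1
    if not mask0.any() or not mask1.any():
        raise ValueError("both classes must be non-empty")
    pvals = {}
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        pvals[col] = rank_sum_pvalue(v[mask0], v[mask1])
    pvalues = pd.Series(pvals)
    retained = [c for c in X.columns if pvalues[c] < alpha]
    return retained, pvalues


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"expected exactly 2 classes, found {classes.size}")
    return (y == classes[1]).astype(int)


# ---------------------------------------------------------------------------
# Gaussian NB cross-validated wrapper criterion

def _stratified_folds(y: np.ndarray, n_folds: int, seed: int):
    smallest = int(np.bincount(y).min())
    k = min(n_folds, smallest)
    if k < n_folds:
        logger.info("fold count reduced to %d (smallest class size)", k)
    if k < 2:
        raise ValueError("need at least 2 samples per class for CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return list(skf.split(np.zeros_like(y), y))


def _nb_fold_logliks(X: np.ndarray, y: np.ndarray, folds,
                     var_smoothing: float = 1e-9):
    """Per-fold per-feature class log-likelihood matrices.

    Returns a list of (L, logprior, y_test) with L of shape
    (n_test, 2, n_features).  Variance smoothing follows the usual Gaussian
    NB convention: ``var_smoothing`` times the largest training-set feature
    variance is added to every class variance (computed once over the full
    candidate pool so the criterion is stable under feature removal).
    """
    out = []
    for train, test in folds:
        Xtr, ytr = X[train], y[train]
        eps = var_smoothing * float(np.var(Xtr, axis=0).max())
        if eps == 0.0:
            eps = var_smoothing
        L = np.empty((len(test), 2, X.shape[1]))
        logprior = np.empty(2)
        for c in (0, 1):
            Xc = Xtr[ytr == c]
            mu = Xc.mean(axis=0)
            var = Xc.var(axis=0) + eps
            L[:, c, :] = -0.5 * (_LOG2PI + np.log(var)
                                 + (X[test] - mu) ** 2 / var)
            logprior[c] = np.log(len(Xc) / len(ytr))
        out.append((L, logprior, y[test]))
    return out


def _cv_accuracy(totals, fold_data) -> float:
    accs = [float(np.mean(np.argmax(T, axis=1) == ytest))
            for T, (_, _, ytest) in zip(totals, fold_data)]
    return float(np.mean(accs))


def sbs_round(X: pd.DataFrame, labels, seed: int, folds: int = 10,
              tol: float = 1e-12) -> list[str]:
    """One round of sequential backward selection; returns the final subset.

    Fold assignment derives from ``seed``.  A feature is removed while the
    best removal keeps the CV accuracy within ``tol`` of the current value
    (i.e. plateaus are pruned through); ties between equally good removals
    are broken toward the lowest column index, so the result is
    column-order dependent only at exact ties.  Never returns an empty set.
    """
    y = _encode_labels(labels)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if p < 1:
        raise ValueError("need at least one feature")
    if n < 10:
        raise ValueError("need at least 10 samples")
    fold_data = _nb_fold_logliks(Xv, y, _stratified_folds(y, folds, seed))
    active = np.arange(p)
    totals = [logprior[None, :] + L.sum(axis=2) for L, logprior, _ in fold_data]
    current = _cv_accuracy(totals, fold_data)
    while active.size > 1:
        cand_accs = np.zeros(active.size)
        for T, (L, _, ytest) in zip(totals, fold_data):
            S = T[:, :, None] - L[:, :, active]          # (n_test, 2, n_active)
            preds = np.argmax(S, axis=1)                 # (n_test, n_active)
            cand_accs += (preds == ytest[:, None]).mean(axis=0)
        cand_accs /= len(fold_data)
        best = int(np.argmax(cand_accs))                 # first index wins ties
        if cand_accs[best] < current - tol:
            break
        removed = active[best]
        for k, (L, _, _) in enumerate(fold_data):
            totals[k] = totals[k] - L[:, :, removed]
        current = float(cand_accs[best])
        active = np.delete(active, best)
    return [X.columns[i] for i in active]


# ---------------------------------------------------------------------------
# Repeated selection and the null-model frequency test

@dataclasses.dataclass
class SelectionResult:
    """Per-feature selection frequencies over repeated SBS rounds.

    ``frequencies`` are percentages of rounds (index: retained features);
    ``order`` is the descending-frequency permutation of the retained
    features (alphabetical tie-break); ``pvalues`` holds null-model
    p-values once :func:`null_frequency_test` has run.
    """

    frequencies: pd.Series
    order: list[str]
    retained_after_filter: list[str]
    filter_pvalues: pd.Series
    rounds: int
    pvalues: pd.Series | None = None

    def report(self) -> pd.DataFrame:
        """Selection report mirroring the frequency-table layout
        (Feature Set, Feature, ROI Type, Frequency %)."""
        from cesmcad.features.extract import parse_feature_name

        rows = []
        for name in self.order:
            try:
                fn = parse_feature_name(name)
                rows.append({"Feature Set": fn.set_tag, "Feature": fn.display(),
                             "ROI Type": fn.source,
                             "Frequency (%)": self.frequencies[name]})
            except Exception:
                rows.append({"Feature Set": "", "Feature": name, "ROI Type": "",
                             "Frequency (%)": self.frequencies[name]})
        return pd.DataFrame(rows)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def selection_frequencies(X: pd.DataFrame, labels, rounds: int = 100,
                          seed: int = 0, alpha: float = 0.05,
                          folds: int = 10, prefiltered: bool = False
                          ) -> SelectionResult:
    """Run the filter plus R re-randomized SBS rounds and rank by frequency."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if prefiltered:
        retained, pvalues = list(X.columns), pd.Series(np.nan, index=X.columns)
    else:
        retained, pvalues = wilcoxon_filter(X, labels, alpha)
    if len(retained) < 2:
        # degenerate screen: fall back to the unfiltered pool
        logger.warning("Wilcoxon filter retained %d features; using all",
                       len(retained))
        retained = list(X.columns)
    Xf = X[retained]
    counts = pd.Series(0, index=retained, dtype=float)
    for rseed in _spawn_seeds(seed, rounds):
        for name in sbs_round(Xf, labels, seed=int(rseed), folds=folds):
            counts[name] += 1
    freq = 100.0 * counts / rounds
    order = sorted(retained, key=lambda c: (-freq[c], c))
    return SelectionResult(frequencies=freq, order=order,
                           retained_after_filter=retained,
                           filter_pvalues=pvalues, rounds=rounds)


def null_frequency_test(result: SelectionResult, X: pd.DataFrame, labels,
                        permutations: int = 50, seed: int = 0,
                        rounds: int | None = None, alpha: float = 0.05,
                        folds: int = 10) -> pd.Series:
    """Per-feature p-values of the observed selection frequencies.

    The null distribution reruns :func:`selection_frequencies` on
    label-permuted data (a reduced number of rounds may be used); the
    p-value is the fraction of null frequencies >= the observed frequency.
    Features never selected get p = 1.  The result's ``pvalues`` field is
    filled in place.
    """
    if permutations < 20:
        raise ValueError("need at least 20 permutations")
    rounds = rounds if rounds is not None else result.rounds
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    observed = result.frequencies.reindex(X.columns, fill_value=0.0)
    exceed = pd.Series(0.0, index=X.columns)
    for k in range(permutations):
        y_perm = rng.permutation(y)
        null = selection_frequencies(
            X, y_perm, rounds=rounds, seed=int(rng.integers(2 ** 31)),
            alpha=alpha, folds=folds,
        ).frequencies.reindex(X.columns, fill_value=0.0)
        exceed += (null >= observed).astype(float)
    pvalues = exceed / permutations
    result.pvalues = pvalues
    return pvalues
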