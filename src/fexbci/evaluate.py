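"""Cross-validation bookkeeping and chance-corrected agreement metrics.

Recognition accuracy is estimated by stratified k-fold cross-validation
(k = 5 by default, optionally repeated with fresh shuffles).  Agreement is
summarised by Cohen's kappa,

    kappa = (p0 - pe) / (1 - pe),

where p0 is the observed accuracy (trace of the confusion matrix over its
total) and pe the expected chance agreement.  For C classes pe is the
marginal product sum  pe = sum_c row_c * col_c / total^2;  for two classes
this reduces exactly to the familiar TP/TN/FP/FN form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from fexbci.synthdata import EpochSet, N_CLASSES

__all__ = [
    "FoldPlan", "MetricsReport", "make_folds", "confusion_matrix", "metrics",
    "cross_validate", "compare_methods",
]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignments: one row of fold ids per repeat."""

    k: int
    assignments: np.ndarray  # (repeats, n) int fold id in 0..k-1
    seed: int

    @property
    def repeats(self) -> int:
        return self.assignments.shape[0]

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def folds(self, repeat: int = 0):
        """Yield (train_idx, test_idx) for each fold of one repeat."""
        a = self.assignments[repeat]
        for f in range(self.k):
            yield np.flatnonzero(a != f), np.flatnonzero(a == f)


def make_folds(n: int, labels, k: int = 5, repeats: int = 1, seed: int = 0
               ) -> FoldPlan:
    """Stratified k-fold assignments, deterministic under seed.

    Folds are disjoint, cover all n epochs, differ in size by at most one,
    and every class appears in every fold (which requires at least k members
    per class).
    """
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for n={n}")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} epochs")
    classes, counts = np.unique(labels, return_counts=True)
    thin = classes[counts < k]
    if len(thin):
        raise ValueError(f"classes {thin.tolist()} have fewer than k={k} members")
    assignments = np.empty((repeats, n), dtype=np.int64)
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            assignments[r, test_idx] = f
    return FoldPlan(k=k, assignments=assignments, seed=seed)


def confusion_matrix(y_true, y_pred, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    for name, y in (("true", y_true), ("predicted", y_pred)):
        if len(y) and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclass
class MetricsReport:
    """Accuracy, expected chance agreement and kappa, with per-fold detail."""

    p0: float
    pe: float
    kappa: float | None
    confusion: np.ndarray = field(repr=False)
    fold_accuracies: np.ndarray | None = None
    fold_confusions: list[np.ndarray] | None = field(default=None, repr=False)
    kappa_undefined_reason: str | None = None

    @property
    def mean_accuracy(self) -> float | None:
        if self.fold_accuracies is None:
            return None
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float | None:
        if self.fold_accuracies is None:
            return None
        return float(np.std(self.fold_accuracies, ddof=1)) \
            if len(self.fold_accuracies) > 1 else 0.0

    def to_dict(self) -> dict:
        d = {"p0": self.p0, "pe": self.pe, "kappa": self.kappa}
        if self.fold_accuracies is not None:
            d["fold_accuracies"] = list(map(float, self.fold_accuracies))
            d["mean_accuracy"] = self.mean_accuracy
            d["sd_accuracy"] = self.sd_accuracy
        if self.kappa_undefined_reason:
            d["kappa_undefined_reason"] = self.kappa_undefined_reason
        return d


def metrics(cm: np.ndarray, fold_accuracies=None, fold_confusions=None
            ) -> MetricsReport:
    """p0, pe and kappa from a confusion matrix.

    When pe = 1 (both marginals concentrated on one class) kappa has a zero
    denominator and is reported as missing with a reason rather than NaN.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {cm.shape}")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    p0 = float(np.trace(cm) / total)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    pe = float((row * col).sum() / total**2)
    if pe == 1.0:
        return MetricsReport(
            p0=p0, pe=pe, kappa=None, confusion=cm,
            fold_accuracies=None if fold_accuracies is None
            else np.asarray(fold_accuracies, dtype=float),
            fold_confusions=fold_confusions,
            kappa_undefined_reason="pe = 1: all mass on a single class in "
                                   "both marginals; kappa denominator is zero")
    kappa = (p0 - pe) / (1.0 - pe)
    return MetricsReport(p0=p0, pe=pe, kappa=float(kappa), confusion=cm,
                         fold_accuracies=None if fold_accuracies is None
                         else np.asarray(fold_accuracies, dtype=float),
                         fold_confusions=fold_confusions)


def cross_validate(data: EpochSet, plan: FoldPlan, fit_predict,
                   n_classes: int = N_CLASSES) -> MetricsReport:
    """Train/score each fold of each repeat and pool the confusion matrix.

    ``fit_predict(train: EpochSet, test: EpochSet, fold_seed: int)`` must
    return predicted labels for the test set.  Per-fold accuracies (over all
    repeats) and per-fold confusion matrices accompany the pooled metrics.
    A training fold missing a class raises before any model is fitted.
    """
    if plan.n != data.n_epochs:
        raise ValueError(f"plan covers {plan.n} epochs, data has {data.n_epochs}")
    fold_accs, fold_cms = [], []
    pooled = np.zeros((n_classes, n_classes), dtype=np.int64)
    for r in range(plan.repeats):
        for f, (tr, te) in enumerate(plan.folds(r)):
            if len(np.unique(data.labels[tr])) < n_classes:
                raise ValueError(f"repeat {r} fold {f}: training split lacks a class")
            pred = np.asarray(fit_predict(data.subset(tr), data.subset(te),
                                          plan.seed + 1000 * r + f))
            cm = confusion_matrix(data.labels[te], pred, n_classes)
            fold_cms.append(cm)
            fold_accs.append(float(np.trace(cm) / cm.sum()))
            pooled += cm
    return metrics(pooled, fold_accuracies=fold_accs, fold_confusions=fold_cms)


def compare_methods(accuracies_by_method: dict[str, np.ndarray]) -> pd.DataFrame:
    """Paired t-tests between every method pair plus a one-way ANOVA.

    Input vectors must be paired (same folds/seeds, same length).  Rows with
    test = 'anova' carry the F statistic; paired rows carry t.  Degenerate
    zero-variance differences are flagged in the ``note`` column instead of
    producing silent NaNs.
    """
    names = list(accuracies_by_method)
    if len(names) < 2:
        raise ValueError("need at least two methods to compare")
    vecs = {k: np.asarray(v, dtype=float) for k, v in accuracies_by_method.items()}
    lengths = {len(v) for v in vecs.values()}
    if len(lengths) != 1:
        raise ValueError(f"paired comparison needs equal lengths, got {lengths}")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = vecs[a] - vecs[b]
            if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
                t, p = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
                note = "zero-variance paired differences"
            else:
                t, p = stats.ttest_rel(vecs[a], vecs[b])
                note = ""
            rows.append({"test": "paired_t", "methods": f"{a} vs {b}",
                         "statistic": float(t), "p_value": float(p), "note": note})
    groups = [vecs[k] for k in names]
    if all(np.allclose(g, groups[0]) for g in groups):
        rows.append({"test": "anova", "methods": " vs ".join(names),
                     "statistic": 0.0, "p_value": 1.0,
                     "note": "identical groups"})
    else:
        F, p = stats.f_oneway(*groups)
        rows.append({"test": "anova", "methods": " vs ".join(names),
                     "statistic": float(F), "p_value": float(p), "note": ""})
    return pd.DataFrame(rows)
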