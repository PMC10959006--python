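"""Evaluation metrics, cross-validation, balanced-test construction, and
wavelength-importance analysis.

Metrics are the field's five-class precision/recall summaries, always
computed *from the confusion matrix* (the matrix is the single source of
truth):

* MAP — macro averaged precision, the unweighted mean of the five
  per-class precisions;
* WAP — weighted averaged precision, weights alpha_i = C_i / sum C_i
  (true-class shares);
* WR  — weighted recall; algebraically identical to overall (micro)
  accuracy, trace / total.

Wavelength importance combines random-forest Gini importance (impurity
decrease summed over all splits on a band) with per-band Pearson
correlation against the measured element concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from nirleaf.spectra_io import LabeledSet, SpectrumMatrix

__all__ = ["MetricsReport", "ImportanceProfile", "confusion_matrix",
           "precision_recall", "summary_metrics", "compute_metrics",
           "balance_test_set", "cross_validate", "gini_importance",
           "band_element_correlation", "importance_profile"]


@dataclass
class MetricsReport:
    """Confusion matrix and the derived precision/recall summaries.

    Fractions are stored in [0, 1]; multiply by 100 for the conventional
    percentage presentation.
    """

    confusion: np.ndarray
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    map: float
    wap: float
    wr: float
    alpha: np.ndarray
    mu_testset: float

    def as_percent(self) -> dict:
        return {"WAP": 100 * self.wap, "MAP": 100 * self.map,
                "WR": 100 * self.wr}

    def summary(self) -> str:
        lines = ["Classification metrics", "-" * 40,
                 f"WAP {100 * self.wap:6.1f} %   MAP {100 * self.map:6.1f} %"
                 f"   WR {100 * self.wr:6.1f} %",
                 f"test-set imbalance ratio mu = {self.mu_testset:.2f}",
                 "class  precision  recall  share",
                 ]
        for i in range(self.confusion.shape[0]):
            lines.append(f"{i:5d}  {self.per_class_precision[i]:9.3f}"
                         f"  {self.per_class_recall[i]:6.3f}"
                         f"  {self.alpha[i]:5.3f}")
        return "\n".join(lines)


@dataclass
class ImportanceProfile:
    """Per-band Gini importance, Pearson correlation, and the top bands."""

    gini: np.ndarray
    pearson_r: np.ndarray | None
    top_bands: np.ndarray
    wavelengths: np.ndarray


def confusion_matrix(y_true, y_pred, n_classes: int = 5) -> np.ndarray:
    """Entry (i, j): count of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")
    M = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(M, (y_true, y_pred), 1)
    return M


def precision_recall(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class precision (TP / column sum) and recall (TP / row sum).

    Empty denominators (class never predicted / never true) yield 0.
    """
    M = np.asarray(confusion, dtype=float)
    tp = np.diag(M)
    col = M.sum(axis=0)
    row = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
    return precision, recall


def summary_metrics(confusion: np.ndarray) -> tuple[float, float, float]:
    """(MAP, WAP, WR) from a confusion matrix.

    MAP averages the per-class precisions with equal weight; WAP and WR
    weight by the true-class shares alpha_i, making WR identical to
    trace / total.
    """
    M = np.asarray(confusion, dtype=float)
    precision, recall = precision_recall(M)
    k_plus_1 = M.shape[0]
    total = M.sum()
    alpha = M.sum(axis=1) / total if total else np.zeros(k_plus_1)
    map_ = float(precision.sum() / k_plus_1)
    wap = float((alpha * precision).sum())
    wr = float((alpha * recall).sum())
    return map_, wap, wr


def compute_metrics(y_true, y_pred, n_classes: int = 5) -> MetricsReport:
    """Full metrics report for a prediction vector."""
    M = confusion_matrix(y_true, y_pred, n_classes)
    precision, recall = precision_recall(M)
    map_, wap, wr = summary_metrics(M)
    row = M.sum(axis=1)
    alpha = row / row.sum() if row.sum() else np.zeros(n_classes)
    nonzero = row[row > 0]
    mu = float(nonzero.max() / nonzero.min()) if nonzero.size else float("nan")
    return MetricsReport(confusion=M, per_class_precision=precision,
                         per_class_recall=recall, map=map_, wap=wap, wr=wr,
                         alpha=alpha, mu_testset=mu)


def balance_test_set(test: LabeledSet, seed: int = 0) -> LabeledSet:
    """Downsample every class (without replacement) to the minimum class
    count, so the balanced test set has mu = 1."""
    counts = test.class_counts
    if np.any(counts == 0):
        raise ValueError("balance_test_set requires every class non-empty")
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = np.concatenate([
        rng.choice(np.where(test.labels == c)[0], size=m, replace=False)
        for c in range(counts.size)])
    return test.subset(np.sort(keep))


def cross_validate(L: LabeledSet, U: SpectrumMatrix, config, folds: int = 5,
                   seed: int = 0) -> tuple[float, np.ndarray]:
    """Stratified k-fold cross-validation of the self-training model.

    Each fold trains on the remaining folds (plus the unlabeled pool) and
    scores WAP on the held-out fold; returns (mean WAP, per-fold WAP).
    """
    from nirleaf.selftrain import SelfTrainingModel
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = L.class_counts
    min_count = int(counts[counts > 0].min())
    if min_count < folds:
        warnings.warn(f"smallest class has {min_count} samples; "
                      f"refolding with {max(2, min_count)} folds")
        folds = max(2, min_count)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(L.spectra.values, L.labels):
        results = SelfTrainingModel(L.subset(train_idx), U, config).fit()
        report = results.evaluate(L.subset(test_idx))
        scores.append(report.wap)
    scores = np.asarray(scores)
    return float(scores.mean()), scores


# ---------------------------------------------------------------------------
# wavelength importance


def _tree_importance(tree, n_features: int, mode: str) -> np.ndarray:
    t = tree.tree_
    imp = np.zeros(n_features)
    internal = t.children_left != -1
    for q in np.where(internal)[0]:
        left, right = t.children_left[q], t.children_right[q]
        f = t.feature[q]
        if mode == "weighted":
            imp[f] += (t.weighted_n_node_samples[q] * t.impurity[q]
                       - t.weighted_n_node_samples[left] * t.impurity[left]
                       - t.weighted_n_node_samples[right] * t.impurity[right])
        else:  # literal: raw Gini difference, no child-size weights
            imp[f] += t.impurity[q] - t.impurity[left] - t.impurity[right]
    if mode == "weighted":
        imp /= t.weighted_n_node_samples[0]
    return imp


def gini_importance(model, mode: str = "weighted", *,
                    X: SpectrumMatrix | None = None, y=None,
                    seed: int = 0, allow_auxiliary: bool = True) -> np.ndarray:
    """Per-band Gini importance of a tree-ensemble classifier.

    ``mode="weighted"`` (default) is the standard impurity-decrease
    importance — each split on band b contributes
    G_q - (n_i/n_q) G_i - (n_j/n_q) G_j — normalised to sum 1.
    ``mode="literal"`` omits the child-size weights (the raw Gini
    difference G_q - G_i - G_j), which can go negative; it is offered for
    fidelity to the unweighted form sometimes printed, and is normalised
    by the sum of absolute values.

    If ``model`` has no trees (LDA/PLSDA) an auxiliary seeded forest is
    fitted on (X, y) — the same data the model was trained on — unless
    ``allow_auxiliary`` is False.
    """
    if mode not in ("weighted", "literal"):
        raise ValueError("mode must be 'weighted' or 'literal'")
    forest = getattr(model, "classifier_", model)
    if not hasattr(forest, "estimators_"):
        if not allow_auxiliary:
            raise TypeError("model has no decision trees and the auxiliary "
                            "forest is disabled")
        if X is None or y is None:
            raise TypeError("model has no decision trees; pass X and y to "
                            "fit an auxiliary forest")
        forest = RandomForestClassifier(n_estimators=100, random_state=seed,
                                        n_jobs=1).fit(X.values, np.asarray(y))
    n_features = forest.n_features_in_
    per_tree = []
    for est in forest.estimators_:
        imp = _tree_importance(est, n_features, mode)
        if mode == "weighted":
            s = imp.sum()
            if s > 0:
                imp = imp / s
        per_tree.append(imp)
    total = np.mean(per_tree, axis=0)
    if mode == "weighted":
        s = total.sum()
        return total / s if s > 0 else total
    s = np.abs(total).sum()
    return total / s if s > 0 else total


def band_element_correlation(spectra: SpectrumMatrix, conc) -> np.ndarray:
    """Pearson correlation of each band's reflectance with the element
    concentration; constant bands yield r = 0 with a warning."""
    conc = np.asarray(conc, dtype=float)
    if conc.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(conc) == 0:
        raise ValueError("concentrations are constant")
    X = spectra.values
    xc = X - X.mean(axis=0)
    yc = conc - conc.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    constant = sx == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant band(s); r set to 0")
    denom = np.where(constant, 1.0, sx * sy)
    r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.where(constant, 0.0, r)


def importance_profile(model, spectra: SpectrumMatrix, conc=None, *,
                       y=None, mode: str = "weighted", top: int = 5,
                       seed: int = 0) -> ImportanceProfile:
    """Bundle Gini importance, optional concentration correlation, and the
    ``top`` highest-importance band indices (descending)."""
    gini = gini_importance(model, mode, X=spectra, y=y, seed=seed)
    r = None if conc is None else band_element_correlation(spectra, conc)
    top_bands = np.argsort(-gini, kind="stable")[:top]
    return ImportanceProfile(gini=gini, pearson_r=r, top_bands=top_bands,
                             wavelengths=spectra.wavelengths)
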