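"""Leave-one-out cross-validation and performance measures.

Each sample is predicted by a classifier trained on the other N-1; the held
out probabilities are pooled into sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), misclassification, accuracy, the Mann–Whitney empirical AUC
(ties counted 1/2, i.e. midranks) and an ROC polyline whose trapezoidal area
equals that AUC exactly.

Two protocols are supported.  The default mirrors the original study: feature
selection happens once on the full data before LOOCV (a deliberately
reproduced optimistic protocol).  Strict mode (``select_alpha`` set) repeats
the selection inside every fold, which is the unbiased variant; on data with
no class signal only strict mode is expected to sit at chance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    DEFAULT_COST_GRID,
    DEFAULT_INNER_FOLDS,
    ClassifierSpec,
    TrainedModel,
    fit,
    tune_svm_cost,
)
from .features import FeatureMatrix
from .selection import select_features, selected_features


def empirical_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Mann–Whitney AUC: P(score of a random positive > random negative),
    ties counted 1/2 (midrank convention)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(probs)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(probs: Sequence[float], labels: Sequence[int]) -> list[tuple[float, float]]:
    """(FPR, TPR) polyline, one vertex per distinct threshold (descending),
    anchored at (0,0) and (1,1).  Its trapezoidal area equals
    :func:`empirical_auc` (diagonal segments encode tied scores)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both classes must be present")
    order = np.argsort(-probs, kind="stable")
    sorted_probs = probs[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels == 1)
    fp = np.cumsum(sorted_labels == 0)
    # keep the last index of each run of tied scores
    distinct = np.r_[sorted_probs[1:] != sorted_probs[:-1], True]
    pts = [(0.0, 0.0)]
    for i in np.flatnonzero(distinct):
        pts.append((fp[i] / n_neg, tp[i] / n_pos))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def confusion_metrics(true_labels: Sequence[int], pred_labels: Sequence[int]) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/misclassification from 0/1 vectors."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    tp = int(((t == 1) & (p == 1)).sum())
    fn = int(((t == 1) & (p == 0)).sum())
    tn = int(((t == 0) & (p == 0)).sum())
    fp = int(((t == 0) & (p == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(t)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "misclassification": 1.0 - acc,
    }


@dataclass
class CVReport:
    """Per-sample LOOCV predictions plus pooled performance measures."""

    per_sample: pd.DataFrame  # id-indexed: true_label, prob_positive, pred_label
    metrics: dict[str, float]
    roc: list[tuple[float, float]]
    classifier: ClassifierSpec
    tuned_costs: list[float] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "classifier": {
                "kind": self.classifier.kind,
                "params": self.classifier.params,
                "standardize": self.classifier.standardize,
            },
            "metrics": self.metrics,
            "roc_points": self.roc,
            "tuned_costs": self.tuned_costs,
            "per_sample": self.per_sample.reset_index().to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _metrics_from_predictions(
    true_labels: np.ndarray, probs: np.ndarray
) -> tuple[dict[str, float], list[tuple[float, float]]]:
    preds = (probs >= 0.5).astype(int)
    metrics = confusion_metrics(true_labels, preds)
    metrics["auc"] = empirical_auc(probs, true_labels)
    return metrics, roc_points(probs, true_labels)


def loocv(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    nested_tuning: bool = False,
    seed: int = 0,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    select_alpha: float | None = None,
) -> CVReport:
    """Leave-one-out cross-validation of one classifier.

    With ``nested_tuning`` and an SVM spec, the cost C is re-tuned by
    stratified inner CV inside each of the N training sets.  With
    ``select_alpha`` set (strict mode) the t-test feature selection is
    repeated inside each training set and applied to the held-out sample;
    folds where nothing is selected fall back to all features.
    """
    if matrix.labels is None:
        raise ValueError("LOOCV requires a labeled matrix")
    y = matrix.labels
    n = len(matrix)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs at least 2 samples")

    probs = np.empty(n)
    tuned: list[float] = []
    for i in range(n):
        train_idx = np.r_[0:i, i + 1 : n]
        train = matrix.subset_samples(train_idx)
        test = matrix.subset_samples(np.array([i]))
        if len(np.unique(train.labels)) < 2:
            raise ValueError("degenerate fold: training set has a single class")
        if select_alpha is not None:
            table = select_features(train, alpha=select_alpha)
            names = selected_features(table)
            if names:
                train = train.subset_features(names)
                test = test.subset_features(names)
        fold_spec = spec
        if nested_tuning and spec.kind == "svm_linear":
            c = tune_svm_cost(train, cost_grid, inner_folds, seed=seed)
            tuned.append(c)
            fold_spec = ClassifierSpec(spec.kind, {**spec.params, "C": c}, spec.standardize)
        model = fit(fold_spec, train, seed=seed)
        probs[i] = model.predict_proba(test)[0]

    metrics, roc = _metrics_from_predictions(y, probs)
    per_sample = pd.DataFrame(
        {
            "true_label": y,
            "prob_positive": probs,
            "pred_label": (probs >= 0.5).astype(int),
        },
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
    return CVReport(per_sample, metrics, roc, spec, tuned)


def trapezoid_area(points: Sequence[tuple[float, float]]) -> float:
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


# ---------------------------------------------------------------------------
# plots (probability strip and ROC curves)
# ---------------------------------------------------------------------------

def plot_probability_strip(report: CVReport, path: str | Path) -> None:
    """Per-sample class probabilities ordered by true label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.per_sample.sort_values("true_label", kind="stable")
    x = np.arange(len(df))
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(x, 1 - df["prob_positive"], s=8, c="red", label="P(class 0)")
    ax.scatter(x, df["prob_positive"], s=8, c="green", label="P(class 1)")
    boundary = int((df["true_label"] == 0).sum())
    ax.axvline(boundary - 0.5, ls=":", c="k")
    ax.set_xlabel("samples (ordered by true class)")
    ax.set_ylabel("probability")
    ax.set_title(report.classifier.kind)
    ax.legend(loc="center right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(reports: Sequence[CVReport], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        pts = np.asarray(rep.roc)
        ax.plot(pts[:, 0], pts[:, 1], label=f"{rep.classifier.kind} (AUC {rep.metrics['auc']:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
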