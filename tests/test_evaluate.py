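import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from conftest import fm_from_array
from prc2lnc.classify import ClassifierSpec
from prc2lnc.evaluate import (
    confusion_metrics,
    empirical_auc,
    loocv,
    roc_points,
    trapezoid_area,
)


# ---------------------------------------------------------------- AUC / ROC

@pytest.mark.parametrize(
    "probs,labels,expected",
    [
        ([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5], [1, 0], 0.5),
        ([0.9, 0.2, 0.5, 0.1], [1, 1, 0, 0], 3 / 4),
    ],
)
def test_empirical_auc_examples(probs, labels, expected):
    assert empirical_auc(probs, labels) == pytest.approx(expected)


def test_empirical_auc_matches_sklearn_midranks():
    rng = np.random.default_rng(0)
    for _ in range(50):
        labels = rng.integers(0, 2, 25)
        if labels.min() == labels.max():
            continue
        probs = np.round(rng.random(25), 1)  # coarse grid forces ties
        assert empirical_auc(probs, labels) == pytest.approx(
            roc_auc_score(labels, probs), abs=1e-12
        )


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        empirical_auc([0.1, 0.9], [1, 1])


def test_roc_endpoints_and_perfect_separation():
    pts = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
    assert (0.0, 1.0) in pts


def test_roc_all_tied_scores_is_diagonal():
    pts = roc_points([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert pts == [(0.0, 0.0), (1.0, 1.0)]
    assert trapezoid_area(pts) == pytest.approx(0.5)


def test_roc_trapezoid_equals_mann_whitney_auc():
    rng = np.random.default_rng(123)
    for _ in range(100):
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            continue
        probs = np.round(rng.random(20), 1)
        pts = roc_points(probs, labels)
        fprs = [p[0] for p in pts]
        tprs = [p[1] for p in pts]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)  # monotone
        assert trapezoid_area(pts) == pytest.approx(empirical_auc(probs, labels), abs=1e-9)


# ---------------------------------------------------------------- metrics

def test_confusion_example_counts():
    # labels (1,1,1,0,0), predictions (1,0,1,0,1): TP=2 FN=1 TN=1 FP=1
    m = confusion_metrics([1, 1, 1, 0, 0], [1, 0, 1, 0, 1])
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(1 / 2)
    assert m["accuracy"] == pytest.approx(3 / 5)
    assert m["misclassification"] == pytest.approx(2 / 5)


def test_all_positive_predictor_identity():
    labels = [1, 1, 0, 0, 0, 1]
    m = confusion_metrics(labels, [1] * 6)
    assert m["sensitivity"] == 1.0
    assert m["specificity"] == 0.0
    assert m["accuracy"] == pytest.approx(np.mean(labels))


def test_accuracy_misclassification_complementary_exactly():
    rng = np.random.default_rng(5)
    for _ in range(50):
        t = rng.integers(0, 2, 17)
        p = rng.integers(0, 2, 17)
        m = confusion_metrics(t, p)
        assert m["accuracy"] + m["misclassification"] == 1.0


def test_balanced_accuracy_is_mean_of_sens_spec():
    rng = np.random.default_rng(6)
    t = np.r_[np.ones(30, int), np.zeros(30, int)]
    for _ in range(20):
        p = rng.integers(0, 2, 60)
        m = confusion_metrics(t, p)
        assert m["accuracy"] == pytest.approx(
            (m["sensitivity"] + m["specificity"]) / 2, abs=1e-9
        )


# ---------------------------------------------------------------- LOOCV

def _separable(n=8, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.5, (n, 3)), rng.normal(6, 0.5, (n, 3))])
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    return fm_from_array(X, y)


@pytest.mark.parametrize("kind", ["svm_linear", "sda", "logistic_regression"])
def test_loocv_perfect_on_separable_data(kind):
    report = loocv(_separable(), ClassifierSpec(kind), seed=0)
    m = report.metrics
    assert m["sensitivity"] == m["specificity"] == m["accuracy"] == m["auc"] == 1.0
    assert m["misclassification"] == 0.0


def test_loocv_row_order_invariant():
    fm = _separable(n=6, seed=3)
    rep = loocv(fm, ClassifierSpec("logistic_regression"), seed=0)
    perm = np.random.default_rng(1).permutation(len(fm))
    rep_perm = loocv(fm.subset_samples(perm), ClassifierSpec("logistic_regression"), seed=0)
    a = rep.per_sample.sort_index()
    b = rep_perm.per_sample.sort_index()
    np.testing.assert_allclose(a["prob_positive"], b["prob_positive"], atol=1e-9)


def test_loocv_nested_tuning_records_grid_members():
    fm = _separable(n=6)
    grid = (0.01, 0.1, 1.0)
    rep = loocv(fm, ClassifierSpec("svm_linear"), nested_tuning=True, cost_grid=grid, seed=0)
    assert len(rep.tuned_costs) == len(fm)
    assert set(rep.tuned_costs) <= set(grid)


def test_loocv_metric_identities_hold():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(14, 4))  # pure noise -> imperfect predictions
    y = np.r_[np.ones(7, int), np.zeros(7, int)]
    rep = loocv(fm_from_array(X, y), ClassifierSpec("sda"), seed=0)
    m = rep.metrics
    assert m["accuracy"] + m["misclassification"] == 1.0
    assert m["accuracy"] == pytest.approx((m["sensitivity"] + m["specificity"]) / 2, abs=1e-9)
    assert trapezoid_area(rep.roc) == pytest.approx(m["auc"], abs=1e-9)


def test_loocv_rejects_tiny_or_single_class_input():
    with pytest.raises(ValueError):
        loocv(fm_from_array(np.zeros((3, 2)), [1, 0, 1]), ClassifierSpec("sda"))
    with pytest.raises(ValueError):
        loocv(fm_from_array(np.zeros((6, 2)), [1, 1, 1, 1, 1, 0]), ClassifierSpec("sda"))


def test_loocv_report_serializes(tmp_path):
    rep = loocv(_separable(n=5), ClassifierSpec("logistic_regression"), seed=0)
    path = tmp_path / "cv.json"
    rep.to_json(path)
    import json

    doc = json.loads(path.read_text())
    assert doc["metrics"]["accuracy"] == 1.0
    assert len(doc["per_sample"]) == 10
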