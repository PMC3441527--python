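"""The four classifier families: linear SVM, SDA, random forest, logistic
regression.

All four behave reasonably when the number of features approaches the number
of samples, which is the regime of the lncRNA problem (hundreds of selected
k-word/PWM features for ~600 transcripts).  Shrinkage discriminant analysis
(SDA) is implemented here directly: a linear discriminant rule whose pooled
covariance uses James–Stein-type shrinkage of the per-feature variances
toward their median and of the correlations toward zero, with analytic
data-driven intensities, so the rule stays well-defined when features
outnumber samples.  Standardization is applied to logistic regression only by
default; the other classifiers see raw feature values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

KINDS = ("svm_linear", "sda", "random_forest", "logistic_regression")

#: default cost grid for nested SVM tuning
DEFAULT_COST_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_INNER_FOLDS = 5


class FeatureMismatchError(ValueError):
    """Query matrix features do not match the features bound at fit time."""


@dataclass
class ClassifierSpec:
    """Which classifier to train and with which hyperparameters.

    ``params`` keys by kind: svm_linear: ``C``; random_forest: ``n_trees``,
    ``seed``; logistic_regression: ``C``; sda: ``var_shrinkage``,
    ``cor_shrinkage`` (floats in [0, 1] or "auto").  ``standardize`` defaults
    to True for logistic regression only.
    """

    kind: str
    params: dict = field(default_factory=dict)
    standardize: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.standardize is None:
            self.standardize = self.kind == "logistic_regression"
        c = self.params.get("C")
        if c is not None and c <= 0:
            raise ValueError("C must be > 0")
        n_trees = self.params.get("n_trees")
        if n_trees is not None and n_trees < 1:
            raise ValueError("n_trees must be >= 1")


class _PlattScaledSVC:
    """Linear SVM whose probabilities come from a logistic (Platt) link
    fitted to decision values predicted on training folds.

    The decision rule is the SVM's own; the link only maps margins to
    calibrated probabilities.  Deterministic given ``random_state``.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PlattScaledSVC":
        self.svc_ = SVC(kernel="linear", C=self.C)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        folds = min(5, int(np.bincount(y, minlength=2).min()))
        if folds >= 2:
            dv = cross_val_predict(
                SVC(kernel="linear", C=self.C),
                X,
                y,
                cv=StratifiedKFold(folds, shuffle=True, random_state=self.random_state),
                method="decision_function",
            )
        else:  # too few samples for held-out decision values
            dv = self.svc_.decision_function(X)
        self.link_ = LogisticRegression(C=1.0, max_iter=1000)
        self.link_.fit(dv.reshape(-1, 1), y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.predict(X)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        dv = self.svc_.decision_function(X)
        return self.link_.predict_proba(dv.reshape(-1, 1))


class _ShrinkageDiscriminant:
    """Linear discriminant with shrunken pooled covariance.

    The pooled within-class covariance S is decomposed into standard
    deviations and correlations.  Variances are shrunk toward their median,
    correlations toward zero:

        v*_k = lam_v * median(v) + (1 - lam_v) * v_k
        R*   = (1 - lam_c) * R + lam_c * I

    with intensities estimated analytically (ratio of the summed sampling
    variances of the entries to their summed squared deviation from the
    target), clipped to [0, 1].  Classification uses the usual linear
    discriminant scores with class priors; when features outnumber samples
    the correlation-matrix solve goes through the Woodbury identity on the
    n x n Gram matrix, never forming a p x p inverse.
    """

    def __init__(self, var_shrinkage="auto", cor_shrinkage="auto"):
        self.var_shrinkage = var_shrinkage
        self.cor_shrinkage = cor_shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ShrinkageDiscriminant":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("SDA implemented for two classes")
        n, p = X.shape
        g = self.classes_.size
        self.means_ = np.vstack([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([(y == c).mean() for c in self.classes_])
        Xc = X.copy()
        for i, c in enumerate(self.classes_):
            Xc[y == c] -= self.means_[i]
        dof = max(n - g, 1)
        v = (Xc ** 2).sum(axis=0) / dof
        v = np.where(v <= 0, np.finfo(float).tiny, v)

        # analytic variance shrinkage toward the median
        if self.var_shrinkage == "auto":
            target = np.median(v)
            w = Xc ** 2
            var_v = n / (n - 1.0) ** 3 * ((w - w.mean(axis=0)) ** 2).sum(axis=0) if n > 1 else v * 0
            denom = ((v - target) ** 2).sum()
            lam_v = 1.0 if denom <= 0 else float(np.clip(var_v.sum() / denom, 0.0, 1.0))
        else:
            lam_v = float(self.var_shrinkage)
            target = np.median(v)
        v_star = lam_v * target + (1.0 - lam_v) * v
        self.lambda_var_ = lam_v
        self.sd_ = np.sqrt(v_star)

        # standardized residuals; correlations R = Xs' Xs / dof
        Xs = Xc / self.sd_
        if self.cor_shrinkage == "auto":
            lam_c = self._analytic_cor_shrinkage(Xs, dof)
        else:
            lam_c = float(self.cor_shrinkage)
        self.lambda_cor_ = float(np.clip(lam_c, 0.0, 1.0))

        self._Xs = Xs
        self._dof = dof
        # discriminant directions: beta_c = Sigma*^-1 mu_c with
        # Sigma* = D^{1/2} R* D^{1/2}
        self._betas = np.vstack(
            [self._sigma_solve(self.means_[i]) for i in range(g)]
        )
        self._offsets = np.array(
            [
                -0.5 * self.means_[i] @ self._betas[i] + np.log(self.priors_[i])
                for i in range(g)
            ]
        )
        return self

    @staticmethod
    def _analytic_cor_shrinkage(Xs: np.ndarray, dof: int) -> float:
        """lam_c = sum Var(r_ij) / sum r_ij^2 over i != j, via Gram tricks."""
        n = Xs.shape[0]
        if n < 3:
            return 1.0
        G = Xs @ Xs.T  # n x n
        sq_rows = (Xs ** 2).sum(axis=1)  # per-sample sum_i xs_ki^2
        # sum_{ij} (sum_k w_kij)^2 = tr(G G) ; w_kij = xs_ki xs_kj
        total_sum_sq = float(np.sum(G * G))
        diag_sum_sq = float(np.sum((Xs ** 2).sum(axis=0) ** 2))
        off_sum_sq = total_sum_sq - diag_sum_sq  # sum_{i!=j} (sum_k w)^2
        # sum_{ij} sum_k w_kij^2 = sum_k (sum_i xs_ki^2)^2
        total_w2 = float(np.sum(sq_rows ** 2))
        diag_w2 = float(np.sum((Xs ** 4).sum(axis=0)))
        off_w2 = total_w2 - diag_w2
        # Var(r_ij) ~ n/(n-1)^3 * (sum_k w^2 - (sum_k w)^2 / n), r = sum_k w / dof
        var_sum = n / (n - 1.0) ** 3 * (off_w2 - off_sum_sq / n)
        r2_sum = off_sum_sq / dof ** 2
        if r2_sum <= 0:
            return 1.0
        return float(np.clip(var_sum / r2_sum, 0.0, 1.0))

    def _sigma_solve(self, b: np.ndarray) -> np.ndarray:
        """Solve Sigma* x = b with Sigma* = D^{1/2} R* D^{1/2}."""
        z = b / self.sd_
        x = self._cor_solve(z)
        return x / self.sd_

    def _cor_solve(self, z: np.ndarray) -> np.ndarray:
        """Solve R* x = z, R* = lam_c I + (1 - lam_c) Xs' Xs / dof."""
        lam = self.lambda_cor_
        Xs, dof = self._Xs, self._dof
        n, p = Xs.shape
        if lam < 1e-12 or p <= n:
            R = Xs.T @ Xs / dof
            R_star = (1.0 - lam) * R + lam * np.eye(p)
            try:
                return np.linalg.solve(R_star, z)
            except np.linalg.LinAlgError:
                return np.linalg.lstsq(R_star, z, rcond=None)[0]
        # Woodbury: (lam I + U U')^{-1} z, U = sqrt((1-lam)/dof) Xs'
        scale = (1.0 - lam) / dof
        M = lam * np.eye(n) + scale * (Xs @ Xs.T)
        t = np.linalg.solve(M, Xs @ z)
        return (z - scale * (Xs.T @ t)) / lam

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self._betas.T + self._offsets

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(np.asarray(X, dtype=float))
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(np.asarray(X, float)), axis=1)]


@dataclass
class TrainedModel:
    """A fitted classifier bound to an ordered feature-name list."""

    spec: ClassifierSpec
    feature_names: list[str]
    estimator: object
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    def _check_features(self, matrix: FeatureMatrix) -> np.ndarray:
        if matrix.feature_names != self.feature_names:
            missing = [n for n in self.feature_names if n not in matrix.feature_names]
            extra = [n for n in matrix.feature_names if n not in self.feature_names]
            if missing or extra:
                raise FeatureMismatchError(
                    f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            # same names, different order: realign
            return matrix.data[self.feature_names].to_numpy()
        return matrix.values

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is not None:
            return (X - self.mean_) / self.sd_
        return X

    def predict_proba(self, matrix: FeatureMatrix) -> np.ndarray:
        """P(class = positive) per sample, in matrix row order."""
        X = self._transform(self._check_features(matrix))
        proba = self.estimator.predict_proba(X)
        classes = list(getattr(self.estimator, "classes_", [0, 1]))
        return proba[:, classes.index(1)]

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        """0/1 calls; the tie at probability 0.5 goes to the positive class."""
        return (self.predict_proba(matrix) >= 0.5).astype(int)


def _make_estimator(spec: ClassifierSpec, seed: int | None):
    if spec.kind == "svm_linear":
        return _PlattScaledSVC(
            C=spec.params.get("C", 1.0),
            random_state=0 if seed is None else seed,
        )
    if spec.kind == "sda":
        return _ShrinkageDiscriminant(
            var_shrinkage=spec.params.get("var_shrinkage", "auto"),
            cor_shrinkage=spec.params.get("cor_shrinkage", "auto"),
        )
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.params.get("n_trees", 500),
            max_features="sqrt",
            random_state=spec.params.get("seed", seed if seed is not None else 0),
        )
    if spec.kind == "logistic_regression":
        return LogisticRegression(
            C=spec.params.get("C", 1.0), max_iter=5000, solver="lbfgs"
        )
    raise AssertionError(spec.kind)


def fit(spec: ClassifierSpec, matrix: FeatureMatrix, seed: int | None = None) -> TrainedModel:
    """Train one classifier on a labeled feature matrix.

    Deterministic for svm_linear / sda / logistic_regression given fixed
    inputs, and for random_forest given its seed.  When ``spec.standardize``,
    per-feature mean/SD are estimated on the training data only and stored on
    the model; a zero-variance feature gets SD 1 with a warning.
    """
    if matrix.labels is None:
        raise ValueError("fit requires a labeled matrix")
    if len(np.unique(matrix.labels)) < 2:
        raise ValueError("both classes must be present")
    X = matrix.values
    mean = sd = None
    if spec.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            logger.warning("%d zero-variance features; SD set to 1 for standardization", zero.sum())
            sd = np.where(zero, 1.0, sd)
        X = (X - mean) / sd
    est = _make_estimator(spec, seed)
    est.fit(X, matrix.labels)
    return TrainedModel(spec, matrix.feature_names, est, mean, sd)


def tune_svm_cost(
    matrix: FeatureMatrix,
    grid: Sequence[float] = DEFAULT_COST_GRID,
    inner_folds: int = DEFAULT_INNER_FOLDS,
    seed: int = 0,
) -> float:
    """Choose the linear-SVM cost with the smallest stratified inner-CV
    misclassification rate; ties go to the smallest C.
    """
    if not grid:
        raise ValueError("cost grid must be nonempty")
    if any(c <= 0 for c in grid):
        raise ValueError("costs must be > 0")
    if matrix.labels is None:
        raise ValueError("tuning requires labels")
    y = matrix.labels
    X = matrix.values
    counts = np.bincount(y, minlength=2)
    folds = min(inner_folds, counts.min())
    if folds < 2:
        raise ValueError("cannot stratify: a class has fewer than 2 samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_c, best_err = None, np.inf
    for c in sorted(grid):
        errs = 0
        total = 0
        for train_idx, test_idx in splits:
            clf = SVC(kernel="linear", C=c)
            clf.fit(X[train_idx], y[train_idx])
            pred = clf.predict(X[test_idx])
            errs += int((pred != y[test_idx]).sum())
            total += len(test_idx)
        err = errs / total
        if err < best_err - 1e-12:
            best_c, best_err = c, err
    return float(best_c)


# ---------------------------------------------------------------------------
# model serialization (text container for linear models; pickle otherwise)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model.

    Linear models (svm_linear, logistic_regression, sda) are written as a
    versioned JSON document carrying the spec, feature names, standardization
    parameters and fitted coefficients.  Random forests fall back to a pickle
    sidecar referenced from the JSON header.
    """
    path = Path(path)
    doc: dict = {
        "format_version": _FORMAT_VERSION,
        "spec": {"kind": model.spec.kind, "params": model.spec.params,
                 "standardize": model.spec.standardize},
        "feature_names": model.feature_names,
        "mean": None if model.mean_ is None else model.mean_.tolist(),
        "sd": None if model.sd_ is None else model.sd_.tolist(),
    }
    est = model.estimator
    if model.spec.kind == "svm_linear":
        doc["coef"] = est.svc_.coef_.ravel().tolist()
        doc["intercept"] = float(est.svc_.intercept_[0])
        doc["link_coef"] = float(est.link_.coef_[0, 0])
        doc["link_intercept"] = float(est.link_.intercept_[0])
        doc["C"] = est.C
    elif model.spec.kind == "logistic_regression":
        doc["coef"] = est.coef_.ravel().tolist()
        doc["intercept"] = float(est.intercept_[0])
    elif model.spec.kind == "sda":
        doc["betas"] = est._betas.tolist()
        doc["offsets"] = est._offsets.tolist()
        doc["classes"] = est.classes_.tolist()
        doc["sd_pooled"] = est.sd_.tolist()
        doc["lambda_var"] = est.lambda_var_
        doc["lambda_cor"] = est.lambda_cor_
    else:
        doc["payload"] = "pickle"
    if doc.get("payload") == "pickle":
        import pickle

        sidecar = path.with_suffix(path.suffix + ".pkl")
        with open(sidecar, "wb") as fh:
            pickle.dump(est, fh)
        doc["payload_path"] = sidecar.name
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc["format_version"] != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc['format_version']}")
    spec = ClassifierSpec(
        doc["spec"]["kind"], doc["spec"]["params"], doc["spec"]["standardize"]
    )
    if doc.get("payload") == "pickle":
        import pickle

        with open(path.parent / doc["payload_path"], "rb") as fh:
            est = pickle.load(fh)
    elif spec.kind == "svm_linear":
        est = _PlattScaledSVC(C=doc.get("C", 1.0))
        est.classes_ = np.array([0, 1])

        class _Linear:
            def __init__(self, coef, intercept):
                self.coef = np.asarray(coef)
                self.intercept = intercept
                self.classes_ = np.array([0, 1])

            def decision_function(self, X):
                return X @ self.coef + self.intercept

            def predict(self, X):
                return (self.decision_function(X) >= 0).astype(int)

        est.svc_ = _Linear(doc["coef"], doc["intercept"])
        link = LogisticRegression()
        link.classes_ = np.array([0, 1])
        link.coef_ = np.array([[doc["link_coef"]]])
        link.intercept_ = np.array([doc["link_intercept"]])
        est.link_ = link
    elif spec.kind == "logistic_regression":
        est = LogisticRegression()
        est.classes_ = np.array([0, 1])
        est.coef_ = np.array([doc["coef"]])
        est.intercept_ = np.array([doc["intercept"]])
    elif spec.kind == "sda":
        est = _ShrinkageDiscriminant()
        est._betas = np.array(doc["betas"])
        est._offsets = np.array(doc["offsets"])
        est.classes_ = np.array(doc["classes"])
        est.sd_ = np.array(doc["sd_pooled"])
        est.lambda_var_ = doc["lambda_var"]
        est.lambda_cor_ = doc["lambda_cor"]
    else:
        raise ValueError(f"cannot reconstruct {spec.kind} from JSON alone")
    mean = None if doc["mean"] is None else np.array(doc["mean"])
    sd = None if doc["sd"] is None else np.array(doc["sd"])
    return TrainedModel(spec, doc["feature_names"], est, mean, sd)
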