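"""Ridge-based sex classification and age regression on mandible descriptors.

Ridge regularization handles the strong collinearity between mandible
measurements and shape features. Classification is a ridge-penalized
linear model on ±1 labels with a sign decision at threshold 0. Features
are standardized; the regularization strength is chosen by seeded 5-fold
cross-validation over a 13-point logarithmic grid 1e-3..1e3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

ALPHA_GRID = np.logspace(-3, 3, 13)


@dataclass
class RidgeModel:
    task: str                       # "sex" | "age"
    coef: np.ndarray
    intercept: float
    alpha: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    descriptor_kind: str | None = None
    seed: int = 0
    classes: tuple | None = None    # (negative, positive) for sex

    def _standardize(self, X):
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def decision(self, X) -> np.ndarray:
        return self._standardize(X) @ self.coef + self.intercept

    def predict(self, X) -> np.ndarray:
        d = self.decision(X)
        if self.task == "sex":
            return np.where(d >= 0, self.classes[1], self.classes[0])
        return d

    def save(self, path) -> None:
        doc = {
            "task": self.task,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "alpha": self.alpha,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "descriptor_kind": self.descriptor_kind,
            "seed": self.seed,
            "classes": list(self.classes) if self.classes else None,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path) -> "RidgeModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            task=doc["task"],
            coef=np.asarray(doc["coef"], dtype=float),
            intercept=float(doc["intercept"]),
            alpha=float(doc["alpha"]),
            feature_mean=np.asarray(doc["feature_mean"], dtype=float),
            feature_scale=np.asarray(doc["feature_scale"], dtype=float),
            descriptor_kind=doc.get("descriptor_kind"),
            seed=int(doc.get("seed", 0)),
            classes=tuple(doc["classes"]) if doc.get("classes") else None,
        )


@dataclass
class ClassificationReport:
    accuracy: float
    f1: dict                 # class -> F1
    confusion: dict          # class -> {TP, FP, FN, TN}
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1": self.f1,
            "confusion": self.confusion, "n": self.n,
        }


@dataclass
class RegressionReport:
    mae: float
    mae_sd: float
    se: float
    r2: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae, "mae_sd": self.mae_sd,
            "se": self.se, "r2": self.r2, "n": self.n,
        }


def fit_model(
    X, y, task: str, seed: int = 0, descriptor_kind: str | None = None,
    alphas=ALPHA_GRID,
) -> RidgeModel:
    """Fit a ridge model with internal CV choice of regularization.

    For ``task='sex'`` the two label values are mapped to ±1 and CV picks
    the alpha with the best fold-mean accuracy; for ``task='age'`` CV
    minimizes fold-mean squared error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with one label per row")
    if len(X) < 10:
        raise ValueError("need at least 10 samples to fit")
    if np.isnan(X).any():
        raise ValueError("missing values in descriptor matrix")
    classes = None
    if task == "sex":
        classes = tuple(sorted(np.unique(y).tolist()))
        if len(classes) != 2:
            raise ValueError(
                f"sex classification needs exactly 2 classes, got {classes}"
            )
        yy = np.where(y == classes[1], 1.0, -1.0)
        splitter = StratifiedKFold(5, shuffle=True, random_state=seed)
        folds = list(splitter.split(X, y))
    elif task == "age":
        yy = y.astype(float)
        splitter = KFold(5, shuffle=True, random_state=seed)
        folds = list(splitter.split(X))
    else:
        raise ValueError(f"unknown task {task!r}")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mu) / sd

    best_alpha, best_score = None, -np.inf
    for alpha in alphas:
        scores = []
        for tr, te in folds:
            r = Ridge(alpha=alpha).fit(Z[tr], yy[tr])
            pred = r.predict(Z[te])
            if task == "sex":
                scores.append(float(np.mean(np.sign(pred) == np.sign(yy[te]))))
            else:
                scores.append(-float(np.mean((pred - yy[te]) ** 2)))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_alpha = score, float(alpha)

    final = Ridge(alpha=best_alpha).fit(Z, yy)
    return RidgeModel(
        task=task,
        coef=np.asarray(final.coef_, dtype=float).ravel(),
        intercept=float(final.intercept_),
        alpha=best_alpha,
        feature_mean=mu,
        feature_scale=sd,
        descriptor_kind=descriptor_kind,
        seed=seed,
        classes=classes,
    )


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 of one class from its confusion counts: TP / (TP + (FP+FN)/2)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp == 0 and fp == 0 and fn == 0:
        warnings.warn("F1 undefined with all-zero counts; returning 0.0",
                      stacklevel=2)
        return 0.0
    return tp / (tp + 0.5 * (fp + fn))


def evaluate(model: RidgeModel, X, y):
    """Held-out evaluation: accuracy + per-class F1, or MAE/SE/R²."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] != len(model.coef):
        raise ValueError(
            f"descriptor length {X.shape[1]} != model length {len(model.coef)}"
        )
    pred = model.predict(X)
    if model.task == "sex":
        f1, confusion = {}, {}
        for cls in model.classes:
            tp = int(np.sum((pred == cls) & (y == cls)))
            fp = int(np.sum((pred == cls) & (y != cls)))
            fn = int(np.sum((pred != cls) & (y == cls)))
            tn = int(np.sum((pred != cls) & (y != cls)))
            confusion[str(cls)] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
            f1[str(cls)] = f1_score(tp, fp, fn)
        return ClassificationReport(
            accuracy=float(np.mean(pred == y)),
            f1=f1, confusion=confusion, n=len(y),
        )
    resid = y.astype(float) - pred
    abs_err = np.abs(resid)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.astype(float).mean()) ** 2).sum())
    n = len(y)
    return RegressionReport(
        mae=float(abs_err.mean()),
        mae_sd=float(abs_err.std()),
        se=float(np.sqrt(ss_res / max(n - 2, 1))),
        r2=1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0,
        n=n,
        residuals=resid,
    )


def cross_validated_accuracy(X, y, seed: int = 0, folds: int = 5) -> float:
    """Stratified k-fold CV accuracy of the ridge sex classifier."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        m = fit_model(X[tr], y[tr], "sex", seed=seed)
        accs.append(evaluate(m, X[te], y[te]).accuracy)
    return float(np.mean(accs))


def train_test_evaluate(
    X, y, task: str, seed: int = 0, test_size: float = 0.2,
    descriptor_kind: str | None = None,
):
    """Seeded (stratified for sex) train/test split, fit, and evaluate."""
    y = np.asarray(y)
    strat = y if task == "sex" else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        np.asarray(X, dtype=float), y, test_size=test_size,
        random_state=seed, stratify=strat,
    )
    model = fit_model(X_tr, y_tr, task, seed=seed,
                      descriptor_kind=descriptor_kind)
    return model, evaluate(model, X_te, y_te)
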