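"""Diagnosis prediction from microstate features with leave-one-out CV.

Feature vectors (24 per band: duration/occurrence/coverage for each map plus
12 transition percentages) are z-scored, optionally compressed by PCA keeping
99% of variance, and fed to multinomial/logistic regression, LDA, QDA or an
RBF SVM.  By default every preprocessing step is refit inside each training
fold so the held-out subject never leaks into scaling or PCA; a deliberately
leaky ``paper_mode`` that fits them once on the full matrix is available for
comparison with analyses that did not specify fold-internal fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["FeatureMatrix", "ClassifierResult", "build_feature_matrix",
           "pca_compress", "loo_cv", "MODELS"]

MAP_FEATURES = ("duration", "occurrence", "coverage")

#: models for which PCA compression is applied by default (LDA and SVM run on
#: the uncompressed z-scored features)
MODELS = {"multinomial", "logistic", "lda", "qda", "svm"}
_PCA_DEFAULT = {"multinomial": True, "logistic": True, "qda": True,
                "lda": False, "svm": False}


@dataclass
class FeatureMatrix:
    X: np.ndarray                  # subjects x features, z-scored columns
    feature_names: tuple[str, ...]
    band_tags: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ClassifierResult:
    model: str
    classes: tuple[str, ...]
    accuracy_pct: float
    sensitivity_pct: dict[str, float]
    specificity_pct: float
    predictions: np.ndarray
    confusion: np.ndarray = field(repr=False)
    n_error_folds: int = 0


def feature_columns(band: str, map_labels=("A", "B", "C", "D")) -> list[str]:
    """Canonical 24-column order for one band's feature block."""
    cols = [f"{band}_{feat}_{m}" for m in map_labels for feat in MAP_FEATURES]
    cols += [f"{band}_trans_{a}_to_{b}_pct" for a in map_labels
             for b in map_labels if a != b]
    return cols


def build_feature_matrix(table: pd.DataFrame, bands="broadband",
                         map_labels=("A", "B", "C", "D")) -> FeatureMatrix:
    """Assemble the z-scored subjects x features matrix from the cohort table.

    ``bands`` is ``"broadband"`` (24 columns), ``"all"`` (broadband + delta/
    theta/alpha/beta = 120 columns), or an explicit list of band names.
    """
    if bands == "broadband":
        band_list = ["broadband"]
    elif bands == "all":
        band_list = ["broadband", "delta", "theta", "alpha", "beta"]
    else:
        band_list = list(bands)
    names, tags = [], []
    for band in band_list:
        cols = feature_columns(band, map_labels)
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing feature columns for band {band!r}: "
                             f"{missing[:4]}{'...' if len(missing) > 4 else ''}")
        names.extend(cols)
        tags.extend([band] * len(cols))
    X = table[names].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = table.loc[np.isnan(X).any(axis=1)]
        ids = (bad["subject_id"].tolist() if "subject_id" in bad.columns
               else bad.index.tolist())
        raise ValueError(f"missing feature values for subjects {ids}")
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    ids = (tuple(table["subject_id"]) if "subject_id" in table.columns
           else tuple(map(str, table.index)))
    return FeatureMatrix(X=X, feature_names=tuple(names), band_tags=tuple(tags),
                         subject_ids=ids)


def pca_compress(X: np.ndarray, retained_variance: float = 0.99
                 ) -> tuple[np.ndarray, PCA]:
    """Project onto the fewest leading components reaching the variance target."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 subjects")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("constant feature matrix has no principal components")
    pca = PCA(n_components=retained_variance, svd_solver="full")
    return pca.fit_transform(X), pca


def _make_estimator(model: str, seed: int):
    if model in ("multinomial", "logistic"):
        # near-unpenalized maximum likelihood; the tiny ridge keeps separable
        # LOO folds finite
        return LogisticRegression(C=1e6, max_iter=5000, solver="lbfgs")
    if model == "lda":
        return LinearDiscriminantAnalysis()
    if model == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6)
    if model == "svm":
        grid = {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]}
        return GridSearchCV(SVC(kernel="rbf", random_state=seed), grid, cv=3)
    raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")


def loo_cv(X: np.ndarray, y, model: str = "multinomial",
           use_pca: bool | None = None, retained_variance: float = 0.99,
           seed: int = 0, paper_mode: bool = False,
           control_label: str | None = None) -> ClassifierResult:
    """Leave-one-out cross-validated classification.

    Each subject is predicted by a pipeline (z-scoring, optional PCA, model)
    fitted on all other subjects.  ``paper_mode=True`` instead fits z-scoring
    and PCA once on the full matrix (leaky; comparison mode only).
    Specificity is the correct-classification rate of the control class
    (``"HC"`` when present, else the first class alphabetically).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
    if use_pca is None:
        use_pca = _PCA_DEFAULT[model]
    n = len(y)

    if paper_mode:
        Xp = StandardScaler().fit_transform(X)
        if use_pca:
            Xp, _ = pca_compress(Xp, retained_variance)

        def fold(i):
            mask = np.arange(n) != i
            est = _make_estimator(model, seed)
            est.fit(Xp[mask], y[mask])
            return est.predict(Xp[i:i + 1])[0]
    else:
        def fold(i):
            mask = np.arange(n) != i
            steps = [("scale", StandardScaler())]
            if use_pca:
                steps.append(("pca", PCA(n_components=retained_variance,
                                         svd_solver="full")))
            steps.append(("model", _make_estimator(model, seed)))
            pipe = Pipeline(steps)
            pipe.fit(X[mask], y[mask])
            return pipe.predict(X[i:i + 1])[0]

    predictions = np.empty(n, dtype=object)
    n_errors = 0
    for i in range(n):
        try:
            predictions[i] = fold(i)
        except Exception:  # non-convergent / degenerate fold counts as a miss
            predictions[i] = "__error__"
            n_errors += 1
    correct = predictions == y
    accuracy = 100.0 * float(np.mean(correct))
    sensitivity = {c: 100.0 * float(np.mean(correct[y == c])) for c in classes}
    if control_label is None:
        control_label = "HC" if "HC" in classes else classes[0]
    specificity = sensitivity[control_label]
    conf = confusion_matrix(y, np.where(predictions == "__error__",
                                        "(error)", predictions).astype(str),
                            labels=[*classes, "(error)"])
    return ClassifierResult(model=model, classes=classes, accuracy_pct=accuracy,
                            sensitivity_pct=sensitivity,
                            specificity_pct=specificity,
                            predictions=predictions.astype(str),
                            confusion=conf, n_error_folds=n_errors)
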