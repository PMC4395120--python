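"""Dimension reduction and cross-validated classification.

The feature matrix (one row per stimulus epoch) is standardized, reduced
to 25 principal components, and evaluated with three classifiers — kNN,
Gaussian naive Bayes and linear discriminant analysis — under
leave-one-out cross-validation.  Two leakage regimes are supported:

* ``strict`` (default): standardization and PCA are refit inside every
  fold, so the held-out row never influences the transform;
* ``pooled``: the transform is fit once on all rows before
  cross-validation, mirroring a common (leakier) practice of fitting the
  reduction on the full data set.

SAM reports are classified the same way but on their raw three
dimensions (arousal, valence, dominance) with LDA, without reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import InvalidArgumentError, InvalidDesignError
from .types import CVResult

N_COMPONENTS = 25
#: heuristic neighbourhood sizes for the two four-class tasks
KNN_K = {"archetypes": 20, "emotions": 25}

#: small ridge on the pooled LDA covariance for degenerate inputs
LDA_SHRINKAGE = 1e-4


@dataclass(frozen=True)
class ReductionSummary:
    """What the fitted reduction did: per-component explained variance."""

    n_components: int
    explained_variance_ratio: np.ndarray

    @property
    def total_explained(self) -> float:
        return float(self.explained_variance_ratio.sum())


def reduce_dimensions(
    matrix: pd.DataFrame | np.ndarray, n_components: int = N_COMPONENTS
) -> tuple[pd.DataFrame | np.ndarray, ReductionSummary]:
    """Standardize columns and project onto the leading principal
    components (scores ordered by non-increasing explained variance)."""
    X = np.asarray(matrix, dtype=float)
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise InvalidArgumentError(
            f"n_components={n_components} exceeds min(rows-1, columns)"
        )
    pipe = Pipeline(
        [("scale", StandardScaler()), ("pca", PCA(n_components=n_components))]
    )
    scores = pipe.fit_transform(X)
    summary = ReductionSummary(
        n_components, pipe.named_steps["pca"].explained_variance_ratio_.copy()
    )
    if isinstance(matrix, pd.DataFrame):
        scores = pd.DataFrame(
            scores,
            index=matrix.index,
            columns=[f"pc_{i + 1:02d}" for i in range(n_components)],
        )
    return scores, summary


def make_classifier(name: str, k: int = 20):
    """The three study classifiers by name: ``knn`` (k neighbours),
    ``naive_bayes`` (Gaussian), ``lda`` (ridge-regularized)."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=k)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=LDA_SHRINKAGE)
    raise InvalidArgumentError(f"unknown classifier {name!r}")


def _confusion(classes, y_true, y_pred) -> np.ndarray:
    classes = list(classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[lut[t], lut[p]] += 1
    return cm


def loocv_classify(
    matrix: pd.DataFrame | np.ndarray,
    labels,
    classifier: str = "knn",
    k: int = 20,
    n_components: int | None = N_COMPONENTS,
    leakage_mode: str = "strict",
) -> CVResult:
    """Leave-one-out evaluation of one classifier.

    ``n_components=None`` skips reduction (used for the 3-column SAM
    matrix).  In ``strict`` mode the standardizer and PCA are refit on
    the training rows of every fold; ``pooled`` fits them once on all
    rows first.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise InvalidArgumentError("matrix and labels disagree on rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InvalidDesignError("need at least two classes")
    if np.any(counts < 2):
        raise InvalidDesignError(
            "every class needs >= 2 samples for leave-one-out"
        )
    if classifier == "knn" and k >= X.shape[0] - 1:
        raise InvalidArgumentError("k must be smaller than the training size")
    if leakage_mode not in ("strict", "pooled"):
        raise InvalidArgumentError(f"unknown leakage_mode {leakage_mode!r}")

    def build():
        steps = [("scale", StandardScaler())]
        if n_components is not None:
            steps.append(("pca", PCA(n_components=n_components)))
        steps.append(("clf", make_classifier(classifier, k)))
        return Pipeline(steps)

    n = X.shape[0]
    preds = np.empty(n, dtype=object)
    if leakage_mode == "pooled":
        if n_components is not None:
            Xr, _ = reduce_dimensions(X, n_components)
        else:
            Xr = StandardScaler().fit_transform(X)
        for i in range(n):
            tr = np.arange(n) != i
            clf = make_classifier(classifier, k)
            clf.fit(Xr[tr], y[tr])
            preds[i] = clf.predict(Xr[i : i + 1])[0]
    else:
        for i in range(n):
            tr = np.arange(n) != i
            pipe = build()
            pipe.fit(X[tr], y[tr])
            preds[i] = pipe.predict(X[i : i + 1])[0]

    cm = _confusion(classes, y, preds)
    return CVResult(
        classifier=classifier,
        classes=tuple(classes),
        predictions=np.asarray(preds),
        confusion=cm,
    )


def sam_classify(
    sam: pd.DataFrame | np.ndarray, labels, leakage_mode: str = "strict"
) -> CVResult:
    """Leave-one-out LDA on the three SAM dimensions."""
    X = np.asarray(sam, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise InvalidArgumentError("SAM matrix must have exactly 3 columns")
    if X.min() < 1 or X.max() > 9:
        raise InvalidArgumentError("SAM values must lie in [1, 9]")
    return loocv_classify(
        X, labels, classifier="lda", n_components=None, leakage_mode=leakage_mode
    )


def task_rows(matrix: pd.DataFrame, classes: tuple[str, ...]) -> pd.DataFrame:
    """Rows of a (subject, class)-indexed matrix belonging to one
    four-class task."""
    sel = matrix.index.get_level_values("class").isin(classes)
    return matrix.loc[sel]
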