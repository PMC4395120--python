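"""Exhaustive triplet resampling and paired statistical comparisons.

A single cohort yields one accuracy per classifier, which supports no
significance statement.  To compare against chance and across data
modalities, the cohort is resampled into *all* C(n, 3) three-subject
groups; each group (12 epochs: 3 subjects x 4 classes) is scored with a
small kNN under stratified 3-fold cross-validation (each fold holds one
subject's four epochs), and the resulting per-group accuracies enter
paired-samples t-tests:

* each task (archetypes, emotions) against the 25 % four-class chance
  level,
* archetypes vs emotions on physiological features,
* physiological features vs SAM reports within each task.

The same triplet shares samples with many others, so the paired t-tests
inherit the positive dependence of overlapping resamples; a subject-level
disjoint-partition t-test is provided as a conservative diagnostic.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    DegenerateVarianceError,
    InvalidArgumentError,
    InvalidDesignError,
)
from .types import ARCHETYPE_CLASSES, EMOTION_CLASSES, GroupResult, TTestResult

#: chance accuracy of a balanced four-class task
CHANCE_LEVEL = 0.25
#: neighbourhood size for group-level kNN (8 training rows per fold)
GROUP_KNN_K = 3
GROUP_FOLDS = 3


def enumerate_triplets(subject_ids) -> list[tuple]:
    """All unordered 3-subsets of the subjects, lexicographic in the
    sorted subject order.  C(25, 3) = 2300 at full cohort size."""
    ids = sorted(set(subject_ids))
    if len(ids) != len(list(subject_ids)):
        raise InvalidArgumentError("duplicate subject ids")
    if len(ids) < 3:
        raise InvalidArgumentError("need at least 3 subjects")
    return list(combinations(ids, 3))


def _knn_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray, k: int
) -> np.ndarray:
    """Plain kNN vote with deterministic tie handling: ties are broken
    by the largest summed inverse distance to the test point, then by
    lexicographic class order."""
    d = np.sqrt(((X_test[:, None, :] - X_train[None, :, :]) ** 2).sum(-1))
    classes = np.unique(y_train)
    out = np.empty(len(X_test), dtype=object)
    for i in range(len(X_test)):
        nn = np.argsort(d[i], kind="stable")[:k]
        votes = {c: 0 for c in classes}
        weight = {c: 0.0 for c in classes}
        for j in nn:
            c = y_train[j]
            votes[c] += 1
            weight[c] += 1.0 / max(d[i, j], 1e-12)
        out[i] = min(classes, key=lambda c: (-votes[c], -weight[c], c))
    return out


def evaluate_group(
    X: np.ndarray,
    labels,
    subjects,
    k: int = GROUP_KNN_K,
    folds: int = GROUP_FOLDS,
) -> float:
    """Stratified k-fold accuracy of one three-subject group.

    Folds are the subjects themselves: each fold holds exactly one
    sample per class (one subject's four epochs), which realises a
    stratified 3-fold split and avoids within-subject leakage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    subj = np.asarray(subjects)
    uniq_subj = np.unique(subj)
    uniq_cls = np.unique(y)
    if len(uniq_subj) != folds:
        raise InvalidDesignError(f"group must contain exactly {folds} subjects")
    for s in uniq_subj:
        if sorted(y[subj == s].tolist()) != sorted(uniq_cls.tolist()):
            raise InvalidDesignError(
                "unbalanced group: every subject needs one epoch per class"
            )
    correct = 0
    for s in uniq_subj:
        te = subj == s
        pred = _knn_predict(X[~te], y[~te], X[te], k)
        correct += int((pred == y[te]).sum())
    return correct / len(y)


def group_accuracies(
    matrix: pd.DataFrame,
    task: str,
    modality: str,
    classes: tuple[str, ...],
    k: int = GROUP_KNN_K,
) -> list[GroupResult]:
    """Accuracy of every three-subject group on one task and modality.

    ``matrix`` is (subject, class)-indexed with feature columns already
    reduced (physiological) or raw SAM dimensions.
    """
    sel = matrix.index.get_level_values("class").isin(classes)
    sub = matrix.loc[sel]
    subjects = sub.index.get_level_values("subject").to_numpy()
    labels = sub.index.get_level_values("class").to_numpy()
    X = sub.to_numpy(dtype=float)

    results = []
    for trip in enumerate_triplets(np.unique(subjects)):
        rows = np.isin(subjects, trip)
        acc = evaluate_group(X[rows], labels[rows], subjects[rows], k=k)
        results.append(
            GroupResult(subjects=trip, task=task, modality=modality, accuracy=acc)
        )
    return results


def paired_t(a, b, comparison: str = "") -> TTestResult:
    """Paired-samples t-test; ``b`` may be a constant (e.g. the 25 %
    chance level), in which case it is treated as that constant repeated.

    t = mean(d) / (sd(d) / sqrt(n)) with the sample (n-1) sd;
    two-sided p from the t distribution with df = n - 1.
    """
    a = np.asarray(a, dtype=float)
    b_arr = np.broadcast_to(np.asarray(b, dtype=float), a.shape).astype(float)
    if a.ndim != 1 or a.size < 2:
        raise InvalidArgumentError("need at least 2 paired observations")
    d = a - b_arr
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical samples: no evidence of any difference
            return TTestResult(comparison, 0.0, d.size - 1, 1.0, 0.0)
        raise DegenerateVarianceError("paired differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        comparison=comparison, t=float(t), df=df, p=float(p),
        mean_diff=float(d.mean()),
    )


def run_comparisons(
    reduced: pd.DataFrame,
    sam: pd.DataFrame,
    k: int = GROUP_KNN_K,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The full triplet-resampling comparison battery.

    Parameters
    ----------
    reduced : DataFrame
        PCA-reduced physiological feature matrix, (subject, class) index.
    sam : DataFrame
        SAM report matrix, same index, 3 columns.

    Returns
    -------
    groups : DataFrame
        One row per (triplet, task, modality) with its accuracy.
    comparisons : DataFrame
        The five paired t-tests: each task vs the 25 % chance level,
        archetypes vs emotions (physiological), and physiological vs SAM
        within each task.
    """
    series: dict[tuple[str, str], np.ndarray] = {}
    group_rows = []
    for task, classes in (
        ("archetypes", ARCHETYPE_CLASSES),
        ("emotions", EMOTION_CLASSES),
    ):
        for modality, matrix in (("physiological", reduced), ("sam", sam)):
            res = group_accuracies(matrix, task, modality, classes, k=k)
            series[(task, modality)] = np.array([g.accuracy for g in res])
            group_rows.extend(res)

    tests = [
        paired_t(series[("archetypes", "physiological")], CHANCE_LEVEL,
                 "archetypes_physiological_vs_chance"),
        paired_t(series[("emotions", "physiological")], CHANCE_LEVEL,
                 "emotions_physiological_vs_chance"),
        paired_t(series[("archetypes", "physiological")],
                 series[("emotions", "physiological")],
                 "archetypes_vs_emotions_physiological"),
        paired_t(series[("archetypes", "physiological")],
                 series[("archetypes", "sam")],
                 "physiological_vs_sam_archetypes"),
        paired_t(series[("emotions", "sam")],
                 series[("emotions", "physiological")],
                 "sam_vs_physiological_emotions"),
    ]

    groups = pd.DataFrame(
        [
            {
                "subjects": "+".join(g.subjects),
                "task": g.task,
                "modality": g.modality,
                "accuracy": g.accuracy,
            }
            for g in group_rows
        ]
    )
    comparisons = pd.DataFrame(
        [
            {
                "comparison": t.comparison,
                "t": t.t,
                "df": t.df,
                "p": t.p,
                "mean_diff": t.mean_diff,
            }
            for t in tests
        ]
    )
    return groups, comparisons


def disjoint_partition_t(
    matrix: pd.DataFrame,
    task: str,
    classes: tuple[str, ...],
    seed: int = 0,
    k: int = GROUP_KNN_K,
) -> TTestResult:
    """Diagnostic t-test on non-overlapping three-subject groups.

    The exhaustive triplet enumeration reuses every subject in many
    groups, so those t-tests violate independence.  This variant
    partitions the subjects into floor(n/3) disjoint triples (one seeded
    random partition) and tests their accuracies against chance — far
    fewer degrees of freedom, but independent groups.
    """
    subjects = np.unique(matrix.index.get_level_values("subject"))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(subjects)
    n_groups = len(subjects) // 3
    if n_groups < 2:
        raise InvalidDesignError("need at least 6 subjects for the diagnostic")
    accs = []
    sel = matrix.index.get_level_values("class").isin(classes)
    sub = matrix.loc[sel]
    subj_col = sub.index.get_level_values("subject").to_numpy()
    labels = sub.index.get_level_values("class").to_numpy()
    X = sub.to_numpy(dtype=float)
    for g in range(n_groups):
        trip = perm[3 * g : 3 * g + 3]
        rows = np.isin(subj_col, trip)
        accs.append(evaluate_group(X[rows], labels[rows], subj_col[rows], k=k))
    return paired_t(accs, CHANCE_LEVEL, f"{task}_disjoint_vs_chance")
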