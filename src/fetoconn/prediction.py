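"""Evaluating connectome templates by gestational-age prediction.

Two evaluation protocols:

* a nearest-neighbor classifier on graph edit distance: a subject is
  assigned the week of the template closest in l1 distance;
* a same-age binary classifier: each (subject, template) pair is
  summarized by the l1/l2/l-inf norms of the difference between feature
  vectors (all edge weights plus eight topological descriptors), and a
  linear support vector machine predicts whether the pair shares a
  gestational week.  Subject-level ten-fold cross-validation reports the
  resulting age-prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import Cohort, Connectome
from .metrics import (
    NullModelConfig,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    eigenvector_centrality,
    global_efficiency,
    local_efficiency,
    small_world_index,
    total_strength,
)
from .templates import TemplateSet, graph_edit_distance

__all__ = [
    "PairFeatures",
    "ged_nn_predict",
    "evaluate_age_prediction",
    "connectome_features",
    "pair_features",
    "train_same_age_classifier",
    "SameAgeClassifierReport",
]

#: the eight topological descriptors appended to the edge-weight block
DESCRIPTOR_NAMES = (
    "global_efficiency",
    "local_efficiency",
    "characteristic_path_length",
    "clustering_coefficient",
    "small_world_index",
    "total_strength",
    "mean_betweenness",
    "mean_eigenvector_centrality",
)


@dataclass
class PairFeatures:
    l1: float
    l2: float
    linf: float

    def as_array(self) -> np.ndarray:
        return np.array([self.l1, self.l2, self.linf])


def ged_nn_predict(c: Connectome, templates: TemplateSet) -> int:
    """Week of the template minimizing GED to the subject (ties: younger)."""
    if len(templates) == 0:
        raise ValueError("empty template set")
    geds = [graph_edit_distance(c, t) for t in templates.templates]
    order = np.argsort(templates.weeks)
    best = min(order, key=lambda i: (geds[i], templates.weeks[i]))
    return int(templates.weeks[best])


def evaluate_age_prediction(
    cohort: Cohort, templates: TemplateSet
) -> tuple[float, float, pd.DataFrame]:
    """Per-subject |predicted - round(true age)|; returns (mean, SD, table)."""
    rows = []
    for s in cohort:
        pred = ged_nn_predict(s, templates)
        true_week = round(s.age_weeks)
        rows.append((s.subject_id, s.age_weeks, pred, abs(pred - true_week)))
    df = pd.DataFrame(
        rows, columns=["subject_id", "true_age", "predicted_week", "abs_error"]
    )
    return (
        float(df["abs_error"].mean()),
        float(df["abs_error"].std(ddof=1)) if len(df) > 1 else 0.0,
        df,
    )


def connectome_features(
    c: Connectome, null_cfg: NullModelConfig | None = None
) -> np.ndarray:
    """Edge weights (upper triangle) plus the eight topological descriptors.

    For d nodes the vector has d(d-1)/2 + 8 entries, in the documented
    order: edge block (pairs i<j, row-major), then ``DESCRIPTOR_NAMES``.
    The small-world index uses a seeded null ensemble so the vector is
    deterministic.
    """
    if null_cfg is None:
        null_cfg = NullModelConfig()
    edge_block = c.upper_triangle()
    if edge_block.sum() == 0:
        return np.concatenate([edge_block, np.zeros(len(DESCRIPTOR_NAMES))])
    descriptors = np.array([
        global_efficiency(c),
        local_efficiency(c),
        characteristic_path_length(c),
        clustering_coefficient(c),
        small_world_index(c, null_cfg),
        total_strength(c),
        float(betweenness_centrality(c).mean()),
        float(eigenvector_centrality(c).mean()),
    ])
    return np.concatenate([edge_block, descriptors])


def pair_features(f1: np.ndarray, f2: np.ndarray) -> PairFeatures:
    """l1, l2 and l-inf norms of the difference between two feature vectors."""
    f1, f2 = np.asarray(f1, dtype=float), np.asarray(f2, dtype=float)
    if f1.shape != f2.shape:
        raise ValueError("feature vectors must have equal length")
    diff = f1 - f2
    return PairFeatures(
        l1=float(np.abs(diff).sum()),
        l2=float(np.linalg.norm(diff)),
        linf=float(np.abs(diff).max()) if diff.size else 0.0,
    )


@dataclass
class SameAgeClassifierReport:
    mean_abs_error: float
    sd_abs_error: float
    per_subject: pd.DataFrame
    fold_errors: list[float]


def _subject_folds(n_subjects: int, folds: int, rng: np.random.Generator):
    order = rng.permutation(n_subjects)
    return np.array_split(order, folds)


def train_same_age_classifier(
    cohort: Cohort,
    templates: TemplateSet,
    folds: int = 10,
    seed: int = 0,
    null_cfg: NullModelConfig | None = None,
    feature_fn=None,
) -> SameAgeClassifierReport:
    """Linear-SVM same-age classifier with subject-level cross-validation.

    Training pairs are all (subject, template) combinations labeled by
    same-week / different-week; features are the pairwise norm triplets.
    Fold assignment is by subject, so no subject contributes pairs to both
    train and test.  A held-out subject's age is predicted as the week of
    the template with the highest same-age decision score (ties: younger
    week); errors are |predicted - round(true age)|.
    """
    if null_cfg is None:
        null_cfg = NullModelConfig()
    if feature_fn is None:
        feature_fn = lambda c: connectome_features(c, null_cfg)
    weeks = np.asarray(templates.weeks)
    if len(set(round(s.age_weeks) for s in cohort)) < 2:
        raise ValueError("cohort must span at least 2 gestational weeks")

    subj_feats = [feature_fn(s) for s in cohort]
    tmpl_feats = [feature_fn(t) for t in templates.templates]
    n, m = len(cohort), len(templates)
    X = np.empty((n * m, 3))
    y = np.empty(n * m, dtype=int)
    subj_of_pair = np.empty(n * m, dtype=int)
    for i, s in enumerate(cohort):
        for j in range(m):
            r = i * m + j
            X[r] = pair_features(subj_feats[i], tmpl_feats[j]).as_array()
            y[r] = int(round(s.age_weeks) == weeks[j])
            subj_of_pair[r] = i

    rng = np.random.default_rng(seed)
    fold_members = _subject_folds(n, folds, rng)
    preds = np.full(n, -1, dtype=int)
    fold_errors = []
    for fold in fold_members:
        test_mask = np.isin(subj_of_pair, fold)
        y_train = y[~test_mask]
        if len(np.unique(y_train)) < 2:
            raise ValueError("a training fold contains a single class")
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
        clf.fit(X[~test_mask], y_train)
        errs = []
        for i in fold:
            rows = np.flatnonzero(subj_of_pair == i)
            scores = clf.decision_function(X[rows])
            best = min(range(m), key=lambda j: (-scores[j], weeks[j]))
            preds[i] = weeks[best]
            errs.append(abs(int(weeks[best]) - round(cohort.subjects[i].age_weeks)))
        fold_errors.append(float(np.mean(errs)))
    table = pd.DataFrame({
        "subject_id": [s.subject_id for s in cohort],
        "true_age": [s.age_weeks for s in cohort],
        "predicted_week": preds,
        "abs_error": [
            abs(int(p) - round(s.age_weeks)) for p, s in zip(preds, cohort)
        ],
    })
    return SameAgeClassifierReport(
        mean_abs_error=float(table["abs_error"].mean()),
        sd_abs_error=float(table["abs_error"].std(ddof=1)) if n > 1 else 0.0,
        per_subject=table,
        fold_errors=fold_errors,
    )
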