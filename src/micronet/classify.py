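"""Module-abundance features and a cross-validated logistic classifier.

Dense network modules whose members are disease markers suggest a compact
feature set: each module's feature value for a sample is the mean abundance
of its member units in that sample.  A logistic regression over these
features, evaluated by stratified k-fold cross-validation with pooled
out-of-fold predictions, measures how much of the case/control signal the
modules capture (AUC of the ROC curve, area under the precision-recall
curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .mcode import ModuleSet
from .profiles import AbundanceProfile

__all__ = [
    "FeatureMatrix",
    "CVResult",
    "module_features",
    "crossval_logistic",
    "roc_pr",
]


@dataclass
class FeatureMatrix:
    """Samples x modules feature matrix of mean member abundances."""

    values: pd.DataFrame  # rows: samples, columns: modules
    labels: pd.Series


@dataclass
class CVResult:
    """Pooled out-of-fold predictions of a cross-validated classifier."""

    sample_ids: list
    y_true: np.ndarray
    y_score: np.ndarray
    fold: np.ndarray
    k: int
    seed: int
    positive_label: str


def module_features(profile: AbundanceProfile, ms: ModuleSet) -> FeatureMatrix:
    """Mean abundance of each module's member units, per sample."""
    if profile.labels is None:
        raise ValueError("profile has no sample labels")
    cols = {}
    for m in ms:
        present = [u for u in sorted(map(str, m.members)) if u in profile.unit_ids]
        if not present:
            raise ValueError(f"module {m.rank} has no unit present in the profile")
        cols[f"module_{m.rank}"] = profile.abundance.loc[present].mean(axis=0)
    values = pd.DataFrame(cols, index=profile.sample_ids)
    return FeatureMatrix(values=values, labels=profile.labels.copy())


def crossval_logistic(
    fm: FeatureMatrix, k: int = 10, seed: int = 0, positive_label: str | None = None
) -> CVResult:
    """Stratified k-fold logistic regression with pooled predictions.

    Features are standardized inside each fold using training-fold
    statistics only.  The logistic fit is unpenalized; if it fails to
    converge (quasi-separation on a small fold), a weak ridge penalty is
    applied as a fallback.  Every sample receives exactly one
    out-of-fold predicted probability.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    classes = sorted(fm.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected two classes, got {classes}")
    if positive_label is None:
        positive_label = classes[0]
    y = (fm.labels == positive_label).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    if k > min(y.sum(), len(y) - y.sum()):
        raise ValueError("k exceeds the smaller class size")
    X = fm.values.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[tr])
        Xtr, Xte = scaler.transform(X[tr]), scaler.transform(X[te])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf = LogisticRegression(penalty=None, max_iter=2000)
            clf.fit(Xtr, y[tr])
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            clf = LogisticRegression(C=1e3, max_iter=2000)
            clf.fit(Xtr, y[tr])
        scores[te] = clf.predict_proba(Xte)[:, 1]
        fold_of[te] = f
    return CVResult(
        sample_ids=list(fm.values.index),
        y_true=y,
        y_score=scores,
        fold=fold_of,
        k=k,
        seed=seed,
        positive_label=str(positive_label),
    )


def roc_pr(cv: CVResult) -> dict:
    """ROC and PR curves with their areas from pooled predictions.

    AUC is the trapezoid-rule area under the ROC curve (equal to the
    normalized Mann-Whitney U statistic of the score ranking, with ties
    counted half).  AUPR integrates the PR curve stepwise (average
    precision); precision at zero predicted positives follows the
    convention of the highest-threshold point being (recall 0,
    precision 1).
    """
    y, s = cv.y_true, cv.y_score
    if y.min() == y.max():
        raise ValueError("need both classes to compute ROC")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, s)
    # stepwise (right-continuous) integration, as in average precision
    aupr = float(-np.sum(np.diff(recall) * precision[:-1]))
    return {
        "auc": auc,
        "aupr": aupr,
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "pr": {"precision": precision.tolist(), "recall": recall.tolist()},
    }
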