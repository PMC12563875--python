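"""Subject-level cross-validation harness and baselines.

Folds partition *subjects* (never trials), class-balanced, so no individual
contributes to both training and test.  Metrics are computed at trial level
with PTSD as the positive class; fold metrics are aggregated as
mean +/- 1.96 * sd / sqrt(k).  Baselines: an SVM (RBF kernel, C = 0.1) on
CSTP log-variance features refit inside each training fold, and a raw-feature
SVM control on flattened epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (accuracy_score, confusion_matrix, f1_score,
                             precision_score, recall_score, roc_auc_score)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import EpochSet
from .cstp import CSTP
from .sttcnet import STTCNet

__all__ = [
    "LeakageError",
    "make_folds",
    "compute_metrics",
    "aggregate",
    "CVReport",
    "cross_validate_sttcnet",
    "svm_baseline",
    "raw_svm_control",
]

POSITIVE_CLASS = "PTSD"
METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")


class LeakageError(RuntimeError):
    """Raised when a training fold would see test-fold subjects."""


def make_folds(subjects, groups, k: int = 4, seed: int = 0):
    """Class-balanced subject partition into k test folds.

    Returns a list of k lists of subject ids; per-class counts across folds
    differ by at most one.
    """
    subjects = list(subjects)
    groups = list(groups)
    if k < 2:
        raise ValueError("k must be >= 2 (a single fold has no held-out rotation)")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in sorted(set(groups)):
        members = [s for s, g in zip(subjects, groups) if g == cls]
        if len(members) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} subjects")
        order = rng.permutation(len(members))
        for i, j in enumerate(order):
            folds[i % k].append(members[j])
    return folds


def _audit_no_leakage(train_subjects, test_subjects) -> None:
    overlap = set(train_subjects) & set(test_subjects)
    if overlap:
        raise LeakageError(f"subjects in both train and test: {sorted(overlap)}")


def compute_metrics(y_true, y_pred, y_score, positive=POSITIVE_CLASS) -> dict:
    """Accuracy / precision / recall / F1 / AUC plus raw and row-normalized
    confusion matrices (rows = true classes, sorted label order)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = sorted(set(y_true) | set(y_pred))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    row_sums = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, row_sums, out=np.zeros_like(cm, dtype=float),
                        where=row_sums > 0)
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, pos_label=positive, zero_division=0),
        "recall": recall_score(y_true, y_pred, pos_label=positive, zero_division=0),
        "f1": f1_score(y_true, y_pred, pos_label=positive, zero_division=0),
        "confusion": cm,
        "confusion_normalized": cm_norm,
        "labels": labels,
    }
    if len(set(y_true)) < 2:
        out["auc"] = np.nan
        out["auc_defined"] = False
    else:
        out["auc"] = roc_auc_score((y_true == positive).astype(int), np.asarray(y_score))
        out["auc_defined"] = True
    return out


def aggregate(fold_metrics: list[dict]) -> dict:
    """Across-fold mean and normal-approximation 95% CI per metric."""
    if len(fold_metrics) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    out = {}
    k = len(fold_metrics)
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in fold_metrics], dtype=float)
        vals = vals[~np.isnan(vals)]
        mean = vals.mean()
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(vals.size)
        out[name] = {"mean": float(mean), "ci_low": float(mean - half),
                     "ci_high": float(mean + half)}
    out["n_folds"] = k
    return out


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation results."""

    folds: list = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(m):
            m = dict(m)
            m["confusion"] = np.asarray(m["confusion"]).tolist()
            m["confusion_normalized"] = np.asarray(m["confusion_normalized"]).tolist()
            return m
        return {"seed": self.seed, "aggregate": self.aggregate,
                "folds": [clean(f) for f in self.folds]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in METRIC_NAMES:
            a = self.aggregate[name]
            rows.append({"metric": name, "mean": a["mean"],
                         "ci_low": a["ci_low"], "ci_high": a["ci_high"]})
        return pd.DataFrame(rows)


def _fold_split(ep: EpochSet, test_subjects, strict: bool = True):
    sid = ep.meta["subject_id"].to_numpy()
    test_mask = np.isin(sid, list(test_subjects))
    train_ep, test_ep = ep.select(~test_mask), ep.select(test_mask)
    if strict:
        _audit_no_leakage(train_ep.meta["subject_id"], test_ep.meta["subject_id"])
    return train_ep, test_ep


def _run_cv(ep: EpochSet, folds, fit_predict, seed: int, shuffle_labels: bool = False) -> CVReport:
    rng = np.random.default_rng(seed)
    report = CVReport(seed=seed)
    for test_subjects in folds:
        train_ep, test_ep = _fold_split(ep, test_subjects)
        y_train = train_ep.meta["group"].to_numpy().copy()
        if shuffle_labels:
            rng.shuffle(y_train)
        y_pred, y_score = fit_predict(train_ep, y_train, test_ep)
        m = compute_metrics(test_ep.meta["group"].to_numpy(), y_pred, y_score)
        m["test_subjects"] = list(test_subjects)
        report.folds.append(m)
    report.aggregate = aggregate(report.folds)
    return report


def cross_validate_sttcnet(ep: EpochSet, folds, seed: int = 0,
                           shuffle_labels: bool = False, ensemble: int = 1,
                           **net_params) -> CVReport:
    """Subject-level CV of the P300-STTCNet at trial level.

    ``ensemble > 1`` trains that many differently-seeded networks per fold and
    averages their class probabilities (soft voting) — a standard variance
    reduction for small-cohort EEG classification.
    """

    def fit_predict(train_ep, y_train, test_ep):
        probas = []
        for e in range(ensemble):
            clf = STTCNet(channels=list(ep.channels), t_axis=ep.t_axis,
                          random_state=seed + 1000 * e, **net_params)
            clf.fit(train_ep.data, y_train,
                    groups=train_ep.meta["subject_id"].to_numpy())
            probas.append(clf.predict_proba(test_ep.data))
        proba = np.mean(probas, axis=0)
        pos_col = int(np.where(clf.classes_ == POSITIVE_CLASS)[0][0])
        return clf.classes_[proba.argmax(axis=1)], proba[:, pos_col]

    return _run_cv(ep, folds, fit_predict, seed, shuffle_labels)


def svm_baseline(ep: EpochSet, folds, seed: int = 0, m_filters: int = 6,
                 k_filters: int = 6, C: float = 0.1,
                 shuffle_labels: bool = False) -> CVReport:
    """CSTP + RBF-SVM baseline; the CSTP filters are refit inside each
    training fold so no test-fold subject influences feature learning."""

    def fit_predict(train_ep, y_train, test_ep):
        cstp = CSTP(m_filters=min(m_filters, len(ep.channels)),
                    k_filters=k_filters).fit(train_ep.data, y_train)
        f_train = cstp.transform(train_ep.data)
        f_test = cstp.transform(test_ep.data)
        svm = SVC(kernel="rbf", C=C, gamma="scale")
        svm.fit(f_train, y_train)
        score = svm.decision_function(f_test)
        if svm.classes_[1] != POSITIVE_CLASS:  # decision_function favors classes_[1]
            score = -score
        return svm.predict(f_test), score

    return _run_cv(ep, folds, fit_predict, seed, shuffle_labels)


def raw_svm_control(ep: EpochSet, folds, seed: int = 0, C: float = 0.1,
                    shuffle_labels: bool = False) -> CVReport:
    """SVM control on flattened raw epochs (no learned features)."""

    def fit_predict(train_ep, y_train, test_ep):
        Xtr = train_ep.data.reshape(train_ep.n_trials, -1)
        Xte = test_ep.data.reshape(test_ep.n_trials, -1)
        svm = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma="scale"))
        svm.fit(Xtr, y_train)
        score = svm.decision_function(Xte)
        if svm.classes_[1] != POSITIVE_CLASS:
            score = -score
        return svm.predict(Xte), score

    return _run_cv(ep, folds, fit_predict, seed, shuffle_labels)
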