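"""Cohort-level analysis of IST heterogeneity indices.

Age normalisation uses the healthy-population regression lines

    sigma_V(age) = 0.0043 * age + 0.46
    sigma_P(age) = 0.0045 * age + 0.75

and expresses a measured index as a percentage of its age-predicted value,
removing the effect of normal ageing before comparing health states.  The
classification utilities cover the binary healthy-vs-COPD task (rank-based
ROC AUC) and the five-way GOLD grading (multinomial logistic regression by
maximum likelihood on the two %-predicted indices, evaluated in-sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .exceptions import ConfigurationError, UndefinedInputError
from .patients import GOLD_LABELS, cohort_to_frame

__all__ = [
    "AgeNormModel",
    "ClassificationReport",
    "percent_predicted",
    "roc_auc",
    "classify_gold",
    "group_tests",
]


@dataclass(frozen=True)
class AgeNormModel:
    """Linear age-prediction model of the heterogeneity indices."""

    slope_v: float = 0.0043
    intercept_v: float = 0.46
    slope_p: float = 0.0045
    intercept_p: float = 0.75

    def __post_init__(self):
        for age in (0.0, 120.0):
            if self.predicted(age, "V") <= 0 or self.predicted(age, "P") <= 0:
                raise ConfigurationError(
                    "age-norm model must predict positive values on [0, 120]"
                )

    def predicted(self, age: float, channel: str) -> float:
        if channel == "V":
            return self.slope_v * age + self.intercept_v
        if channel == "P":
            return self.slope_p * age + self.intercept_p
        raise ConfigurationError(f"channel must be 'V' or 'P', got {channel!r}")


def percent_predicted(
    sigma, age, channel: str = "V", model: AgeNormModel | None = None
):
    """Measured index as % of its age-predicted value, ``100*sigma/pred(age)``."""
    model = model or AgeNormModel()
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ConfigurationError("age must be > 0")
    slope, intercept = (
        (model.slope_v, model.intercept_v)
        if channel == "V"
        else (model.slope_p, model.intercept_p)
    )
    if channel not in ("V", "P"):
        raise ConfigurationError(f"channel must be 'V' or 'P', got {channel!r}")
    pred = slope * age + intercept
    if np.any(pred <= 0):
        raise ConfigurationError("age-predicted value <= 0: model misuse")
    return 100.0 * np.asarray(sigma, dtype=float) / pred


def roc_auc(labels, scores) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties half."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise UndefinedInputError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class ClassificationReport:
    """Confusion matrix and accuracies of the GOLD classification."""

    confusion: np.ndarray
    class_labels: tuple = GOLD_LABELS
    overall_accuracy: float = 0.0
    per_class_accuracy: dict = field(default_factory=dict)
    auc: float = float("nan")

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion, index=self.class_labels, columns=self.class_labels
        )

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_labels": list(self.class_labels),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "auc": self.auc,
        }


def _feature_matrix(df: pd.DataFrame, features: str, model: AgeNormModel):
    pv = percent_predicted(df["sigma_v"], df["age_years"], "V", model)
    pp = percent_predicted(df["sigma_p"], df["age_years"], "P", model)
    if features == "percent_predicted":
        return np.column_stack([pv, pp])
    if features == "raw_age":
        return np.column_stack([df["sigma_v"], df["sigma_p"], df["age_years"]])
    raise ConfigurationError(
        f"features must be 'percent_predicted' or 'raw_age', got {features!r}"
    )


def classify_gold(
    records,
    seed: int = 0,
    features: str = "percent_predicted",
    model: AgeNormModel | None = None,
    cv: int | None = None,
) -> ClassificationReport:
    """Multinomial logistic GOLD classification of a cohort.

    Fits a maximum-likelihood (unpenalised) multinomial logistic regression
    on the %-predicted heterogeneity indices and reports the in-sample
    confusion matrix, overall and per-class accuracy, and the binary
    healthy-vs-COPD ROC AUC using the model's COPD probability.  Set ``cv``
    to a fold count to get cross-validated predictions instead.
    Deterministic given the records and seed.
    """
    records = list(records)
    model = model or AgeNormModel()
    df = cohort_to_frame(records)
    counts = df["group"].value_counts()
    present = [g for g in GOLD_LABELS if counts.get(g, 0) > 0]
    if len(present) < 2:
        raise ConfigurationError("classification needs at least 2 classes present")
    for g in present:
        if counts[g] < 2:
            raise ConfigurationError(
                f"class {g!r} has only {counts[g]} record(s); need at least 2"
            )
    X = _feature_matrix(df, features, model)
    y = df["group"].to_numpy()

    def make_clf():
        return LogisticRegression(C=np.inf, max_iter=5000, solver="lbfgs")

    if cv:
        from sklearn.model_selection import StratifiedKFold, cross_val_predict

        splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        y_pred = cross_val_predict(make_clf(), X, y, cv=splitter)
        proba = cross_val_predict(
            make_clf(), X, y, cv=splitter, method="predict_proba"
        )
        classes = np.unique(y)
    else:
        clf = make_clf().fit(X, y)
        y_pred = clf.predict(X)
        proba = clf.predict_proba(X)
        classes = clf.classes_

    label_index = {g: i for i, g in enumerate(GOLD_LABELS)}
    confusion = np.zeros((len(GOLD_LABELS), len(GOLD_LABELS)), dtype=int)
    for truth, pred in zip(y, y_pred):
        confusion[label_index[truth], label_index[pred]] += 1

    overall = 100.0 * float(np.mean(y_pred == y))
    per_class = {}
    for g in present:
        mask = y == g
        per_class[g] = 100.0 * float(np.mean(y_pred[mask] == y[mask]))

    auc = float("nan")
    is_copd = (y != "healthy").astype(int)
    if "healthy" in classes and is_copd.min() != is_copd.max():
        healthy_col = int(np.where(classes == "healthy")[0][0])
        auc = roc_auc(is_copd, 1.0 - proba[:, healthy_col])

    return ClassificationReport(
        confusion=confusion,
        class_labels=GOLD_LABELS,
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        auc=auc,
    )


def group_tests(records, value: str = "sigma_v") -> dict:
    """Two-group t test (healthy vs pooled COPD) and Kruskal-Wallis across grades.

    Returns a dict with ``t_stat``, ``t_pvalue`` (unpaired two-sided t test of
    healthy vs pooled COPD), ``kruskal_h``, ``kruskal_pvalue`` (across all
    groups present) and the group sizes.  No multiple-testing correction is
    applied.
    """
    records = list(records)
    if value not in ("sigma_v", "sigma_p"):
        raise ConfigurationError("value must be 'sigma_v' or 'sigma_p'")
    df = cohort_to_frame(records)
    col = df[value].to_numpy()
    groups = {g: col[df["group"] == g] for g in GOLD_LABELS if (df["group"] == g).any()}
    for g, vals in groups.items():
        if len(vals) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 records")
    healthy = groups.get("healthy", np.array([]))
    copd = np.concatenate([v for g, v in groups.items() if g != "healthy"] or [np.array([])])
    out = {"n_per_group": {g: int(len(v)) for g, v in groups.items()}}
    if len(healthy) >= 2 and len(copd) >= 2:
        t_stat, t_p = stats.ttest_ind(healthy, copd)
        out["t_stat"] = float(t_stat)
        out["t_pvalue"] = float(t_p)
    if len(groups) >= 2:
        h_stat, h_p = stats.kruskal(*groups.values())
        out["kruskal_h"] = float(h_stat)
        out["kruskal_pvalue"] = float(h_p)
    return out
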