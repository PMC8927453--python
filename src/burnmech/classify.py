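"""Binary tissue classification with LOOCV logistic regression.

The five-property vector (ultimate tensile stress and strain, toughness, and
the Veronda-Westmann coefficients mu and gamma) feeds a logistic-regression
classifier assessed by leave-one-out cross-validation: for each specimen the
model is trained on the remaining n-1 rows (features standardized with the
training statistics only, so no information leaks from the held-out row) and
the held-out probability of the positive class (human) is recorded.  The
pooled out-of-fold probabilities and hard labels at threshold 0.5 yield the
confusion matrix and an eight-metric suite: accuracy, sensitivity,
specificity, F1, ROC-AUC, Matthews correlation coefficient (MCC),
Fowlkes-Mallows index (FMI) and adjusted Rand index (ARI).

A weak L2 penalty (weight 1e-4 on the standardized coefficients) keeps the
likelihood bounded on (near-)separable data; predicted labels are
insensitive to this stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression

from .errors import InvalidTaskError, SchemaError

POSITIVE_CLASS = "human"
_L2_WEIGHT = 1e-4  # penalty weight of the predictive model; sklearn's C is its inverse
_CONTRIB_L2_WEIGHT = 1.0  # unit ridge for the contribution analysis (see below)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with 'human' as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationReport:
    """Full outcome of one LOOCV classification task."""

    task_label: str
    confusion: ConfusionMatrix
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    roc_auc: float
    mcc: float
    fmi: float
    ari: float
    oof_probabilities: np.ndarray = field(repr=False)
    contributions: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "roc_auc": self.roc_auc, "mcc": self.mcc,
                "fmi": self.fmi, "ari": self.ari}


def _new_model() -> LogisticRegression:
    return LogisticRegression(C=1.0 / _L2_WEIGHT, solver="lbfgs", max_iter=2000)


def _validate_task(features: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(features)):
        raise InvalidTaskError("non-finite feature values")
    classes = np.unique(y)
    if classes.size != 2:
        raise InvalidTaskError(f"need exactly two classes, got {classes.tolist()}")
    if y.size < 10:
        raise InvalidTaskError(f"need >= 10 samples, got {y.size}")


def roc_auc(probabilities, y_true) -> float:
    """Area under the ROC curve as the normalized Mann-Whitney statistic.

    Computed from the mid-ranks of the positive-class scores among all
    scores, which handles ties by the usual half-credit convention.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y_true, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(p)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _pair_counting_fmi(tp: int, fp: int, fn: int, tn: int) -> float:
    """Fowlkes-Mallows index of the true vs predicted 2-class partitions.

    The pair-counting (clustering) form: with ``a`` the pairs placed together
    in both partitions, ``FMI = a / sqrt((a+b)(a+c))`` where ``a+b`` counts
    pairs together in the true partition and ``a+c`` in the predicted one.
    For binary classification reported from a confusion matrix this is the
    convention whose values sit between ARI and F1 (NOT sqrt(PPV*TPR), which
    ignores the negative class's pairs).
    """
    a = sum(comb(x, 2) for x in (tp, fp, fn, tn))
    true_pairs = comb(tp + fn, 2) + comb(fp + tn, 2)
    pred_pairs = comb(tp + fp, 2) + comb(fn + tn, 2)
    if true_pairs == 0 or pred_pairs == 0:
        return float("nan")
    return float(a / np.sqrt(float(true_pairs) * pred_pairs))


def _pair_counting_ari(tp: int, fp: int, fn: int, tn: int) -> float:
    """Adjusted Rand index between the true and predicted 2-class partitions.

    Hubert-Arabie form evaluated on the 2x2 contingency table that the
    confusion matrix is.
    """
    n = tp + fp + fn + tn
    sum_cells = sum(comb(x, 2) for x in (tp, fp, fn, tn))
    sum_rows = comb(tp + fn, 2) + comb(fp + tn, 2)      # true partition
    sum_cols = comb(tp + fp, 2) + comb(fn + tn, 2)      # predicted partition
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total if total else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0 if sum_cells == max_index else 0.0
    return float((sum_cells - expected) / (max_index - expected))


def compute_metrics(confusion: ConfusionMatrix, oof_probabilities=None,
                    y_true=None) -> tuple[dict[str, float], list[str]]:
    """The eight-metric suite from a confusion matrix (+ scores for the AUC).

    Metrics with a zero denominator are reported as NaN together with a
    diagnostic note rather than silently as 0.  ``roc_auc`` is NaN when no
    out-of-fold scores are supplied.
    """
    tp, fp, fn, tn = confusion.tp, confusion.fp, confusion.fn, confusion.tn
    n = confusion.n
    notes: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            notes.append(f"{name} undefined: zero denominator")
            return float("nan")
        return num / den

    metrics = {
        "accuracy": ratio(tp + tn, n, "accuracy"),
        "sensitivity": ratio(tp, tp + fn, "sensitivity"),
        "specificity": ratio(tn, tn + fp, "specificity"),
        "f1": ratio(2 * tp, 2 * tp + fp + fn, "f1"),
    }
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        notes.append("mcc undefined: zero denominator")
        metrics["mcc"] = float("nan")
    else:
        metrics["mcc"] = float((tp * tn - fp * fn) / mcc_den)
    metrics["fmi"] = _pair_counting_fmi(tp, fp, fn, tn)
    if not np.isfinite(metrics["fmi"]):
        notes.append("fmi undefined: a partition has no co-clustered pairs")
    metrics["ari"] = _pair_counting_ari(tp, fp, fn, tn)
    if oof_probabilities is not None and y_true is not None:
        metrics["roc_auc"] = roc_auc(oof_probabilities, y_true)
    else:
        metrics["roc_auc"] = float("nan")
        notes.append("roc_auc undefined: no out-of-fold scores supplied")
    return metrics, notes


def feature_contributions(features, labels, feature_names=None) -> dict[str, float]:
    """Per-feature shares of the full-data standardized logistic model.

    The model is fitted once on all rows with standardized features; the
    share of feature j is ``|beta_j| / sum_k |beta_k|``, a normalized measure
    of how much each standardized property moves the log-odds.  Shares sum
    to 1.  Unlike the predictive LOOCV model, this fit uses a unit-strength
    ridge: on (near-)separable data an unpenalized maximum-likelihood
    direction is arbitrary among collinear features, whereas the ridge
    solution shares credit between correlated predictors and gives a stable,
    interpretable attribution.  An all-zero coefficient vector (degenerate
    fit) yields uniform shares and is flagged in the returned dict under the
    key ``_unreliable``.
    """
    X, y, names = _as_arrays(features, labels, feature_names)
    _validate_task(X, y)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    model = LogisticRegression(C=1.0 / _CONTRIB_L2_WEIGHT, solver="lbfgs",
                               max_iter=2000).fit(Xs, y)
    beta = np.abs(model.coef_.ravel())
    total = beta.sum()
    if total == 0:
        shares = dict.fromkeys(names, 1.0 / len(names))
        shares["_unreliable"] = 1.0
        return shares
    return dict(zip(names, (beta / total).tolist()))


def _as_arrays(features, labels, feature_names):
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"feature_{j}" for j in range(X.shape[1])]
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == POSITIVE_CLASS)
    y = y.astype(bool)
    return X, y, names


def loocv_classify(features, labels, *, task_label: str = "task",
                   feature_names=None, threshold: float = 0.5) -> ClassificationReport:
    """Leave-one-out cross-validated logistic regression.

    Each row is held out once; the model is trained on the remaining rows
    with features standardized by the training statistics, and the held-out
    positive-class probability is recorded.  Labels may be strings (positive
    class ``"human"``) or booleans.  The report carries the confusion matrix
    at the given threshold, the eight metrics, the pooled out-of-fold
    probabilities, and full-data feature contributions.
    """
    X, y, names = _as_arrays(features, labels, feature_names)
    _validate_task(X, y)
    n = y.size
    oof = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train = X[mask]
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        model = _new_model().fit((X_train - mean) / sd, y[mask])
        prob = model.predict_proba(((X[i] - mean) / sd).reshape(1, -1))
        oof[i] = prob[0, model.classes_.tolist().index(True)]
    pred = oof >= threshold
    confusion = ConfusionMatrix(
        tp=int(np.sum(pred & y)), fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)), tn=int(np.sum(~pred & ~y)),
    )
    metrics, notes = compute_metrics(confusion, oof, y)
    contributions = feature_contributions(X, y, names)
    return ClassificationReport(
        task_label=task_label, confusion=confusion,
        oof_probabilities=oof, contributions=contributions, notes=notes,
        **metrics,
    )


def combine_rates(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-rate property tables into one rate-independent task.

    Loading rate is deliberately NOT a feature of the combined task; the
    rows are simply stacked.  All tables must share the same columns in the
    same order.
    """
    if len(tables) < 2:
        raise SchemaError("need at least two tables to combine")
    columns = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=1):
        if list(t.columns) != columns:
            raise SchemaError(
                f"table {i} columns {list(t.columns)} differ from {columns}")
    return pd.concat(tables, ignore_index=True)
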