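"""Linear SVM training, leave-one-out evaluation and confusion metrics.

The classifier is a linear-kernel SVM with L2 penalty, squared-hinge loss
and regularization parameter C (default 1.0), fitted on per-feature
z-scored inputs.  Standardization is part of the model and is refitted
inside every leave-one-out fold so no information leaks from the held-out
sample.  The positive class is "patient" throughout: sensitivity measures
patient detection, and a decision value of exactly zero resolves to the
patient label.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

POSITIVE = "patient"
NEGATIVE = "control"


class ClassifierError(ValueError):
    pass


class AmbiguousConfusionError(ValueError):
    """Several integer confusion matrices reproduce the supplied metrics."""


class InconsistentConfusionError(ValueError):
    """No integer confusion matrix reproduces the supplied metrics."""


def _as_binary(y) -> np.ndarray:
    """Map labels to 1 = patient / 0 = control."""
    arr = np.asarray(y)
    if arr.dtype.kind in "SUO":
        bad = set(np.unique(arr)) - {POSITIVE, NEGATIVE}
        if bad:
            raise ClassifierError(f"labels must be in {{{POSITIVE!r}, {NEGATIVE!r}}}, found {sorted(bad)}")
        return (arr == POSITIVE).astype(int)
    return arr.astype(int)


def _as_matrix(X) -> np.ndarray:
    return np.asarray(X.values if isinstance(X, pd.DataFrame) else X, dtype=float)


@dataclass(frozen=True)
class LinearSVMModel:
    """Fitted linear SVM together with its standardization.

    ``weights`` and ``bias`` live on the z-scored feature scale; the
    decision function is ``w . (x - mean) / scale + b``, positive for the
    patient class.
    """

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    scale: np.ndarray
    C: float
    feature_names: tuple[str, ...] | None = None

    def standardize(self, X) -> np.ndarray:
        Z = _as_matrix(X)
        if Z.ndim != 2 or Z.shape[1] != len(self.weights):
            raise ClassifierError(
                f"expected {len(self.weights)} features, got shape {Z.shape}"
            )
        return (Z - self.mean) / self.scale


def train(X, y, C: float = 1.0, standardize: bool = True) -> LinearSVMModel:
    """Fit the L2 / squared-hinge linear SVM on (optionally z-scored) X.

    Deterministic for fixed input; solver tolerance 1e-6.  Constant
    features get unit scale so standardization never divides by zero.
    """
    Z = _as_matrix(X)
    yb = _as_binary(y)
    if len(np.unique(yb)) < 2:
        raise ClassifierError("training labels contain a single class")
    if not np.all(np.isfinite(Z)):
        raise ClassifierError("training features contain non-finite values")
    if standardize:
        mean = Z.mean(axis=0)
        scale = Z.std(axis=0)
        scale[scale == 0.0] = 1.0
    else:
        mean = np.zeros(Z.shape[1])
        scale = np.ones(Z.shape[1])
    Zs = (Z - mean) / scale
    clf = LinearSVC(
        C=C, penalty="l2", loss="squared_hinge", dual=False, tol=1e-6, max_iter=100_000
    )
    clf.fit(Zs, yb)
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
    return LinearSVMModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        mean=mean,
        scale=scale,
        C=C,
        feature_names=names,
    )


def decision_function(model: LinearSVMModel, X) -> np.ndarray:
    return model.standardize(X) @ model.weights + model.bias


def predict(model: LinearSVMModel, X) -> np.ndarray:
    """Labels from the sign of the decision function (0 -> patient)."""
    scores = decision_function(model, X)
    return np.where(scores >= 0.0, POSITIVE, NEGATIVE)


def loo_predict(X, y, C: float = 1.0, standardize: bool = True) -> np.ndarray:
    """Leave-one-out predictions, one per sample, in input order.

    Each fold refits the standardization and the SVM on the other n - 1
    samples; a fold whose training labels collapse to one class is an
    error naming the held-out sample.
    """
    Z = _as_matrix(X)
    yb = _as_binary(y)
    n = len(Z)
    if n < 3:
        raise ClassifierError("leave-one-out needs at least 3 samples")
    out = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        if len(np.unique(yb[mask])) < 2:
            raise ClassifierError(f"fold holding out sample {i} has a single training class")
        model = train(Z[mask], yb[mask], C=C, standardize=standardize)
        out[i] = predict(model, Z[i : i + 1])[0]
        mask[i] = True
    return out.astype(str)


# ---------------------------------------------------------------------------
# confusion matrices and metrics

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with patient as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ClassifierError("confusion counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class Metrics:
    """Standard binary metrics; a ratio with zero denominator is None."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    t = _as_binary(y_true)
    p = _as_binary(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fn=int(np.sum((t == 1) & (p == 0))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fp=int(np.sum((t == 0) & (p == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(counts: ConfusionCounts) -> Metrics:
    if counts.n == 0:
        raise ClassifierError("empty confusion matrix")
    accuracy = _ratio(counts.tp + counts.tn, counts.n)
    sensitivity = _ratio(counts.tp, counts.n_pos)
    specificity = _ratio(counts.tn, counts.n_neg)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return Metrics(accuracy, sensitivity, specificity, precision, f1)


def round_half_up(value: float, digits: int = 4) -> float:
    """Decimal half-up rounding, matching how printed metrics are rounded."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def solve_confusion(
    n_pos: int,
    n_neg: int,
    accuracy: float | None = None,
    sensitivity: float | None = None,
    specificity: float | None = None,
    digits: int = 4,
) -> ConfusionCounts:
    """Invert printed metrics back to the unique integer confusion matrix.

    Enumerates all (TP, TN) with 0 <= TP <= n_pos, 0 <= TN <= n_neg and
    keeps the pairs whose metrics round (half-up, ``digits`` places) to
    every supplied value.  Raises if none or several survive.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ClassifierError("cohort sizes must be positive")
    supplied = {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
    }
    supplied = {k: v for k, v in supplied.items() if v is not None}
    if not supplied:
        raise ClassifierError("at least one metric must be supplied")
    matches = []
    for tp, tn in product(range(n_pos + 1), range(n_neg + 1)):
        counts = ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
        m = metrics_from_confusion(counts)
        if all(
            round_half_up(getattr(m, name), digits) == round_half_up(value, digits)
            for name, value in supplied.items()
        ):
            matches.append(counts)
    if not matches:
        raise InconsistentConfusionError(
            f"no integer confusion matrix with n_pos={n_pos}, n_neg={n_neg} "
            f"reproduces {supplied} at {digits} d.p."
        )
    if len(matches) > 1:
        raise AmbiguousConfusionError(
            f"{len(matches)} confusion matrices reproduce {supplied}; "
            "supply more metrics"
        )
    return matches[0]
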