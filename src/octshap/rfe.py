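"""Recursive feature elimination driven by SHAP relevance (RFE-SHAP).

Starting from the full feature set, each iteration (i) evaluates the
linear SVM by leave-one-out on the active features, (ii) fits on all
samples and ranks the active features by mean |SHAP|, and (iii) discards
the least relevant feature, until a single feature remains.  The subset
size maximizing LOO accuracy along the trace is selected; at a tie the
smallest subset wins.

By default the SHAP ranking at each step comes from one model fitted on
all samples, explained on all samples against the training background --
deterministic and cheap.  ``rank_per_fold=True`` instead averages the
mean-|SHAP| ranking over the leave-one-out fold models.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    ClassifierError,
    ConfusionCounts,
    Metrics,
    confusion_from_predictions,
    loo_predict,
    metrics_from_confusion,
    predict,
    train,
)
from .explain import aggregate_by, linear_shap, mean_abs_shap, ranking_from_values
from .features import FeatureTable


@dataclass(frozen=True)
class RFEStep:
    """State recorded at one trace point with N active features."""

    n: int
    features: tuple[str, ...]
    metrics: Metrics
    confusion: ConfusionCounts
    ranking: pd.DataFrame = field(repr=False)
    eliminated: str | None


@dataclass(frozen=True)
class RFETrace:
    steps: list[RFEStep]
    C: float
    options: dict

    def accuracy_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_features": [s.n for s in self.steps],
                "loo_accuracy": [s.metrics.accuracy for s in self.steps],
                "eliminated": [s.eliminated for s in self.steps],
            }
        )

    def step_at(self, n: int) -> RFEStep:
        for step in self.steps:
            if step.n == n:
                return step
        raise KeyError(f"no trace step with {n} active features")


@dataclass(frozen=True)
class SelectionResult:
    """Optimal subset: smallest N attaining the maximal LOO accuracy."""

    n_relevant: int
    selected_features: tuple[str, ...]
    accuracy: float


def run_rfe_shap(
    table: FeatureTable,
    C: float = 1.0,
    rank_per_fold: bool = False,
    standardize: bool = True,
) -> RFETrace:
    """Full elimination trace from all features down to one.

    Deterministic given the table and options.  Elimination tie-break:
    among features with equal mean |SHAP|, the one later in the table's
    column order is dropped.
    """
    X, y = table.X, table.y
    if X.shape[1] < 2:
        raise ClassifierError("RFE needs at least 2 features")
    if not np.all(np.isfinite(X.to_numpy())):
        raise ClassifierError("feature table contains non-finite values")
    if len(pd.unique(y)) < 2:
        raise ClassifierError("both classes must be present")

    active = list(X.columns)
    steps: list[RFEStep] = []
    while active:
        Xa = X[active]
        if rank_per_fold:
            preds, ranking = _loo_with_fold_ranking(Xa, y, C, standardize)
        else:
            preds = loo_predict(Xa, y, C=C, standardize=standardize)
            model = train(Xa, y, C=C, standardize=standardize)
            ranking = mean_abs_shap(linear_shap(model, Xa, Xa))
        confusion = confusion_from_predictions(y, preds)
        metrics = metrics_from_confusion(confusion)
        eliminated = ranking["feature"].iloc[-1] if len(active) > 1 else None
        steps.append(
            RFEStep(
                n=len(active),
                features=tuple(active),
                metrics=metrics,
                confusion=confusion,
                ranking=ranking,
                eliminated=eliminated,
            )
        )
        if eliminated is None:
            break
        active.remove(eliminated)
    return RFETrace(
        steps=steps,
        C=C,
        options={"rank_per_fold": rank_per_fold, "standardize": standardize},
    )


def _loo_with_fold_ranking(X: pd.DataFrame, y, C: float, standardize: bool):
    """LOO predictions plus the fold-averaged mean-|SHAP| ranking."""
    Z = X.to_numpy()
    n = len(Z)
    if n < 3:
        raise ClassifierError("leave-one-out needs at least 3 samples")
    preds = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    fold_means = np.zeros(X.shape[1])
    for i in range(n):
        mask[i] = False
        if len(pd.unique(np.asarray(y)[mask])) < 2:
            raise ClassifierError(f"fold holding out sample {i} has a single training class")
        model = train(X.iloc[mask], np.asarray(y)[mask], C=C, standardize=standardize)
        preds[i] = predict(model, Z[i : i + 1])[0]
        shap = linear_shap(model, X.iloc[mask], X)
        fold_means += shap.values.abs().mean(axis=0).to_numpy()
        mask[i] = True
    means = pd.Series(fold_means / n, index=X.columns)
    return preds.astype(str), ranking_from_values(means)


def select_optimal(trace: RFETrace) -> SelectionResult:
    """Smallest N among the argmax of LOO accuracy along the trace."""
    if not trace.steps:
        raise ClassifierError("empty trace")
    best = max(s.metrics.accuracy for s in trace.steps)
    candidates = [s for s in trace.steps if s.metrics.accuracy == best]
    chosen = min(candidates, key=lambda s: s.n)
    return SelectionResult(
        n_relevant=chosen.n,
        selected_features=chosen.features,
        accuracy=best,
    )


def report(
    trace: RFETrace,
    selection: SelectionResult,
    out_prefix: str | Path,
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    """Materialize a completed run as data files.

    Writes ``<prefix>_accuracy_vs_n.csv`` (one row per trace step),
    ``<prefix>_ranking.csv`` (mean-|SHAP| ranking at the selected step),
    ``<prefix>_aggregates.json`` (relevance summed by measurement,
    structure and zone), ``<prefix>_metrics.json`` (LOO metrics and
    confusion at the selected step) and ``<prefix>_run.json`` (config
    echo).  Byte-identical across reruns with the same inputs.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["accuracy_vs_n"] = prefix.with_name(prefix.name + "_accuracy_vs_n.csv")
    trace.accuracy_curve().to_csv(paths["accuracy_vs_n"], index=False)

    step = trace.step_at(selection.n_relevant)
    paths["ranking"] = prefix.with_name(prefix.name + "_ranking.csv")
    step.ranking.to_csv(paths["ranking"], index=False)

    aggregates = {
        grouping: aggregate_by(step.ranking, grouping).to_dict(orient="records")
        for grouping in ("measurement", "structure", "zone")
    }
    paths["aggregates"] = prefix.with_name(prefix.name + "_aggregates.json")
    paths["aggregates"].write_text(json.dumps(aggregates, indent=2) + "\n")

    m, c = step.metrics, step.confusion
    metrics_payload = {
        "n_relevant": selection.n_relevant,
        "selected_features": list(selection.selected_features),
        "accuracy": m.accuracy,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "precision": m.precision,
        "f1": m.f1,
        "confusion": {"tp": c.tp, "fn": c.fn, "tn": c.tn, "fp": c.fp},
    }
    paths["metrics"] = prefix.with_name(prefix.name + "_metrics.json")
    paths["metrics"].write_text(json.dumps(metrics_payload, indent=2) + "\n")

    run_payload = {
        "C": trace.C,
        "options": trace.options,
        "n_steps": len(trace.steps),
        "python": platform.python_version(),
    }
    if extra_metadata:
        run_payload.update(extra_metadata)
    paths["run"] = prefix.with_name(prefix.name + "_run.json")
    paths["run"].write_text(json.dumps(run_payload, indent=2) + "\n")
    return paths
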