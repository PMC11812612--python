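"""Exact Shapley attributions for the linear SVM and SHAP-based rankings.

For a linear decision function and a feature-independent (interventional)
background, the Shapley value of feature j on sample i has the closed form

    phi_ij = w_j * (z_ij - mean_background_j)

computed on the standardized scale the model lives on, with base value
equal to the mean decision function over the background.  This module
implements that closed form, a brute-force coalition-enumeration oracle
used to verify it, the mean-|SHAP| feature ranking, and relevance
aggregation by measurement type, retinal structure, or zone.

Attributions stay on the standardized feature scale: a consistent scale is
required for |phi| rankings to be meaningful, and the model's own scale is
the natural one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .classify import LinearSVMModel, decision_function
from .features import parse_feature_name

MAX_BRUTE_FORCE_FEATURES = 12


class ShapError(ValueError):
    pass


@dataclass(frozen=True)
class ShapMatrix:
    """Per-sample, per-feature attributions plus the background base value.

    Efficiency holds row-wise: the attributions of a sample sum to its
    decision value minus ``base_value``.
    """

    values: pd.DataFrame  # samples x features
    base_value: float


def linear_shap(model: LinearSVMModel, background, X) -> ShapMatrix:
    """Exact interventional Shapley values of the linear decision function.

    ``background`` defines the reference distribution (typically the
    model's training samples); ``X`` holds the samples to explain.
    """
    bg = model.standardize(background)
    if bg.shape[0] == 0:
        raise ShapError("background must contain at least one sample")
    Z = model.standardize(X)
    mu = bg.mean(axis=0)
    phi = (Z - mu) * model.weights
    base = float(mu @ model.weights + model.bias)
    names = model.feature_names or [f"f{j}" for j in range(Z.shape[1])]
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Z))
    return ShapMatrix(pd.DataFrame(phi, index=index, columns=list(names)), base)


def brute_force_shapley(value_function, instance, background) -> np.ndarray:
    """Shapley values by exhaustive coalition enumeration (test oracle).

    ``value_function`` maps a (samples x features) matrix to decision
    values.  The coalition value v(S) is the mean of ``value_function``
    over background rows whose S-columns are replaced by the instance's
    values (the interventional expectation).  phi_j is the Shapley-weighted
    sum of marginal contributions v(S + j) - v(S) over all S not
    containing j.  Limited to 12 features (2^12 coalitions).
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    m = x.size
    if bg.shape[1] != m:
        raise ShapError("instance and background disagree on feature count")
    if m > MAX_BRUTE_FORCE_FEATURES:
        raise ShapError(
            f"brute force enumeration limited to {MAX_BRUTE_FORCE_FEATURES} features, got {m}"
        )
    # v(S) for every coalition bitmask
    v = np.empty(1 << m)
    for mask in range(1 << m):
        mixed = bg.copy()
        for j in range(m):
            if mask >> j & 1:
                mixed[:, j] = x[j]
        v[mask] = float(np.mean(value_function(mixed)))
    weight = [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    phi = np.zeros(m)
    for j in range(m):
        for mask in range(1 << m):
            if mask >> j & 1:
                continue
            s = bin(mask).count("1")
            phi[j] += weight[s] * (v[mask | 1 << j] - v[mask])
    return phi


def mean_abs_shap(shap: ShapMatrix) -> pd.DataFrame:
    """Rank features by the mean over samples of |phi|.

    Returns a frame with columns ``feature``, ``mean_abs_shap``, ``rank``
    (1 = most relevant), sorted non-increasing; ties keep the column order
    of the SHAP matrix (canonical order for pipeline-built matrices).
    """
    if len(shap.values) == 0:
        raise ShapError("cannot rank features from an empty SHAP matrix")
    means = shap.values.abs().mean(axis=0)
    ranking = (
        means.rename("mean_abs_shap")
        .rename_axis("feature")
        .reset_index()
        .sort_values("mean_abs_shap", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking


def ranking_from_values(values: pd.Series) -> pd.DataFrame:
    """Build a ranking frame from precomputed per-feature mean |SHAP|."""
    fake = ShapMatrix(pd.DataFrame([values.abs()]), 0.0)
    return mean_abs_shap(fake)


GROUPINGS = ("measurement", "structure", "zone")


def aggregate_by(ranking: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Sum mean-|SHAP| relevance within measurement, structure or zone groups.

    The group sums of any grouping total the same grand sum (the partition
    covers all features), so relative group weights are comparable across
    groupings.  Returns columns ``group``, ``aggregate_shap``,
    ``n_features``, sorted by descending aggregate.
    """
    if grouping not in GROUPINGS:
        raise ShapError(f"grouping must be one of {GROUPINGS}, got {grouping!r}")
    idx = GROUPINGS.index(grouping)
    keys = [parse_feature_name(name)[idx] for name in ranking["feature"]]
    out = (
        ranking.assign(group=keys)
        .groupby("group", sort=False)
        .agg(aggregate_shap=("mean_abs_shap", "sum"), n_features=("feature", "size"))
        .reset_index()
        .sort_values(["aggregate_shap", "group"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    out["group"] = out["group"].astype(str)
    return out


def explain_table(model: LinearSVMModel, background, X) -> tuple[ShapMatrix, pd.DataFrame]:
    """Convenience: SHAP matrix plus its mean-|SHAP| ranking."""
    shap = linear_shap(model, background, X)
    return shap, mean_abs_shap(shap)


def shap_efficiency_gap(model: LinearSVMModel, shap: ShapMatrix, X) -> float:
    """Max row-wise |sum(phi) - (f(x) - base)|; zero for exact attributions."""
    f = decision_function(model, X)
    return float(np.max(np.abs(shap.values.sum(axis=1).to_numpy() - (f - shap.base_value))))
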