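"""Linear SVM training, LOO protocol, and confusion-matrix utilities."""

import numpy as np
import pytest
from scipy.optimize import minimize

import octshap as o
from octshap.classify import (
    AmbiguousConfusionError,
    ClassifierError,
    round_half_up,
)


def _clusters(rng, n=20, sep=10.0, sd=0.1, d=2):
    """Two well-separated Gaussian clusters; first half patients."""
    X = np.vstack(
        [rng.normal(+sep, sd, size=(n // 2, d)), rng.normal(-sep, sd, size=(n // 2, d))]
    )
    y = np.array(["patient"] * (n // 2) + ["control"] * (n // 2))
    return X, y


class TestTrain:
    def test_separable_clusters_classified_perfectly(self, rng):
        X, y = _clusters(rng)
        model = o.train(X, y)
        assert np.array_equal(o.predict(model, X), y)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ClassifierError, match="single class"):
            o.train(X, np.array(["patient"] * 5))

    def test_duplicating_every_sample_keeps_decision_function(self, rng):
        """The objective sums squared-hinge losses, so duplicating every
        sample doubles the data term; halving C restores the identical
        optimization problem and hence the identical decision function."""
        X, y = _clusters(rng, n=12, sep=2.0, sd=1.0)
        model = o.train(X, y, C=1.0)
        doubled = o.train(np.vstack([X, X]), np.concatenate([y, y]), C=0.5)
        probe = rng.normal(size=(6, 2))
        assert np.allclose(
            o.decision_function(model, probe),
            o.decision_function(doubled, probe),
            atol=1e-4,
        )

    def test_objective_matches_independent_minimizer(self, rng):
        """The fit reaches the L2 + squared-hinge optimum found by a
        generic numerical optimizer on the same (intercept-regularized)
        objective."""
        X = rng.normal(size=(8, 2))
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        ypm = 2.0 * y - 1.0
        C = 1.0

        def objective(theta):
            w, b = theta[:2], theta[2]
            margins = np.maximum(0.0, 1.0 - ypm * (X @ w + b))
            return 0.5 * (w @ w + b * b) + C * np.sum(margins**2)

        oracle = min(
            minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in (np.zeros(3), np.array([1.0, -1.0, 0.5]))
        )
        model = o.train(X, y, C=C, standardize=False)
        fitted = objective(np.append(model.weights, model.bias))
        assert fitted == pytest.approx(oracle, abs=1e-4)

    def test_standardization_makes_fit_scale_invariant(self, rng):
        X, y = _clusters(rng, n=16, sep=1.5, sd=1.0)
        a, b = np.array([3.0, 0.2]), np.array([-40.0, 7.0])
        model = o.train(X, y)
        rescaled = o.train(X * a + b, y)
        probe = rng.normal(size=(10, 2))
        assert np.array_equal(
            o.predict(model, probe), o.predict(rescaled, probe * a + b)
        )


class TestPredict:
    def test_zero_decision_value_is_patient(self):
        model = o.LinearSVMModel(
            weights=np.array([1.0]),
            bias=0.0,
            mean=np.zeros(1),
            scale=np.ones(1),
            C=1.0,
        )
        assert o.predict(model, np.array([[0.0]]))[0] == "patient"
        assert o.predict(model, np.array([[-0.1]]))[0] == "control"

    def test_decision_function_is_affine(self, rng):
        X, y = _clusters(rng, n=10)
        model = o.train(X, y)
        x1, x2 = rng.normal(size=(2, 2))
        for alpha in (0.0, 0.3, 0.7, 1.0):
            mix = alpha * x1 + (1 - alpha) * x2
            expected = alpha * o.decision_function(model, x1[None]) + (
                1 - alpha
            ) * o.decision_function(model, x2[None])
            assert o.decision_function(model, mix[None]) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _clusters(rng, n=10)
        model = o.train(X, y)
        with pytest.raises(ClassifierError, match="features"):
            o.predict(model, np.zeros((3, 5)))


class TestLeaveOneOut:
    def test_separable_limit_reaches_perfect_accuracy(self, rng):
        X, y = _clusters(rng, n=20)
        preds = o.loo_predict(X, y)
        assert np.array_equal(preds, y)

    def test_predictions_invariant_to_sample_order(self, rng):
        X, y = _clusters(rng, n=14, sep=1.0, sd=1.0)
        preds = o.loo_predict(X, y)
        perm = rng.permutation(len(y))
        permuted_preds = o.loo_predict(X[perm], y[perm])
        assert np.array_equal(permuted_preds, preds[perm])

    def test_fold_class_collapse_is_identified(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        y = np.array(["patient", "control", "control", "control"])
        with pytest.raises(ClassifierError, match="sample 0"):
            o.loo_predict(X, y)

    def test_null_features_give_chance_level_accuracy(self):
        """Pure-noise features with permuted labels: LOO accuracy stays in
        [0.35, 0.65] for at least 9 of 10 seeds (binomial noise around 0.5
        at n = 200)."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 4))
            y = np.array(["patient"] * 100 + ["control"] * 100)
            rng.shuffle(y)
            acc = np.mean(o.loo_predict(X, y) == y)
            hits += 0.35 <= acc <= 0.65
        assert hits >= 9


class TestMetrics:
    def test_reported_cohort_metrics_reproduced(self):
        counts = o.ConfusionCounts(tp=77, fn=2, tn=60, fp=9)
        m = o.metrics_from_confusion(counts)
        assert round_half_up(m.accuracy) == 0.9257
        assert round_half_up(m.sensitivity) == 0.9747
        assert round_half_up(m.specificity) == 0.8696
        assert round_half_up(m.f1) == 0.9333

    def test_all_correct_gives_ones(self):
        m = o.metrics_from_confusion(o.ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (1, 1, 1, 1)

    def test_symmetric_case(self):
        m = o.metrics_from_confusion(o.ConfusionCounts(tp=1, fn=1, tn=1, fp=1))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1) == (0.5, 0.5, 0.5, 0.5)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = o.metrics_from_confusion(o.ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert m.sensitivity is None
        assert m.f1 is None
        assert m.specificity == 0.75


class TestSolveConfusion:
    def test_recovers_unique_matrix_from_sens_spec(self):
        counts = o.solve_confusion(n_pos=79, n_neg=69, sensitivity=0.9747, specificity=0.8696)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (77, 2, 60, 9)

    def test_perfect_metrics(self):
        counts = o.solve_confusion(n_pos=10, n_neg=10, accuracy=1.0, sensitivity=1.0)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (10, 0, 10, 0)

    def test_underdetermined_input_raises_ambiguity(self):
        with pytest.raises(AmbiguousConfusionError):
            o.solve_confusion(n_pos=2, n_neg=2, accuracy=0.5)

    def test_roundtrip_with_metrics_from_confusion(self, rng):
        """Whenever the solver succeeds, recomputing metrics reproduces the
        supplied values at 4 d.p."""
        for _ in range(20):
            n_pos, n_neg = rng.integers(20, 120, size=2)
            tp = int(rng.integers(0, n_pos + 1))
            tn = int(rng.integers(0, n_neg + 1))
            truth = o.ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
            m = o.metrics_from_confusion(truth)
            try:
                solved = o.solve_confusion(
                    n_pos=int(n_pos),
                    n_neg=int(n_neg),
                    accuracy=round_half_up(m.accuracy),
                    sensitivity=round_half_up(m.sensitivity),
                    specificity=round_half_up(m.specificity),
                )
            except AmbiguousConfusionError:
                continue
            assert solved == truth
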