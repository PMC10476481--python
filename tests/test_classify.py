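"""Kernel SVM, grid search, metrics, nested cross-validation."""

import numpy as np
import pandas as pd
import pytest

from hemisym.asymmetry import FeatureMatrix
from hemisym.classify import (
    KernelSpec,
    compute_metrics,
    grid_search,
    kernel_eval,
    median_pairwise_distance,
    nested_cross_validate,
    train_svm,
)
from hemisym.selection import SelectionConfig


class TestKernelEval:
    def test_rbf_at_zero_distance(self):
        x = np.array([1.0, 2.0])
        assert kernel_eval(KernelSpec("rbf", 1.5), x, x) == 1.0

    def test_rbf_at_distance_u(self):
        u = 2.0
        x, xo = np.array([0.0]), np.array([u])
        assert kernel_eval(KernelSpec("rbf", u), x, xo) == pytest.approx(np.exp(-1))

    def test_polynomial_example(self):
        x = np.array([1.0, 1.0])
        assert kernel_eval(KernelSpec("polynomial", 2), x, x) == 9.0

    def test_sigmoid_form(self):
        spec = KernelSpec("sigmoid", None, 0.5)
        x, xo = np.array([1.0, 0.0]), np.array([2.0, 0.0])
        assert kernel_eval(spec, x, xo) == pytest.approx(np.tanh(0.5 * 2.0 + 0.5))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_eval(KernelSpec("rbf", 1.0), np.zeros(2), np.zeros(3))

    def test_symmetry_in_arguments(self, rng):
        for kind, u in (("rbf", 1.3), ("polynomial", 3), ("sigmoid", None)):
            x, xo = rng.normal(size=4), rng.normal(size=4)
            spec = KernelSpec(kind, u)
            assert kernel_eval(spec, x, xo) == pytest.approx(kernel_eval(spec, xo, x))

    def test_rbf_range(self, rng):
        spec = KernelSpec("rbf", 0.7)
        for _ in range(20):
            v = kernel_eval(spec, rng.normal(size=3), rng.normal(size=3))
            assert 0 < v <= 1


def _blobs(seed=0, n=40, sep=6.0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(-sep / 2, 1.0, (n // 2, 2)), rng.normal(sep / 2, 1.0, (n // 2, 2))]
    )
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return X, y


class TestTrainSVM:
    def test_separable_blobs_fit_perfectly(self):
        X, y = _blobs()
        # separability sanity check by the midpoint rule (independent of SVM)
        assert ((X.sum(axis=1) > 0).astype(int) * 2 - 1 == y).all()
        model = train_svm(X, y, KernelSpec("rbf", 2.0), C_reg=10.0)
        assert (model.predict(X) == y).all()

    def test_decision_function_reconstruction(self, rng):
        X, y = _blobs(seed=3)
        for spec in (KernelSpec("rbf", 2.0), KernelSpec("polynomial", 2), KernelSpec("sigmoid")):
            model = train_svm(X, y, spec, C_reg=1.0)
            pts = rng.normal(scale=3.0, size=(20, 2))
            manual = model.decision_values(pts)
            solver = model._svc.decision_function(pts)
            assert np.abs(manual - solver).max() < 1e-8
            assert (np.where(manual >= 0, 1, -1) == model.predict(pts)).all() or (
                np.abs(manual) < 1e-10
            ).any()

    def test_duplication_invariance(self, rng):
        X, y = _blobs(seed=5)
        grid = rng.normal(scale=4.0, size=(30, 2))
        m1 = train_svm(X, y, KernelSpec("rbf", 2.0), C_reg=1.0)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]), KernelSpec("rbf", 2.0), C_reg=1.0)
        assert (m1.predict(grid) == m2.predict(grid)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), [1, 1, 1, 1])

    def test_non_finite_rejected(self):
        X, y = _blobs()
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_svm(X, y)


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = _blobs()
        assert grid_search(X, y, "rbf", [1.0], [2.0], folds=4) == (1.0, 2.0)

    def test_separable_toy_reaches_perfect_cv(self):
        X, y = _blobs()
        C, u = grid_search(X, y, "rbf", [0.1, 1.0, 10.0], [0.5, 2.0, 8.0], folds=4, seed=0)
        spec = KernelSpec("rbf", u)
        model = train_svm(X, y, spec, C)
        assert (model.predict(X) == y).all()

    def test_grid_order_invariance(self):
        X, y = _blobs(seed=2)
        a = grid_search(X, y, "rbf", [0.1, 1.0, 10.0], [0.5, 2.0], folds=4, seed=1)
        b = grid_search(X, y, "rbf", [10.0, 0.1, 1.0], [2.0, 0.5], folds=4, seed=1)
        assert a == b

    def test_empty_grid_rejected(self):
        X, y = _blobs()
        with pytest.raises(ValueError):
            grid_search(X, y, "rbf", [], [1.0])


class TestMetrics:
    def test_hand_computed_counts(self):
        y_true = [1] * 50 + [0] * 50
        y_pred = [1] * 45 + [0] * 5 + [1] * 2 + [0] * 48
        m = compute_metrics(y_true, y_pred, positive_class=1)
        assert (m.tp, m.fn, m.tn, m.fp) == (45, 5, 48, 2)
        assert m.accuracy == pytest.approx(0.93)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.96)

    def test_all_correct(self):
        m = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0], positive_class=1)
        assert m.accuracy == m.sensitivity == m.specificity == 1.0

    def test_missing_class_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 1], [1, 1], positive_class=1)
        with pytest.raises(ValueError):
            compute_metrics([0, 0], [0, 0], positive_class=1)

    def test_accuracy_decomposition_identity(self, rng):
        for _ in range(10):
            y_true = rng.integers(0, 2, 30)
            y_pred = rng.integers(0, 2, 30)
            if len(set(y_true)) < 2:
                continue
            m = compute_metrics(y_true, y_pred, positive_class=1)
            p, n = m.tp + m.fn, m.tn + m.fp
            assert m.accuracy == pytest.approx(
                (m.sensitivity * p + m.specificity * n) / (p + n)
            )


def _toy_matrix(seed=0, n_per=12, informative=True):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(2 * n_per)]
    y = pd.Series(["NC"] * n_per + ["AD"] * n_per, index=ids)
    X = pd.DataFrame(rng.normal(size=(2 * n_per, 6)),
                     columns=[f"n{i}" for i in range(6)], index=ids)
    if informative:
        X["sig"] = np.where(y == "NC", -3.0, 3.0) + rng.normal(0, 0.4, 2 * n_per)
    return FeatureMatrix(X, y, "whole", {})


class TestNestedCV:
    def test_separable_informative_feature_high_accuracy(self):
        fm = _toy_matrix()
        res = nested_cross_validate(
            fm, ("NC", "AD"), selection_cfg=SelectionConfig(max_k=2, inner_folds=3, n_candidates=7),
            outer_folds=3, repeats=1, seed=0,
        )
        assert res.mean["accuracy"] >= 0.95

    def test_seed_determinism(self):
        fm = _toy_matrix(seed=4)
        kwargs = dict(selection_cfg=None, outer_folds=3, repeats=2, seed=9)
        a = nested_cross_validate(fm, ("NC", "AD"), **kwargs)
        b = nested_cross_validate(fm, ("NC", "AD"), **kwargs)
        assert a.mean == b.mean and a.sd == b.sd

    def test_too_few_subjects_rejected(self):
        fm = _toy_matrix(n_per=3)
        with pytest.raises(ValueError):
            nested_cross_validate(fm, ("NC", "AD"), outer_folds=5)

    def test_selection_never_sees_test_fold(self):
        """Structural leakage guard: recomputing selection from the training
        rows alone reproduces the per-fold selected subsets exactly."""
        from hemisym.classify import _standardize
        from hemisym.selection import sequential_forward_select

        fm = _toy_matrix(seed=6)
        cfg = SelectionConfig(max_k=2, inner_folds=3, n_candidates=7)
        res = nested_cross_validate(
            fm, ("NC", "AD"), selection_cfg=cfg, outer_folds=3, repeats=1, seed=5
        )
        sub = fm.pair_subset("NC", "AD")
        X = sub.X.to_numpy()
        y = np.where(sub.y.to_numpy() == "AD", 1, -1)
        from dataclasses import replace

        for i, fold in enumerate(res.folds):
            Xtr, _ = _standardize(X[fold.train_index], X[fold.test_index])
            redo = sequential_forward_select(
                pd.DataFrame(Xtr, columns=sub.X.columns),
                pd.Series(y[fold.train_index]),
                replace(cfg, seed=5 * 1000 + i),
            )
            assert redo.selected == fold.selected


def test_median_pairwise_distance_simple():
    X = np.array([[0.0], [3.0], [4.0]])
    assert median_pairwise_distance(X) == 3.0
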