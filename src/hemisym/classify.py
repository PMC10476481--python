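"""Kernel SVM training, grid search, metrics and nested cross-validation.

The classifier is the soft-margin SVM with decision function

    f(x) = sgn( sum_o beta_o y_o K(x_o, x) + q* )

and one of three kernels:

    polynomial  K(x, x') = (x.x' + 1)^u          (u = degree)
    rbf         K(x, x') = exp(-|x - x'|^2 / u^2) (u = width)
    sigmoid     K(x, x') = tanh(c x.x' + c)

The dual problem is solved by scikit-learn's SVC; the fitted support
vectors, dual coefficients and bias are stored so the decision function
is recoverable from the model parts alone (and is verified against the
solver to < 1e-8 in the tests).  RBF is the default kernel.

Evaluation metrics follow the clinical convention: the patient group (AD
or MCI) is the positive class, so sensitivity is patient recall and
specificity is control recall.  ``nested_cross_validate`` runs feature
selection and hyperparameter grid search inside every outer training
fold, never touching held-out labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

KERNEL_KINDS = ("polynomial", "rbf", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its single shape parameter ``u`` (polynomial
    degree or RBF width); ``c_sig`` is the sigmoid gain/offset constant.
    ``u=None`` on an RBF kernel means "scale from the data" (median
    pairwise distance at fit time)."""

    kind: str = "rbf"
    u: float | None = None
    c_sig: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel {self.kind!r}; expected one of {KERNEL_KINDS}")
        if self.u is not None and self.u <= 0:
            raise ValueError("kernel parameter u must be positive")
        if self.kind == "polynomial":
            if self.u is None or int(self.u) != self.u:
                raise ValueError("polynomial kernel needs a positive integer degree u")


def kernel_eval(spec: KernelSpec, x: np.ndarray, x_o: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    x_o = np.asarray(x_o, dtype=np.float64)
    if x.shape != x_o.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {x_o.shape}")
    if spec.kind == "polynomial":
        return float((x @ x_o + 1.0) ** spec.u)
    if spec.kind == "rbf":
        if spec.u is None:
            raise ValueError("rbf kernel width u is unresolved")
        return float(np.exp(-np.sum((x - x_o) ** 2) / spec.u ** 2))
    return float(np.tanh(spec.c_sig * (x @ x_o) + spec.c_sig))


def median_pairwise_distance(X: np.ndarray) -> float:
    """Median Euclidean distance between distinct rows (the classical
    bandwidth heuristic); falls back to 1.0 for degenerate inputs."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        return 1.0
    d = pdist(X)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def _svc_params(spec: KernelSpec, C_reg: float) -> dict:
    if spec.kind == "rbf":
        return {"kernel": "rbf", "C": C_reg, "gamma": 1.0 / spec.u ** 2}
    if spec.kind == "polynomial":
        return {"kernel": "poly", "C": C_reg, "degree": int(spec.u), "gamma": 1.0, "coef0": 1.0}
    return {"kernel": "sigmoid", "C": C_reg, "gamma": spec.c_sig, "coef0": spec.c_sig}


def resolve_kernel(spec: KernelSpec, X: np.ndarray) -> KernelSpec:
    """Replace a data-scaled RBF width (u=None) with the median heuristic."""
    if spec.kind == "rbf" and spec.u is None:
        return replace(spec, u=median_pairwise_distance(X))
    return spec


@dataclass
class SVMModel:
    """A fitted kernel SVM whose decision function is recoverable from its
    stored parts (support vectors, dual coefficients beta_o*y_o, bias q*)."""

    kernel: KernelSpec
    C_reg: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray  # beta_o * y_o, one per support vector
    bias: float
    _svc: SVC | None = field(default=None, repr=False)

    def decision_value(self, x: np.ndarray) -> float:
        return float(
            sum(
                c * kernel_eval(self.kernel, sv, x)
                for c, sv in zip(self.dual_coef, self.support_vectors)
            )
            + self.bias
        )

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.array([self.decision_value(row) for row in X])

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._svc is not None:
            return self._svc.predict(np.atleast_2d(np.asarray(X, dtype=np.float64))).astype(int)
        d = self.decision_values(X)
        return np.where(d >= 0, 1, -1)


def train_svm(X: np.ndarray, y: Sequence[int], kernel: KernelSpec | None = None, C_reg: float = 1.0) -> SVMModel:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("y must contain both classes, coded -1/+1")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    kernel = resolve_kernel(kernel or KernelSpec(), X)
    svc = SVC(**_svc_params(kernel, C_reg))
    svc.fit(X, y)
    return SVMModel(
        kernel=kernel,
        C_reg=C_reg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        _svc=svc,
    )


# ---------------------------------------------------------------------------
# grid search

def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    kind: str = "rbf",
    C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    u_grid: Sequence[float] = (),
    folds: int = 5,
    seed: int = 0,
    c_sig: float = 1.0,
) -> tuple[float, float]:
    """Best (C_reg, u) by mean stratified k-fold CV accuracy.

    Ties break toward smaller C_reg, then smaller u, so the winner does
    not depend on grid ordering.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(C_grid) == 0 or len(u_grid) == 0:
        raise ValueError("grids must be nonempty")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    best = None
    for C in sorted(C_grid):
        for u in sorted(u_grid):
            spec = KernelSpec(kind, u, c_sig)
            correct = 0
            total = 0
            for tr, te in splits:
                model = SVC(**_svc_params(spec, C))
                model.fit(X[tr], y[tr])
                correct += int((model.predict(X[te]) == y[te]).sum())
                total += len(te)
            acc = correct / total
            if best is None or acc > best[0]:
                best = (acc, C, u)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# metrics

@dataclass(frozen=True)
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def compute_metrics(y_true: Sequence, y_pred: Sequence, positive_class) -> Metrics:
    """Confusion counts and accuracy/sensitivity/specificity, with the
    patient group as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be same-length, nonempty")
    pos = y_true == positive_class
    if not pos.any():
        raise ValueError("no positive-class samples: sensitivity undefined")
    if pos.all():
        raise ValueError("no negative-class samples: specificity undefined")
    pred_pos = y_pred == positive_class
    m = Metrics(
        tp=int((pos & pred_pos).sum()),
        tn=int((~pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
    )
    # accuracy decomposition identity, asserted on every evaluation
    p, n = m.tp + m.fn, m.tn + m.fp
    assert abs(m.accuracy - (m.sensitivity * p + m.specificity * n) / (p + n)) < 1e-12
    return m


# ---------------------------------------------------------------------------
# nested cross-validation

@dataclass
class FoldResult:
    train_index: np.ndarray
    test_index: np.ndarray
    selected: list[str] | None
    best_C: float
    best_u: float
    metrics: Metrics


@dataclass
class EvalResult:
    """Aggregate of a (repeated) outer CV: mean and sd of each metric plus
    the per-fold details needed for leakage auditing."""

    mean: dict[str, float]
    sd: dict[str, float]
    folds: list[FoldResult]
    positive_class: str
    negative_class: str
    variant: str = ""
    selection_mode: str = "none"


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def nested_cross_validate(
    fm,
    pair: tuple[str, str],
    selection_cfg=None,
    kernel_kind: str = "rbf",
    C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    u_factors: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    inner_folds: int = 5,
    outer_folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> EvalResult:
    """Stratified (repeats x outer_folds) nested CV of one class pair.

    ``pair`` is (negative, positive) = (control, patient).  Per outer
    fold: features are standardized on the training fold; sequential
    forward selection (if ``selection_cfg`` is given) and the
    (C, u) grid search run on the training fold only; the tuned model is
    then scored once on the held-out fold.  RBF widths are the grid
    ``u_factors`` x the training fold's median pairwise distance.
    """
    from .selection import sequential_forward_select

    neg, pos = pair
    sub = fm.pair_subset(neg, pos)
    X_all = sub.X.to_numpy(dtype=np.float64)
    names = list(sub.X.columns)
    y_str = sub.y.to_numpy()
    y = np.where(y_str == pos, 1, -1)
    counts = {neg: int((y == -1).sum()), pos: int((y == 1).sum())}
    if min(counts.values()) < outer_folds:
        raise ValueError(f"need >= {outer_folds} subjects per class, got {counts}")

    cv = RepeatedStratifiedKFold(n_splits=outer_folds, n_repeats=repeats, random_state=seed)
    folds: list[FoldResult] = []
    for fold_i, (tr, te) in enumerate(cv.split(X_all, y)):
        Xtr, Xte = _standardize(X_all[tr], X_all[te])
        ytr, yte = y[tr], y[te]
        fold_seed = seed * 1000 + fold_i
        if selection_cfg is not None:
            cfg = replace(selection_cfg, seed=fold_seed)
            sel = sequential_forward_select(
                pd.DataFrame(Xtr, columns=names), pd.Series(ytr), cfg
            )
            keep = [names.index(nm) for nm in sel.selected]
            selected = list(sel.selected)
        else:
            keep = list(range(len(names)))
            selected = None
        Xtr_k, Xte_k = Xtr[:, keep], Xte[:, keep]
        if kernel_kind == "rbf":
            med = median_pairwise_distance(Xtr_k)
            u_grid = [f * med for f in u_factors]
        else:
            u_grid = list(u_factors)
        C, u = grid_search(
            Xtr_k, ytr, kernel_kind, C_grid, u_grid, folds=inner_folds, seed=fold_seed
        )
        model = train_svm(Xtr_k, ytr, KernelSpec(kernel_kind, u), C)
        pred = model.predict(Xte_k)
        folds.append(
            FoldResult(tr, te, selected, C, u, compute_metrics(yte, pred, positive_class=1))
        )

    keys = ("accuracy", "sensitivity", "specificity")
    per = {k: np.array([getattr(f.metrics, k) for f in folds]) for k in keys}
    return EvalResult(
        mean={k: float(v.mean()) for k, v in per.items()},
        sd={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in per.items()},
        folds=folds,
        positive_class=pos,
        negative_class=neg,
        variant=getattr(fm, "variant", ""),
        selection_mode="none" if selection_cfg is None else "sfs",
    )
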