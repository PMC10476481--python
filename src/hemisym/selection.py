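"""Filter + wrapper feature selection, monotonicity flags and per-structure counts.

The selector is a Fisher-score filter followed by sequential forward
selection (SFS) with a kernel-SVM wrapper:

1. Rank all candidate features by Fisher score
   F = sum_c n_c (mu_c - mu)^2 / sum_c n_c sigma_c^2  (population
   variances).  A feature that separates the classes perfectly (positive
   between-class spread, zero within-class variance) gets a +inf sentinel
   and outranks every finite score; a feature constant in both classes
   scores 0.
2. Keep the ``n_candidates`` top-ranked features, then greedily add the
   feature that maximizes stratified inner-fold CV accuracy of the
   wrapper SVM, stopping when the best improvement falls below
   ``delta_min`` or ``max_k`` features are selected.  Ties break toward
   the higher Fisher score, then the lexicographically smaller name, so
   the procedure is fully deterministic given the seed.

Monotonicity analysis flags a feature whose class means move strictly
monotonically (up or down) across the ordered groups NC -> MCI -> AD; the
per-(structure, hemisphere) tallies of selected and monotone features
summarize where discriminative asymmetry lives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classify import KernelSpec, _svc_params, resolve_kernel
from .grids import FeatureInfo

logger = logging.getLogger(__name__)

CLASS_ORDER = ("NC", "MCI", "AD")


@dataclass(frozen=True)
class SelectionConfig:
    max_k: int = 15
    delta_min: float = 0.002
    inner_folds: int = 5
    n_candidates: int = 40
    seed: int = 0
    svm_C: float = 1.0
    kernel: KernelSpec = field(default_factory=KernelSpec)

    def __post_init__(self) -> None:
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")


@dataclass
class SelectionResult:
    selected: list[str]
    fisher_scores: pd.Series
    step_accuracies: list[float]
    monotone: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        scores = {
            k: (None if np.isinf(v) else float(v))
            for k, v in self.fisher_scores.items()
        }
        return json.dumps(
            {
                "selected": self.selected,
                "step_accuracies": self.step_accuracies,
                "fisher_scores": scores,
                "monotone": self.monotone,
            },
            indent=2,
        )


def fisher_score(X: pd.DataFrame, y: Sequence) -> pd.Series:
    """Per-feature Fisher score for a binary labelling."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    A = X.to_numpy(dtype=np.float64)
    mu = A.mean(axis=0)
    num = np.zeros(A.shape[1])
    den = np.zeros(A.shape[1])
    for c in classes:
        Ac = A[y == c]
        if Ac.shape[0] < 2:
            raise ValueError(f"need >= 2 subjects per class, class {c!r} has {Ac.shape[0]}")
        num += Ac.shape[0] * (Ac.mean(axis=0) - mu) ** 2
        den += Ac.shape[0] * Ac.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = num / den
    score[(den == 0) & (num > 0)] = np.inf   # perfect separation sentinel
    score[(den == 0) & (num == 0)] = 0.0     # constant in both classes
    return pd.Series(score, index=X.columns)


def _wrapper_cv_accuracy(
    A: np.ndarray, y: np.ndarray, cols: list[int], splits, params: dict
) -> float:
    correct = 0
    total = 0
    sub = A[:, cols]
    for tr, te in splits:
        m = SVC(**params)
        m.fit(sub[tr], y[tr])
        correct += int((m.predict(sub[te]) == y[te]).sum())
        total += len(te)
    return correct / total


def sequential_forward_select(
    X: pd.DataFrame, y: Sequence, cfg: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Greedy wrapper selection maximizing inner-CV accuracy of the SVM.

    ``X`` is expected to be standardized by the caller when run inside an
    outer CV fold; the wrapper kernel width (u=None) resolves to the
    median pairwise distance of ``X``.
    """
    y = np.asarray(y)
    scores = fisher_score(X, y)
    # +inf sentinels first, then finite scores descending, then name
    order = sorted(
        X.columns,
        key=lambda n: (not np.isinf(scores[n]), -scores[n] if np.isfinite(scores[n]) else 0.0, n),
    )
    candidates = order[: cfg.n_candidates]

    A = X.to_numpy(dtype=np.float64)
    name_to_col = {n: i for i, n in enumerate(X.columns)}
    kernel = resolve_kernel(cfg.kernel, A)
    params = _svc_params(kernel, cfg.svm_C)
    cv = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed)
    splits = list(cv.split(A, y))

    selected: list[str] = []
    step_acc: list[float] = []
    current = -np.inf
    remaining = list(candidates)
    while remaining and len(selected) < cfg.max_k:
        best_name = None
        best_acc = -np.inf
        for name in remaining:
            cols = [name_to_col[n] for n in selected] + [name_to_col[name]]
            acc = _wrapper_cv_accuracy(A, y, cols, splits, params)
            key = (acc, scores[name], _neg_name(name))
            if best_name is None or key > (best_acc, scores[best_name], _neg_name(best_name)):
                best_name, best_acc = name, acc
        improvement = best_acc - (current if np.isfinite(current) else 0.0)
        if selected and improvement < cfg.delta_min:
            break
        selected.append(best_name)
        step_acc.append(best_acc)
        remaining.remove(best_name)
        current = best_acc
    return SelectionResult(selected, scores, step_acc)


class _neg_name(str):
    """Reverses lexicographic comparison so max() prefers the smaller name."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def monotone_flags(means: Sequence[float]) -> bool:
    """True iff the NC -> MCI -> AD mean triple is strictly increasing or
    strictly decreasing (ties are not monotone)."""
    a, b, c = (float(v) for v in means)
    if not all(np.isfinite([a, b, c])):
        raise ValueError("class means must be finite")
    return (a < b < c) or (a > b > c)


def class_means(X: pd.DataFrame, y: Sequence, order: Sequence[str] = CLASS_ORDER) -> pd.DataFrame:
    """Feature means per class, rows ordered NC, MCI, AD."""
    y = pd.Series(np.asarray(y), index=X.index)
    rows = {}
    for cls in order:
        sel = y == cls
        if not sel.any():
            raise ValueError(f"class {cls!r} absent")
        rows[cls] = X.loc[sel.to_numpy()].mean(axis=0)
    return pd.DataFrame(rows).T


def annotate_monotone(result: SelectionResult, means: pd.DataFrame) -> SelectionResult:
    """Fill ``result.monotone`` from a class-means table (training data only)."""
    for name in result.selected:
        result.monotone[name] = monotone_flags(means[name].to_numpy())
    return result


def count_by_structure(
    result: SelectionResult, metadata: Mapping[str, FeatureInfo]
) -> pd.DataFrame:
    """Selected / monotone feature counts per (structure, hemisphere)."""
    rows: dict[tuple[str, str], dict[str, int]] = {}
    for name in result.selected:
        if name not in metadata:
            raise KeyError(f"feature {name!r} missing from metadata")
        info = metadata[name]
        cell = rows.setdefault((info.structure, info.hemisphere), {"selected": 0, "monotone": 0})
        cell["selected"] += 1
        if result.monotone.get(name, False):
            cell["monotone"] += 1
    idx = pd.MultiIndex.from_tuples(sorted(rows) or [], names=["structure", "hemisphere"])
    table = pd.DataFrame(
        [rows[k] for k in sorted(rows)], index=idx, columns=["selected", "monotone"], dtype=int
    )
    return table
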