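"""Hemispheric feature-set variants: left, right, whole, difference, ratio.

Every structural feature comes in a left/right pair sharing
(structure, family, feature).  The five variants are:

left / right
    Columns of that hemisphere only (72 each with the default pipeline).
whole
    Concatenation of left and right columns (144).
difference
    One column per matched pair: |left - right| by default.  The signed
    form (left - right) is available via ``absolute=False``; the absolute
    form is the default because the asymmetry magnitude, not its sign, is
    what the classifier consumes.
ratio
    left / right per matched pair; columns whose denominator is
    degenerate (|right| <= eps) for any subject are dropped with a
    logged warning rather than imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import FeatureInfo
from .texture import FeatureVector

logger = logging.getLogger(__name__)

VARIANTS = ("left", "right", "whole", "difference", "ratio")

RATIO_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """Subjects x named features plus class labels and per-column provenance."""

    X: pd.DataFrame
    y: pd.Series
    variant: str
    meta: dict[str, FeatureInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.y.index):
            raise ValueError("X and y index mismatch")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("feature matrix contains non-finite values")

    def pair_subset(self, neg: str, pos: str) -> "FeatureMatrix":
        keep = self.y.isin([neg, pos])
        return FeatureMatrix(self.X.loc[keep], self.y.loc[keep], self.variant, self.meta)

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out.insert(0, "class", self.y)
        out.to_csv(path, index_label="subject_id")


def difference_feature(left: float, right: float, absolute: bool = True) -> float:
    if not (math.isfinite(left) and math.isfinite(right)):
        raise ValueError(f"non-finite input: left={left}, right={right}")
    d = left - right
    return abs(d) if absolute else d


def ratio_feature(left: float, right: float, eps: float = RATIO_EPS) -> float:
    if not (math.isfinite(left) and math.isfinite(right)):
        raise ValueError(f"non-finite input: left={left}, right={right}")
    if abs(right) <= eps:
        raise ZeroDivisionError(f"degenerate denominator |{right}| <= {eps}")
    return left / right


def _schema(vec: FeatureVector) -> tuple[str, ...]:
    return tuple(sorted(vec.values))


def _pair_key(info: FeatureInfo) -> tuple[str, str, str]:
    return (info.structure, info.family, info.feature)


def build_variant(
    vectors: list[FeatureVector],
    variant: str,
    absolute: bool = True,
    eps: float = RATIO_EPS,
) -> FeatureMatrix:
    """Assemble one feature-set variant from per-subject feature vectors.

    Column order is deterministic: sorted by (structure, family, feature)
    and, for the hemisphere-resolved variants, hemisphere.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if not vectors:
        raise ValueError("no feature vectors given")
    schema = _schema(vectors[0])
    meta0 = vectors[0].meta
    for v in vectors[1:]:
        if _schema(v) != schema:
            raise ValueError(f"subject {v.subject_id} has a different feature schema")

    ids = [v.subject_id for v in vectors]
    y = pd.Series([v.class_label for v in vectors], index=ids, name="class")

    if variant in ("left", "right", "whole"):
        names = [
            n for n in schema
            if variant == "whole" or meta0[n].hemisphere == variant
        ]
        names.sort(key=lambda n: (_pair_key(meta0[n]), meta0[n].hemisphere))
        data = {n: [v.values[n] for v in vectors] for n in names}
        X = pd.DataFrame(data, index=ids, columns=names)
        meta = {n: meta0[n] for n in names}
        return FeatureMatrix(X, y, variant, meta)

    # matched left/right pairs
    pairs: dict[tuple[str, str, str], dict[str, str]] = {}
    for n, info in meta0.items():
        pairs.setdefault(_pair_key(info), {})[info.hemisphere] = n
    keys = sorted(k for k, sides in pairs.items() if {"left", "right"} <= sides.keys())

    cols: dict[str, list[float]] = {}
    meta = {}
    suffix = "diff" if variant == "difference" else "ratio"
    for key in keys:
        s, fam, feat = key
        lname, rname = pairs[key]["left"], pairs[key]["right"]
        base = f"{s}_volume" if fam == "volume" else f"{s}_{fam}_{feat}"
        cname = f"{base}_{suffix}"
        if variant == "difference":
            vals = [difference_feature(v.values[lname], v.values[rname], absolute) for v in vectors]
        else:
            rvals = [v.values[rname] for v in vectors]
            if any(abs(r) <= eps for r in rvals):
                logger.warning("dropping ratio column %s: degenerate denominator", cname)
                continue
            vals = [v.values[lname] / r for v, r in zip(vectors, rvals)]
        cols[cname] = vals
        meta[cname] = FeatureInfo(s, "bilateral", fam, feat)
    X = pd.DataFrame(cols, index=ids)
    return FeatureMatrix(X, y, variant, meta)
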