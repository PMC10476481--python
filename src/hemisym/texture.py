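"""Masked 3D texture features: first-order, GLCM and run-length.

All statistics are computed strictly inside an arbitrary 3D mask.

GLCM (gray-level co-occurrence matrix)
    Normalized counts P[i, j] of ordered gray-level pairs (i at voxel v,
    j at voxel v + d*phi) with both endpoints in the mask, accumulated
    over a set of 3D direction offsets phi (default: the 13 unique
    directions of the 26-neighborhood; with symmetric closure every
    neighbor pair is counted both ways).  Features: energy = sum P^2,
    contrast = sum (i-j)^2 P, inverse difference moment
    idm = sum P / (1 + (i-j)^2), entropy = -sum P log2 P, and the
    classical marginal-moment correlation
    (sum i*j*P - mu_x mu_y) / (sd_x sd_y), defined as 0 when a marginal
    standard deviation vanishes so feature matrices stay finite.

RLM (run-length matrix)
    R[i, j-1] counts maximal collinear runs of level i and length j; a
    mask gap terminates a run.  Runs are accumulated over the same 13
    directions (a direction and its negation describe the same runs).
    The eight classical emphasis statistics are provided; gray-level
    weights use the 1-based level index so level 0 never divides by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .grids import HEMISPHERES, STRUCTURES, BinaryMask, FeatureInfo, VoxelGrid
from .phantom import SubjectRecord

Direction = tuple[int, int, int]

def _unique_13() -> tuple[Direction, ...]:
    """The 13 unique offsets of the 26-neighborhood (first nonzero
    component positive); negations are covered by symmetric accumulation
    (GLCM) or describe the same scan lines (RLM)."""
    dirs = []
    for a in (0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                d = (a, b, c)
                if d == (0, 0, 0):
                    continue
                if a == 0 and (b < 0 or (b == 0 and c < 0)):
                    continue
                dirs.append(d)
    return tuple(dirs)


DIRECTIONS_13: tuple[Direction, ...] = _unique_13()


@dataclass
class QuantizedVolume:
    """Gray levels 0..Z-1 inside the mask, sentinel -1 outside."""

    data: np.ndarray
    Z: int
    mask: BinaryMask

    def __post_init__(self) -> None:
        inside = self.data[self.mask.data]
        if inside.size and (inside.min() < 0 or inside.max() >= self.Z):
            raise ValueError("in-mask levels must lie in [0, Z-1]")


def quantize(v: VoxelGrid, mask: BinaryMask, Z: int) -> QuantizedVolume:
    """Uniform quantization over the in-mask intensity range.

    Bin edges split [min, max] into Z equal bins; the maximum maps to
    Z-1; a constant region maps entirely to level 0.
    """
    if Z < 2:
        raise ValueError(f"Z must be >= 2, got {Z}")
    if not mask:
        raise ValueError("mask is empty")
    out = np.full(v.data.shape, -1, dtype=np.int32)
    vals = v.data[mask.data]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        out[mask.data] = 0
    else:
        lev = np.floor((vals - lo) / (hi - lo) * Z).astype(np.int32)
        np.clip(lev, 0, Z - 1, out=lev)
        out[mask.data] = lev
    return QuantizedVolume(out, Z, mask)


# ---------------------------------------------------------------------------
# GLCM

@dataclass(frozen=True)
class GLCMSpec:
    Z: int
    d: int = 1
    directions: tuple[Direction, ...] = DIRECTIONS_13
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("distance d must be a positive integer")
        if not self.directions:
            raise ValueError("directions must be nonempty")
        if self.symmetric:
            seen = set(self.directions)
            for dd in self.directions:
                if tuple(-x for x in dd) in seen and dd != tuple(-x for x in dd):
                    raise ValueError(f"direction {dd} duplicated as its negation in symmetric mode")


@dataclass
class GLCM:
    P: np.ndarray
    spec: GLCMSpec
    pair_count: int


def _offset_slices(shape: Sequence[int], offset: Sequence[int]):
    src, dst = [], []
    for n, o in zip(shape, offset):
        if abs(o) >= n:
            return None
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm(q: QuantizedVolume, spec: GLCMSpec) -> GLCM:
    Z = spec.Z
    arr = q.data
    counts = np.zeros((Z, Z), dtype=np.int64)
    for direction in spec.directions:
        offset = tuple(spec.d * o for o in direction)
        sl = _offset_slices(arr.shape, offset)
        if sl is None:
            continue
        src, dst = sl
        a = arr[src].ravel()
        b = arr[dst].ravel()
        valid = (a >= 0) & (b >= 0)
        if not valid.any():
            continue
        pair = a[valid].astype(np.int64) * Z + b[valid]
        counts += np.bincount(pair, minlength=Z * Z).reshape(Z, Z)
    if spec.symmetric:
        counts = counts + counts.T
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no valid voxel pairs for the given mask/offsets")
    return GLCM(counts.astype(np.float64) / total, spec, total)


def glcm_features(g: GLCM) -> dict[str, float]:
    P = g.P
    Z = P.shape[0]
    i = np.arange(Z, dtype=np.float64)
    diff2 = (i[:, None] - i[None, :]) ** 2
    energy = float((P ** 2).sum())
    contrast = float((diff2 * P).sum())
    idm = float((P / (1.0 + diff2)).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mx = float(i @ px)
    my = float(i @ py)
    sx = float(np.sqrt(((i - mx) ** 2) @ px))
    sy = float(np.sqrt(((i - my) ** 2) @ py))
    if sx * sy < 1e-15:
        corr = 0.0
    else:
        corr = (float((np.outer(i, i) * P).sum()) - mx * my) / (sx * sy)
    return {
        "energy": energy,
        "contrast": contrast,
        "idm": idm,
        "entropy": entropy,
        "correlation": corr,
    }


# ---------------------------------------------------------------------------
# run-length matrix

@dataclass
class RunLengthMatrix:
    R: np.ndarray  # Z x Lmax integer counts; R[i, j-1] = runs of level i, length j
    n_runs: int
    Z: int
    directions: tuple[Direction, ...]


def _shift_full(a: np.ndarray, offset: Sequence[int]) -> np.ndarray:
    """Value of ``a`` at position v - offset (zero-padded): out[v] = a[v - o]."""
    out = np.zeros_like(a)
    sl = _offset_slices(a.shape, offset)
    if sl is None:
        return out
    src, dst = sl
    out[dst] = a[src]
    return out


def _run_starts_and_lengths(arr: np.ndarray, direction: Direction):
    """Per-voxel run lengths along ``direction``.

    ``L[v]`` = length of the maximal run beginning at v (only meaningful
    at run starts).  Computed with the recurrence
    L[v] = 1 + (L[v + d] if arr[v] == arr[v + d] else 0), swept slice by
    slice against the direction's leading axis.
    """
    shape = arr.shape
    # same[v]: v + d in bounds, both in mask, equal level
    same = np.zeros(shape, dtype=bool)
    sl = _offset_slices(shape, direction)
    if sl is not None:
        src, dst = sl
        a = arr[src]
        b = arr[dst]
        same[src] = (a >= 0) & (a == b)
    axis = next(i for i, d in enumerate(direction) if d != 0)
    step = direction[axis]
    rest = tuple(direction[i] for i in range(3) if i != axis)
    inmask = arr >= 0
    L = np.zeros(shape, dtype=np.int64)
    order = range(shape[axis] - 1, -1, -1) if step > 0 else range(shape[axis])
    for x in order:
        idx = [slice(None)] * 3
        idx[axis] = x
        idx_t = tuple(idx)
        nxt = x + step
        if 0 <= nxt < shape[axis]:
            jdx = list(idx)
            jdx[axis] = nxt
            l_next = _shift2(L[tuple(jdx)], rest)
            L[idx_t] = inmask[idx_t] * (1 + same[idx_t] * l_next)
        else:
            L[idx_t] = inmask[idx_t].astype(np.int64)
    # run starts: in-mask voxels not continued from the previous voxel
    prev_same = _shift_full(same, direction)  # prev_same[v] = same[v - d]
    starts = inmask & ~prev_same
    return starts, L


def _shift2(a2: np.ndarray, offset2: Sequence[int]) -> np.ndarray:
    """2D analogue of :func:`_shift_full` for the in-slice displacement:
    out[y, z] = a2[y + o1, z + o2] (zero-padded)."""
    out = np.zeros_like(a2)
    sl = _offset_slices(a2.shape, [-o for o in offset2])
    if sl is None:
        return out
    src, dst = sl
    out[dst] = a2[src]
    return out


def rlm(q: QuantizedVolume, directions: Iterable[Direction] = DIRECTIONS_13) -> RunLengthMatrix:
    directions = tuple(directions)
    arr = q.data
    levels_all: list[np.ndarray] = []
    lengths_all: list[np.ndarray] = []
    for d in directions:
        starts, L = _run_starts_and_lengths(arr, d)
        levels_all.append(arr[starts])
        lengths_all.append(L[starts])
    levels = np.concatenate(levels_all)
    lengths = np.concatenate(lengths_all)
    if levels.size == 0:
        return RunLengthMatrix(np.zeros((q.Z, 1), dtype=np.int64), 0, q.Z, directions)
    lmax = int(lengths.max())
    flat = levels.astype(np.int64) * lmax + (lengths - 1)
    R = np.bincount(flat, minlength=q.Z * lmax).reshape(q.Z, lmax)
    return RunLengthMatrix(R, int(R.sum()), q.Z, directions)


def rlm_features(r: RunLengthMatrix) -> dict[str, float]:
    if r.n_runs < 1:
        raise ValueError("run-length matrix has no runs")
    R = r.R.astype(np.float64)
    n = float(r.n_runs)
    j = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    g = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    return {
        "sre": float((R / j ** 2).sum() / n),
        "lre": float((R * j ** 2).sum() / n),
        "lgre": float((R / g ** 2).sum() / n),
        "hgre": float((R * g ** 2).sum() / n),
        "srlge": float((R / (j ** 2) / (g ** 2)).sum() / n),
        "lrlge": float((R * j ** 2 / g ** 2).sum() / n),
        "srhge": float((R * g ** 2 / j ** 2).sum() / n),
        "lrhge": float((R * j ** 2 * g ** 2).sum() / n),
    }


# ---------------------------------------------------------------------------
# first-order statistics

def first_order_features(v: VoxelGrid, mask: BinaryMask, bins: int = 32) -> dict[str, float]:
    """Mean/variance of raw in-mask intensities (population variance) plus
    histogram energy and entropy over ``bins`` uniform bins.

    In-mask values are sorted before reduction so the result depends only
    on the value multiset, not on mask traversal order (this makes
    mirror-image regions yield bit-identical features).
    """
    if not mask:
        raise ValueError("mask is empty")
    vals = np.sort(v.data[mask.data], kind="stable")
    mean = float(vals.mean())
    var = float(vals.var())
    counts, _ = np.histogram(vals, bins=bins)
    p = counts / counts.sum()
    nz = p[p > 0]
    return {
        "mean": mean,
        "variance": var,
        "energy": float((p ** 2).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
    }


# ---------------------------------------------------------------------------
# per-subject feature extraction

@dataclass(frozen=True)
class FeatureSpec:
    """Knobs of the texture pipeline.  The gray-level count Z, offset
    distance d and direction set are deliberate defaults (not dictated by
    any standard) and are recorded in output metadata."""

    Z: int = 32
    d: int = 1
    bins: int = 32
    directions: tuple[Direction, ...] = DIRECTIONS_13
    symmetric: bool = True
    normalize: bool = True

    def to_json(self) -> dict:
        return {
            "Z": self.Z,
            "d": self.d,
            "bins": self.bins,
            "directions": [list(d) for d in self.directions],
            "symmetric": self.symmetric,
            "normalize": self.normalize,
        }


@dataclass
class FeatureVector:
    subject_id: str
    class_label: str
    values: dict[str, float] = field(default_factory=dict)
    meta: dict[str, FeatureInfo] = field(default_factory=dict)


def feature_name(structure: str, hemisphere: str, family: str, feature: str) -> str:
    if family == "volume":
        return f"{structure}_{hemisphere}_volume"
    return f"{structure}_{hemisphere}_{family}_{feature}"


def extract_subject_features(s: SubjectRecord, spec: FeatureSpec = FeatureSpec()) -> FeatureVector:
    """144 features per subject: for each of 4 structures x 2 hemispheres,
    1 volume + 4 first-order + 5 GLCM + 8 RLM features."""
    from .io_preprocess import normalize_intensity, structure_volume

    intensity = s.intensity
    if spec.normalize:
        intensity = normalize_intensity(intensity, s.labels.brain_mask())
    fv = FeatureVector(s.subject_id, s.class_label)
    for structure in STRUCTURES:
        for hemisphere in HEMISPHERES:
            try:
                mask = s.labels.mask(structure, hemisphere)
                if not mask:
                    raise ValueError("empty mask")
                values: dict[str, dict[str, float]] = {}
                values["volume"] = {"volume": structure_volume(mask)}
                values["firstorder"] = first_order_features(intensity, mask, spec.bins)
                q = quantize(intensity, mask, spec.Z)
                g = glcm(q, GLCMSpec(spec.Z, spec.d, spec.directions, spec.symmetric))
                values["glcm"] = glcm_features(g)
                values["rlm"] = rlm_features(rlm(q, spec.directions))
            except Exception as exc:
                raise type(exc)(
                    f"feature extraction failed for ({structure}, {hemisphere}) "
                    f"of subject {s.subject_id}: {exc}"
                ) from exc
            for family, feats in values.items():
                for feat, val in feats.items():
                    name = feature_name(structure, hemisphere, family, feat)
                    fv.values[name] = float(val)
                    fv.meta[name] = FeatureInfo(structure, hemisphere, family, feat)
    return fv


def extract_cohort(records: Iterable[SubjectRecord], spec: FeatureSpec = FeatureSpec()) -> list[FeatureVector]:
    return [extract_subject_features(r, spec) for r in records]


def parse_feature_name(name: str) -> FeatureInfo:
    """Invert :func:`feature_name` (used when reloading feature CSVs)."""
    parts = name.split("_")
    if len(parts) >= 3 and parts[0] in STRUCTURES and parts[1] in HEMISPHERES:
        structure, hemisphere = parts[0], parts[1]
        if parts[2] == "volume" and len(parts) == 3:
            return FeatureInfo(structure, hemisphere, "volume", "volume")
        family = parts[2]
        feature = "_".join(parts[3:])
        if family in ("firstorder", "glcm", "rlm") and feature:
            return FeatureInfo(structure, hemisphere, family, feature)
    raise ValueError(f"cannot parse feature name {name!r}")


def vectors_to_frame(vectors: Iterable[FeatureVector]):
    import pandas as pd

    vectors = list(vectors)
    names = sorted(vectors[0].values)
    df = pd.DataFrame(
        [[v.values[n] for n in names] for v in vectors],
        index=[v.subject_id for v in vectors],
        columns=names,
    )
    df.insert(0, "class", [v.class_label for v in vectors])
    df.index.name = "subject_id"
    return df


def frame_to_vectors(df) -> list[FeatureVector]:
    """Rebuild per-subject feature vectors from a feature CSV frame."""
    names = [c for c in df.columns if c != "class"]
    meta = {n: parse_feature_name(n) for n in names}
    out = []
    for sid, row in df.iterrows():
        out.append(
            FeatureVector(
                str(sid),
                str(row["class"]),
                {n: float(row[n]) for n in names},
                dict(meta),
            )
        )
    return out
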