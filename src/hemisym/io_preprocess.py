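"""NIfTI I/O, intensity normalization, denoising and hemisphere handling.

Volumes are reoriented to the canonical RAS orientation on read, so array
axis 0 is always the left--right axis (low indices = anatomical left).
Real-scan rigid registration and tissue segmentation are out of scope:
label maps are expected as inputs (the phantom module produces them
natively aligned); real-data users must pre-register and segment upstream.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grids import BinaryMask, LabelMap, VoxelGrid


class DegenerateInputError(ValueError):
    """Raised when an operation receives an input it cannot meaningfully process."""


# ---------------------------------------------------------------------------
# NIfTI round trip

def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_volume(path: str | Path) -> VoxelGrid:
    data, spacing = _load_canonical(path)
    return VoxelGrid(data.astype(np.float64), spacing)


def write_volume(v: VoxelGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(v.data.astype(np.float64), _affine(v.spacing_mm))
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, str(path))


def read_labels(path: str | Path, legend_path: str | Path) -> LabelMap:
    data, spacing = _load_canonical(path)
    raw = json.loads(Path(legend_path).read_text())
    legend = {int(k): (v["structure"], v["hemisphere"]) for k, v in raw.items()}
    return LabelMap(np.rint(data).astype(np.int16), legend, spacing)


def write_labels(lm: LabelMap, path: str | Path, legend_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(lm.data.astype(np.int16), _affine(lm.spacing_mm))
    img.header.set_zooms(lm.spacing_mm)
    nib.save(img, str(path))
    if legend_path is not None:
        legend_json = {
            str(lab): {"structure": s, "hemisphere": h} for lab, (s, h) in lm.legend.items()
        }
        Path(legend_path).write_text(json.dumps(legend_json, indent=2) + "\n")


# ---------------------------------------------------------------------------
# intensity preprocessing

def normalize_intensity(v: VoxelGrid, brain_mask: BinaryMask) -> VoxelGrid:
    """Min-max rescale over the mask to [0, 1]; background forced to 0.

    Min-max (rather than z-scoring) keeps gray-level quantization bins
    comparable across subjects.
    """
    if not brain_mask:
        raise DegenerateInputError("brain mask is empty")
    vals = v.data[brain_mask.data]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        raise DegenerateInputError("image is constant within the brain mask")
    out = np.zeros_like(v.data)
    out[brain_mask.data] = (vals - lo) / (hi - lo)
    return VoxelGrid(out, v.spacing_mm, v.orientation)


def denoise(v: VoxelGrid, method: str = "none", param: float | int = 1) -> VoxelGrid:
    if method == "none":
        return v
    if method == "gaussian":
        if param <= 0:
            raise ValueError("gaussian width must be > 0")
        return VoxelGrid(ndimage.gaussian_filter(v.data, sigma=float(param)), v.spacing_mm, v.orientation)
    if method == "median":
        radius = int(param)
        if radius < 1:
            raise ValueError("median radius must be >= 1")
        return VoxelGrid(ndimage.median_filter(v.data, size=2 * radius + 1), v.spacing_mm, v.orientation)
    raise ValueError(f"unknown denoising method {method!r}")


# ---------------------------------------------------------------------------
# hemispheres and structures

def split_hemispheres(
    labels: LabelMap, midplane_fallback: bool = False
) -> tuple[BinaryMask, BinaryMask]:
    """Left/right hemisphere masks.

    Primary path: union of the legend-tagged labels per hemisphere.
    Fallback (``midplane_fallback=True``): split at the midpoint of the
    brain bounding box along axis 0, half-open ([lo, mid) = left,
    [mid, hi) = right).
    """
    if midplane_fallback:
        brain = labels.data > 0
        if not brain.any():
            raise DegenerateInputError("label map is empty")
        xs = np.nonzero(brain.any(axis=(1, 2)))[0]
        lo, hi = int(xs[0]), int(xs[-1]) + 1
        mid = (lo + hi) // 2
        left = np.zeros_like(brain)
        right = np.zeros_like(brain)
        left[lo:mid] = brain[lo:mid]
        right[mid:hi] = brain[mid:hi]
    else:
        left = labels.hemisphere_mask("left").data
        right = labels.hemisphere_mask("right").data
    if not left.any():
        raise DegenerateInputError("left hemisphere mask is empty")
    if not right.any():
        raise DegenerateInputError("right hemisphere mask is empty")
    return BinaryMask(left, labels.spacing_mm), BinaryMask(right, labels.spacing_mm)


def structure_mask(labels: LabelMap, structure: str, hemisphere: str) -> BinaryMask:
    m = labels.mask(structure, hemisphere)
    return m


def structure_volume(m: BinaryMask) -> float:
    """Mask volume in mm^3 (voxel count x voxel volume)."""
    return float(m.count) * float(np.prod(m.spacing_mm))
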