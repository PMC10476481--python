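"""Core in-memory containers for volumetric data.

Volumes are plain 3D numpy arrays carried together with their voxel
spacing; on disk they are NIfTI-1 images.  After canonical reorientation
(see :mod:`hemisym.io_preprocess`) array axis 0 is the left--right axis,
with low indices on the anatomical left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

#: Anatomical structures carried by a label map.
STRUCTURES = ("gm", "wm", "csf", "hc")
#: Hemisphere tags.
HEMISPHERES = ("left", "right")


class FeatureInfo(NamedTuple):
    """Provenance of a named feature column."""

    structure: str
    hemisphere: str  # "left", "right" or "bilateral" for asymmetry features
    family: str      # "volume", "firstorder", "glcm" or "rlm"
    feature: str


def _as_spacing(spacing_mm) -> tuple[float, float, float]:
    s = tuple(float(x) for x in spacing_mm)
    if len(s) != 3 or any(x <= 0 for x in s):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing_mm!r}")
    return s


@dataclass
class VoxelGrid:
    """A 3D scalar intensity image with voxel spacing in millimetres."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = _as_spacing(self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class BinaryMask:
    """A boolean region of interest aligned with a :class:`VoxelGrid`."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"BinaryMask requires a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = _as_spacing(self.spacing_mm)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def __bool__(self) -> bool:  # nonempty test
        return bool(self.data.any())


@dataclass
class LabelMap:
    """Integer label volume plus a legend mapping label -> (structure, hemisphere)."""

    data: np.ndarray
    legend: dict[int, tuple[str, str]] = field(default_factory=dict)
    spacing_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap requires a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be an integer array")
        if (self.data < 0).any():
            raise ValueError("LabelMap data must be nonnegative")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.legend = {int(k): (str(v[0]), str(v[1])) for k, v in self.legend.items()}
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} present in data but absent from legend")

    def label_for(self, structure: str, hemisphere: str) -> int:
        for lab, (s, h) in self.legend.items():
            if s == structure and h == hemisphere:
                return lab
        raise KeyError(f"no label for structure={structure!r}, hemisphere={hemisphere!r}")

    def mask(self, structure: str, hemisphere: str) -> BinaryMask:
        lab = self.label_for(structure, hemisphere)
        return BinaryMask(self.data == lab, self.spacing_mm)

    def hemisphere_mask(self, hemisphere: str) -> BinaryMask:
        labs = [lab for lab, (_, h) in self.legend.items() if h == hemisphere]
        if not labs:
            raise KeyError(f"legend has no labels for hemisphere {hemisphere!r}")
        return BinaryMask(np.isin(self.data, labs), self.spacing_mm)

    def brain_mask(self) -> BinaryMask:
        return BinaryMask(self.data > 0, self.spacing_mm)
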