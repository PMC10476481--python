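"""Synthetic brain-phantom cohorts with class-graded hemispheric asymmetry.

The generator emulates a three-group early-dementia imaging study (normal
controls, mild cognitive impairment, Alzheimer's disease; 50 subjects per
group at a 1.5 mm isotropic voxel size).  Each subject carries four
bilateral structures — gray matter (gm), white matter (wm), cerebrospinal
fluid (csf) and hippocampus (hc) — rasterized as mirror-symmetric
ellipsoids, filled with stationary correlated random-field texture, and
corrupted with Rician magnitude noise.

Disease is injected through :class:`ClassEffect`: a per-structure,
per-hemisphere volume multiplier (acting on ellipsoid radii as the cube
root, so the parameter reads directly as a volume ratio) and a texture
modifier (correlation-length multiplier and intensity shift).  The shipped
defaults grade the effects NC -> MCI -> AD monotonically — atrophy of the
left hippocampus and texture smoothing of the left gray matter — encoding
the premise that hemispheric asymmetry increases gradually with disease
progression.

With identity effects the phantom is exactly mirror-symmetric across the
midsagittal plane (before noise), voxel for voxel: the right-hemisphere
texture field is the reflected left field.  This gives downstream
asymmetry features an exact null (difference 0, ratio 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import HEMISPHERES, STRUCTURES, LabelMap, VoxelGrid

logger = logging.getLogger(__name__)

CLASSES = ("NC", "MCI", "AD")

#: Painting order; later structures overwrite earlier ones, so precedence
#: for overlapping voxels is hc > gm > wm > csf.
_PAINT_ORDER = ("csf", "wm", "gm", "hc")

#: Fixed integer labels (stable across cohorts).
LABELS: dict[tuple[str, str], int] = {
    ("gm", "left"): 1, ("gm", "right"): 2,
    ("wm", "left"): 3, ("wm", "right"): 4,
    ("csf", "left"): 5, ("csf", "right"): 6,
    ("hc", "left"): 7, ("hc", "right"): 8,
}


class DegenerateGeometryError(ValueError):
    """Raised when a rasterized structure mask comes out empty or clipped."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid; center given as an offset from the grid
    center in voxels.  ``center_offset[0]`` is the lateral (left-right)
    offset: negative = left hemisphere, positive = right."""

    center_offset: tuple[float, float, float]
    radii: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError(f"ellipsoid radii must be positive, got {self.radii}")

    def mirrored(self) -> "Ellipsoid":
        dx, dy, dz = self.center_offset
        return Ellipsoid((-dx, dy, dz), self.radii)


@dataclass(frozen=True)
class TextureParams:
    base_intensity: float
    amplitude: float
    correlation_length_vox: float

    def __post_init__(self) -> None:
        if self.correlation_length_vox <= 0:
            raise ValueError("correlation_length_vox must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")


# Canonical geometry designed on a 64^3 grid; scaled proportionally for
# other grid sizes.  Offsets/radii are for the *left* hemisphere ellipsoid
# (lateral offset stored positive, negated when placed on the left).
_CANONICAL_GEOMETRY: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "gm": ((13.0, 10.0, 0.0), (9.0, 11.0, 12.0)),
    "wm": ((13.0, -10.0, 0.0), (9.0, 11.0, 12.0)),
    "csf": ((13.0, 0.0, 14.0), (8.0, 10.0, 6.0)),
    "hc": ((10.0, -2.0, -14.0), (5.0, 6.0, 5.0)),
}

_DEFAULT_TEXTURE: dict[str, TextureParams] = {
    "gm": TextureParams(0.60, 0.08, 1.0),
    "wm": TextureParams(0.90, 0.06, 1.2),
    "csf": TextureParams(0.20, 0.05, 0.8),
    "hc": TextureParams(0.55, 0.08, 1.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, texture and noise parameters of the phantom.

    ``geometry`` maps (structure, hemisphere) to an :class:`Ellipsoid`;
    left/right entries must be mirror images of each other (class effects
    break the symmetry later, the base geometry never does).
    ``jitter_sigma`` is the log-scale standard deviation of a per-subject,
    per-structure volume factor applied identically to both hemispheres —
    it models normal inter-subject anatomical variability without
    introducing asymmetry.  ``noise_sigma`` is the Rician channel sigma,
    by default 2% of the gray-matter base intensity.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.5
    geometry: Mapping[tuple[str, str], Ellipsoid] = field(default_factory=dict)
    texture: Mapping[str, TextureParams] = field(default_factory=lambda: dict(_DEFAULT_TEXTURE))
    noise_sigma: float = 0.012
    jitter_sigma: float = 0.05

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not self.geometry:
            object.__setattr__(self, "geometry", default_geometry(self.grid_shape))
        self._validate_geometry()
        for s in STRUCTURES:
            if s not in self.texture:
                raise ValueError(f"texture parameters missing for structure {s!r}")

    def _validate_geometry(self) -> None:
        for s in STRUCTURES:
            for h in HEMISPHERES:
                if (s, h) not in self.geometry:
                    raise ValueError(f"geometry missing for ({s}, {h})")
            left, right = self.geometry[(s, "left")], self.geometry[(s, "right")]
            if left.mirrored() != right:
                raise ValueError(
                    f"geometry for {s} is not mirror-symmetric: {left} vs {right}"
                )


def default_geometry(grid_shape: Sequence[int]) -> dict[tuple[str, str], Ellipsoid]:
    """Canonical mirror-symmetric geometry, scaled from the 64-voxel design."""
    out: dict[tuple[str, str], Ellipsoid] = {}
    scale = np.asarray(grid_shape, dtype=float) / 64.0
    for s, (off, radii) in _CANONICAL_GEOMETRY.items():
        off_s = tuple(np.asarray(off) * scale)
        radii_s = tuple(np.asarray(radii) * scale)
        right = Ellipsoid(off_s, radii_s)  # lateral offset positive -> right
        out[(s, "right")] = right
        out[(s, "left")] = right.mirrored()
    return out


@dataclass(frozen=True)
class ClassEffect:
    """Disease effect for one class: per-(structure, hemisphere) volume
    multipliers and texture modifiers (all default to identity)."""

    class_label: str
    volume_scale: Mapping[tuple[str, str], float] = field(default_factory=dict)
    correlation_length_multiplier: Mapping[tuple[str, str], float] = field(default_factory=dict)
    intensity_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, v in self.volume_scale.items():
            if v <= 0:
                raise ValueError(f"volume_scale for {key} must be positive, got {v}")
        for key, v in self.correlation_length_multiplier.items():
            if v <= 0:
                raise ValueError(f"correlation_length_multiplier for {key} must be positive")

    def volume_scale_for(self, structure: str, hemisphere: str) -> float:
        return float(self.volume_scale.get((structure, hemisphere), 1.0))

    def clen_multiplier_for(self, structure: str, hemisphere: str) -> float:
        return float(self.correlation_length_multiplier.get((structure, hemisphere), 1.0))

    def shift_for(self, structure: str, hemisphere: str) -> float:
        return float(self.intensity_shift.get((structure, hemisphere), 0.0))

    def is_identity(self) -> bool:
        return (
            all(v == 1.0 for v in self.volume_scale.values())
            and all(v == 1.0 for v in self.correlation_length_multiplier.values())
            and all(v == 0.0 for v in self.intensity_shift.values())
        )


def default_effects() -> dict[str, ClassEffect]:
    """Shipped study conditions: AD shrinks the left hippocampus to 70% of
    its volume and smooths left gray-matter texture (correlation length
    x1.5); MCI sits halfway; NC is identity.  Componentwise monotone
    NC -> MCI -> AD by construction."""
    return {
        "NC": ClassEffect("NC"),
        "MCI": ClassEffect(
            "MCI",
            volume_scale={("hc", "left"): 0.85},
            correlation_length_multiplier={("gm", "left"): 1.25},
        ),
        "AD": ClassEffect(
            "AD",
            volume_scale={("hc", "left"): 0.7},
            correlation_length_multiplier={("gm", "left"): 1.5},
        ),
    }


@dataclass
class SubjectRecord:
    subject_id: str
    class_label: str
    intensity: VoxelGrid
    labels: LabelMap


# ---------------------------------------------------------------------------
# label-map rasterization

def _rasterize_ellipsoid(grid_shape, center, radii) -> np.ndarray:
    nx, ny, nz = grid_shape
    cx, cy, cz = center
    rx, ry, rz = radii
    x = (np.arange(nx, dtype=np.float64) - cx) / rx
    y = (np.arange(ny, dtype=np.float64) - cy) / ry
    z = (np.arange(nz, dtype=np.float64) - cz) / rz
    return (
        x[:, None, None] ** 2 + y[None, :, None] ** 2 + z[None, None, :] ** 2
    ) <= 1.0


def build_label_map(config: PhantomConfig, effect: ClassEffect, seed: int) -> LabelMap:
    """Rasterize the eight structure masks for one subject.

    The per-subject anatomical jitter (one volume factor per structure,
    shared by both hemispheres) is drawn from ``seed``; the class effect's
    ``volume_scale`` then multiplies the affected hemisphere's radii by its
    cube root.  Overlaps are resolved by the fixed paint order
    csf < wm < gm < hc (hippocampus wins).
    """
    rng = np.random.default_rng(seed)
    jitter = {
        s: float(np.exp(rng.normal(0.0, config.jitter_sigma))) for s in STRUCTURES
    }
    shape = config.grid_shape
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    data = np.zeros(shape, dtype=np.int16)
    for s in _PAINT_ORDER:
        radius_jit = jitter[s] ** (1.0 / 3.0)
        for h in HEMISPHERES:
            ell = config.geometry[(s, h)]
            scale = effect.volume_scale_for(s, h) ** (1.0 / 3.0)
            radii = tuple(r * radius_jit * scale for r in ell.radii)
            c = tuple(center[i] + ell.center_offset[i] for i in range(3))
            for i in range(3):
                if c[i] - radii[i] < -0.5 or c[i] + radii[i] > shape[i] - 0.5:
                    raise DegenerateGeometryError(
                        f"grid {shape} too small for structure {s}/{h} "
                        f"(center {c}, radii {radii})"
                    )
            mask = _rasterize_ellipsoid(shape, c, radii)
            data[mask] = LABELS[(s, h)]
    legend = {lab: key for key, lab in LABELS.items()}
    for (s, h), lab in LABELS.items():
        if not (data == lab).any():
            raise DegenerateGeometryError(f"structure mask ({s}, {h}) is empty")
    sp = (config.voxel_size_mm,) * 3
    return LabelMap(data, legend, sp)


# ---------------------------------------------------------------------------
# texture synthesis

def synthesize_texture(
    labels: LabelMap, config: PhantomConfig, effect: ClassEffect, seed: int
) -> VoxelGrid:
    """Fill each structure with a stationary correlated random field.

    One white-noise volume is drawn per structure; each hemisphere's field
    is that noise smoothed with a Gaussian kernel of width
    ``correlation_length_vox x correlation_length_multiplier``, normalized
    to unit variance, scaled by ``amplitude`` and added to
    ``base_intensity + intensity_shift``.  The right hemisphere samples the
    field at mirrored coordinates, so with identity effects the image is
    exactly mirror-symmetric.  Background stays 0.
    """
    shape = labels.data.shape
    rng = np.random.default_rng(seed)
    out = np.zeros(shape, dtype=np.float64)
    for s in STRUCTURES:
        noise = rng.standard_normal(shape)
        params = config.texture[s]
        smoothed_cache: dict[float, np.ndarray] = {}
        for h in HEMISPHERES:
            sigma = params.correlation_length_vox * effect.clen_multiplier_for(s, h)
            if sigma not in smoothed_cache:
                f = gaussian_filter(noise, sigma=sigma, mode="reflect")
                sd = f.std()
                smoothed_cache[sigma] = f / sd if sd > 0 else f
            field = (
                params.base_intensity
                + effect.shift_for(s, h)
                + params.amplitude * smoothed_cache[sigma]
            )
            if h == "right":
                # sample at mirrored lateral coordinate -> exact symmetry
                # of left/right in-mask values under identity effects
                field = field[::-1, :, :]
            m = labels.data == LABELS[(s, h)]
            out[m] = field[m]
    return VoxelGrid(out, (config.voxel_size_mm,) * 3)


def add_rician_noise(v: VoxelGrid, sigma: float, seed: int) -> VoxelGrid:
    """Rician magnitude noise: out = sqrt((I + n1)^2 + n2^2) with n1, n2
    i.i.d. zero-mean Gaussians of standard deviation ``sigma``.  For
    ``sigma == 0`` this returns |I| (identity on nonnegative images)."""
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return VoxelGrid(np.abs(v.data), v.spacing_mm, v.orientation)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, v.data.shape)
    n2 = rng.normal(0.0, sigma, v.data.shape)
    out = np.sqrt((v.data + n1) ** 2 + n2 ** 2)
    return VoxelGrid(out, v.spacing_mm, v.orientation)


# ---------------------------------------------------------------------------
# cohorts

def _subject_seeds(seed: int, class_idx: int, index: int) -> tuple[int, int, int]:
    ss = np.random.SeedSequence([int(seed), class_idx, index])
    a, b, c = ss.generate_state(3)
    return int(a), int(b), int(c)


def generate_subject(
    config: PhantomConfig,
    effect: ClassEffect,
    subject_id: str,
    seed: int,
    class_idx: int = 0,
    index: int = 0,
) -> SubjectRecord:
    s_lab, s_tex, s_noise = _subject_seeds(seed, class_idx, index)
    labels = build_label_map(config, effect, s_lab)
    intensity = synthesize_texture(labels, config, effect, s_tex)
    intensity = add_rician_noise(intensity, config.noise_sigma, s_noise)
    return SubjectRecord(subject_id, effect.class_label, intensity, labels)


def generate_cohort(
    n_per_class: Mapping[str, int],
    config: PhantomConfig | None = None,
    effects: Mapping[str, ClassEffect] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a cohort; optionally write NIfTI volumes + manifest CSV.

    Per-subject seeds derive deterministically from (seed, class index,
    subject index), so a cohort is a pure function of its arguments.
    """
    config = config or PhantomConfig()
    effects = effects or default_effects()
    for cls, n in n_per_class.items():
        if n < 1:
            raise ValueError(f"n_per_class[{cls!r}] must be >= 1, got {n}")
        if cls not in effects:
            raise ValueError(f"no ClassEffect supplied for class {cls!r}")

    records: list[SubjectRecord] = []
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        legend_json = {
            str(lab): {"structure": s, "hemisphere": h}
            for (s, h), lab in sorted(LABELS.items(), key=lambda kv: kv[1])
        }
        (out_path / "legend.json").write_text(json.dumps(legend_json, indent=2) + "\n")

    class_order = [c for c in CLASSES if c in n_per_class] + [
        c for c in n_per_class if c not in CLASSES
    ]
    for cls in class_order:
        class_idx = class_order.index(cls)
        for i in range(n_per_class[cls]):
            sid = f"{cls}_{i:03d}"
            rec = generate_subject(config, effects[cls], sid, seed, class_idx, i)
            records.append(rec)
            row = {"subject_id": sid, "class": cls, "intensity_path": "", "label_path": ""}
            if out_path is not None:
                from .io_preprocess import write_labels, write_volume

                ip = out_path / f"{sid}_intensity.nii.gz"
                lp = out_path / f"{sid}_labels.nii.gz"
                write_volume(rec.intensity, ip)
                write_labels(rec.labels, lp)
                row["intensity_path"] = ip.name
                row["label_path"] = lp.name
            rows.append(row)
    manifest = pd.DataFrame(rows, columns=["subject_id", "class", "intensity_path", "label_path"])
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        logger.info("wrote cohort of %d subjects to %s (seed=%d)", len(records), out_path, seed)
    return records, manifest
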