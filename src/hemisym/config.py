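"""Schema-validated run configuration (YAML) for the end-to-end pipeline.

Unknown keys are rejected up front so typos fail before any computation.
The defaults are the shipped study conditions: 50 subjects per class on a
64^3 grid at 1.5 mm, graded left-lateralized effects, all five feature-set
variants, both class pairs, nested 5-fold x 5-repeat evaluation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .classify import KernelSpec
from .grids import HEMISPHERES, STRUCTURES
from .phantom import ClassEffect, PhantomConfig, default_effects
from .selection import SelectionConfig
from .texture import FeatureSpec

PAIRS = {"NC-AD": ("NC", "AD"), "NC-MCI": ("NC", "MCI")}


class _Forbid(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectSection(_Forbid):
    """Per-class effect override; keys are ``{structure}_{hemisphere}``."""

    volume_scale: dict[str, float] = Field(default_factory=dict)
    correlation_length_multiplier: dict[str, float] = Field(default_factory=dict)
    intensity_shift: dict[str, float] = Field(default_factory=dict)


class CohortSection(_Forbid):
    n_per_class: dict[str, int] = Field(default_factory=lambda: {"NC": 50, "MCI": 50, "AD": 50})
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.5
    noise_sigma: float = 0.012
    jitter_sigma: float = 0.05
    effects: dict[str, EffectSection] | Literal["default"] = "default"


class FeatureSection(_Forbid):
    Z: int = 32
    d: int = 1
    bins: int = 32


class SelectionSection(_Forbid):
    max_k: int = 15
    delta_min: float = 0.002
    inner_folds: int = 5
    n_candidates: int = 40


class ClassifierSection(_Forbid):
    kernel: Literal["polynomial", "rbf", "sigmoid"] = "rbf"
    C_grid: list[float] = Field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0])
    u_factors: list[float] = Field(default_factory=lambda: [0.25, 0.5, 1.0, 2.0, 4.0])
    inner_folds: int = 5
    outer_folds: int = 5
    repeats: int = 5


class RunConfig(_Forbid):
    seed: int = 0
    out_dir: str = "hemisym_out"
    cohort: CohortSection = Field(default_factory=CohortSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    variants: list[Literal["left", "right", "whole", "difference", "ratio"]] = Field(
        default_factory=lambda: ["left", "right", "whole", "difference", "ratio"]
    )
    pairs: list[Literal["NC-AD", "NC-MCI"]] = Field(default_factory=lambda: ["NC-AD", "NC-MCI"])
    selection: SelectionSection = Field(default_factory=SelectionSection)
    classifier: ClassifierSection = Field(default_factory=ClassifierSection)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def _parse_sh_key(key: str) -> tuple[str, str]:
    s, _, h = key.rpartition("_")
    if s not in STRUCTURES or h not in HEMISPHERES:
        raise ValueError(f"effect key {key!r} is not '{{structure}}_{{hemisphere}}'")
    return s, h


def build_effects(cfg: CohortSection) -> Mapping[str, ClassEffect]:
    if cfg.effects == "default":
        return default_effects()
    out = {}
    for cls, sec in cfg.effects.items():
        out[cls] = ClassEffect(
            cls,
            volume_scale={_parse_sh_key(k): v for k, v in sec.volume_scale.items()},
            correlation_length_multiplier={
                _parse_sh_key(k): v for k, v in sec.correlation_length_multiplier.items()
            },
            intensity_shift={_parse_sh_key(k): v for k, v in sec.intensity_shift.items()},
        )
    for cls in cfg.n_per_class:
        out.setdefault(cls, ClassEffect(cls))
    return out


def build_phantom_config(cfg: CohortSection) -> PhantomConfig:
    return PhantomConfig(
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        noise_sigma=cfg.noise_sigma,
        jitter_sigma=cfg.jitter_sigma,
    )


def build_feature_spec(cfg: FeatureSection) -> FeatureSpec:
    return FeatureSpec(Z=cfg.Z, d=cfg.d, bins=cfg.bins)


def build_selection_config(cfg: SelectionSection, seed: int, kernel_kind: str = "rbf") -> SelectionConfig:
    return SelectionConfig(
        max_k=cfg.max_k,
        delta_min=cfg.delta_min,
        inner_folds=cfg.inner_folds,
        n_candidates=cfg.n_candidates,
        seed=seed,
        kernel=KernelSpec(kernel_kind, u=None) if kernel_kind == "rbf" else KernelSpec(kernel_kind, u=2.0),
    )
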