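"""Shared fixtures.

The heavy fixtures (feature matrices of injected-effect cohorts) are
session-scoped and generated once: 30 subjects per class on a 48^3 grid,
the reduced study size used throughout the stochastic acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from hemisym.asymmetry import build_variant
from hemisym.phantom import (
    PhantomConfig,
    default_effects,
    generate_cohort,
    generate_subject,
)
from hemisym.texture import FeatureSpec, extract_cohort

SMALL_GRID = (32, 32, 32)
COHORT_GRID = (48, 48, 48)
N_PER_CLASS = 30
COHORT_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def small_config():
    return PhantomConfig(grid_shape=SMALL_GRID)


@pytest.fixture(scope="session")
def effects():
    return default_effects()


@pytest.fixture(scope="session")
def nc_subject(small_config, effects):
    """One noiseless, identity-effect (hence mirror-symmetric) subject."""
    cfg = PhantomConfig(grid_shape=SMALL_GRID, noise_sigma=0.0)
    return generate_subject(cfg, effects["NC"], "NC_000", seed=11)


@pytest.fixture(scope="session")
def ad_subject(small_config, effects):
    return generate_subject(small_config, effects["AD"], "AD_000", seed=12)


def make_cohort_features(seed: int, n_per_class: int = N_PER_CLASS, grid=COHORT_GRID):
    """Feature vectors for one injected-effect cohort."""
    cfg = PhantomConfig(grid_shape=grid)
    records, _ = generate_cohort(
        {"NC": n_per_class, "MCI": n_per_class, "AD": n_per_class},
        cfg,
        default_effects(),
        seed=seed,
    )
    return extract_cohort(records, FeatureSpec())


@pytest.fixture(scope="session")
def cohort_vectors_by_seed():
    """Ten seeded cohorts (criterion-level stochastic checks share these)."""
    return {s: make_cohort_features(s) for s in COHORT_SEEDS}


@pytest.fixture(scope="session")
def cohort_vectors(cohort_vectors_by_seed):
    return cohort_vectors_by_seed[COHORT_SEEDS[0]]


@pytest.fixture(scope="session")
def whole_matrix(cohort_vectors):
    return build_variant(cohort_vectors, "whole")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
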