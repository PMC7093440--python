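"""Shared fixtures: small grids and session-scoped phantom cohorts.

Heavy artefacts (the noiseless reference, the registered cohort) are
session-scoped so the property tests and the acceptance checks share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from atlasquant.core import ImageGrid, ScalarImage3D
from atlasquant.phantom import (
    default_phantom_spec,
    make_reference,
    make_subject,
    random_deform_params,
)

#: grid used for registration-based tests: large enough for distinct
#: organs, small enough for a minute-scale suite
COHORT_SHAPE = (40, 32, 96)


@pytest.fixture
def small_grid() -> ImageGrid:
    return ImageGrid((8, 8, 8), (2.0, 2.0, 2.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def noiseless_spec():
    return default_phantom_spec(COHORT_SHAPE, mr_sigma=0.0, pet_noise_scale=0.0)


@pytest.fixture(scope="session")
def noiseless_reference(noiseless_spec):
    return make_reference(noiseless_spec)


@pytest.fixture(scope="session")
def default_spec():
    return default_phantom_spec(COHORT_SHAPE, seed=1)


@pytest.fixture(scope="session")
def default_reference(default_spec):
    return make_reference(default_spec)


@pytest.fixture(scope="session")
def registered_cohort(default_reference):
    """Five random subjects registered back to the reference.

    Returns (reference, subjects, fields) and is shared between the
    registration-quality tests and the acceptance checks.
    """
    from atlasquant.registration import register

    rng = np.random.default_rng(2024)
    subjects, fields = [], []
    for _ in range(5):
        subj = make_subject(
            default_reference, random_deform_params(rng), seed=int(rng.integers(2**31))
        )
        fld = register(
            subj.water, subj.fat, default_reference.water, default_reference.fat
        )
        subjects.append(subj)
        fields.append(fld)
    return default_reference, subjects, fields
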