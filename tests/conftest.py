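import numpy as np
import pytest

from prostate_da import (
    CohortSpec,
    SideEffect,
    default_catalog,
    default_registry,
    estimate_matrices,
    generate_truth_matrices,
    sample_cohort,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def truth_matrices(catalog, registry):
    """Deterministic ground-truth transition matrices for every treatment."""
    return generate_truth_matrices(catalog.treatments, registry)


@pytest.fixture(scope="session")
def default_matrices(catalog, registry, truth_matrices):
    """Matrices estimated from one default synthetic cohort (150/arm)."""
    spec = CohortSpec(truth_matrices=truth_matrices, n_per_treatment=150, seed=20260924)
    return estimate_matrices(sample_cohort(spec, registry), registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
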