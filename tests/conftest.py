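import numpy as np
import pytest

from hypertab.table import catalog_models

#: every shipped parameterization, as (label, model) pairs
CATALOG = list(catalog_models())


@pytest.fixture(scope="session")
def catalog_entries():
    return CATALOG


def random_deformation(rng, amplitude=0.08):
    """A random deformation gradient near the reference with det > 0."""
    while True:
        F = np.eye(3) + amplitude * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.2:
            return F


@pytest.fixture
def rng():
    return np.random.default_rng(20240918)
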