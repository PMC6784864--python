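import numpy as np
import pytest

from housemap.classify import load_jmp_lookup, load_material_lookup
from housemap.synth import SyntheticSpec, simulate_survey

COVARIATES = ["aridity", "urbanicity", "accessibility", "friction",
              "nightlights", "irrigation"]


@pytest.fixture(scope="session")
def material_lookup():
    return load_material_lookup()


@pytest.fixture(scope="session")
def jmp_lookup():
    return load_jmp_lookup()


@pytest.fixture(scope="session")
def small_spec():
    """Small synthetic world used across tests (cheap to regenerate)."""
    return SyntheticSpec(nx=20, ny=20, n_clusters=60, households_per_cluster=20,
                         years=(2010,), seed=7)


@pytest.fixture(scope="session")
def small_world(small_spec):
    return simulate_survey(small_spec)
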