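import numpy as np
import pytest
from hypothesis import settings

from cartatlas.fixtures import FixtureSpec, gen_atlas_library, gen_subject_dimensions

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def atlas_library(fixture_spec):
    return gen_atlas_library(fixture_spec)


@pytest.fixture(scope="session")
def subjects(fixture_spec):
    return gen_subject_dimensions(fixture_spec, 9)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
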