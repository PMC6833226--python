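import numpy as np
import pytest
from hypothesis import settings

from spindlemag import FieldSpec, PhysicalConstants

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def consts() -> PhysicalConstants:
    return PhysicalConstants()


@pytest.fixture
def field9() -> FieldSpec:
    return FieldSpec(9.0)


@pytest.fixture
def field0() -> FieldSpec:
    return FieldSpec(0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
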