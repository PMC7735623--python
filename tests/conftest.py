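import math

import pytest

from srdt import ChoiceSet, Lottery, SRDTParams, UtilitySpec
from srdt.experiments import (
    birnbaum_pair,
    evident_dominance_pairs,
    strong_risk_pair,
    time_pressure_pair,
)


@pytest.fixture
def linear_params():
    return SRDTParams(utility=UtilitySpec(family="linear"), D=10.0)


@pytest.fixture
def cara1_params():
    return SRDTParams(utility=UtilitySpec(family="cara", r=1.0), D=10.0)


@pytest.fixture
def birnbaum():
    return birnbaum_pair()


@pytest.fixture
def pressure_pair():
    return time_pressure_pair()


@pytest.fixture
def evident_pairs():
    return evident_dominance_pairs()


@pytest.fixture
def risk_pair():
    return strong_risk_pair()


@pytest.fixture
def simple_pair():
    """Two-branch gain lottery vs a zero-outcome lottery."""
    return ChoiceSet([
        Lottery("A", [(10.0, 0.5), (0.0, 0.5)]),
        Lottery("B", [(0.0, 1.0)]),
    ])
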