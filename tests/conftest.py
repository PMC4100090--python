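"""Shared fixtures: the published sense→antisense map and worked-example data."""

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# The published sense→antisense amino-acid map, transcribed as a fixture so
# the computationally derived maps can be checked cell-for-cell.
TABLE_3TO5 = {
    "F": {"K"}, "L": {"D", "E", "N"}, "I": {"Y"}, "M": {"Y"},
    "V": {"H", "Q"}, "S": {"S", "R"}, "P": {"G"}, "T": {"W", "C"},
    "A": {"R"}, "Y": {"M", "I"}, "H": {"V"}, "Q": {"V"}, "N": {"L"},
    "K": {"F"}, "D": {"L"}, "E": {"L"}, "C": {"T"}, "W": {"T"},
    "R": {"A", "S"}, "G": {"P"},
}

TABLE_5TO3 = {
    "F": {"K", "E"}, "L": {"E", "Q", "K"}, "I": {"N", "D", "Y"},
    "M": {"H"}, "V": {"H", "D", "N", "Y"}, "S": {"G", "R", "T", "A"},
    "P": {"G", "W", "R"}, "T": {"G", "S", "C", "R"},
    "A": {"R", "G", "S", "C"}, "Y": {"I", "V"}, "H": {"V", "M"},
    "Q": {"L"}, "N": {"I", "V"}, "K": {"F", "L"}, "D": {"I", "V"},
    "E": {"L", "F"}, "C": {"T", "A"}, "W": {"P"},
    "R": {"A", "S", "P", "T"}, "G": {"P", "S", "T", "A"},
}

EPITOPE = "LKLYTGEACRTGDR"
ANTISENSE = "DFDIWPLRTAWPLS"


@pytest.fixture(scope="session")
def table_3to5():
    return TABLE_3TO5


@pytest.fixture(scope="session")
def table_5to3():
    return TABLE_5TO3
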