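import numpy as np
import pytest

from suzukiloop.design_space import (
    ContinuousVariable,
    DesignSpace,
    DiscreteCandidate,
)


@pytest.fixture
def case_space() -> DesignSpace:
    """The standard T / residence time / loading domain with 8 candidates."""
    return DesignSpace(
        variables=(
            ContinuousVariable("T_C", 30.0, 110.0, "degC", 1.0),
            ContinuousVariable("t_min", 1.0, 10.0, "min", 0.1),
            ContinuousVariable("loading_molpct", 0.5, 2.5, "mol%", 0.1),
        ),
        roster=tuple(
            DiscreteCandidate.from_id(c)
            for c in ("P1-L1", "P1-L2", "P1-L3", "P1-L4",
                      "P1-L5", "P1-L6", "P1-L7", "P2-L1")
        ),
    )


@pytest.fixture
def small_space() -> DesignSpace:
    """Two continuous variables, two candidates - cheap fits and campaigns."""
    return DesignSpace(
        variables=(
            ContinuousVariable("T_C", 30.0, 110.0, "degC", 1.0),
            ContinuousVariable("loading_molpct", 0.5, 2.5, "mol%", 0.1),
        ),
        roster=(DiscreteCandidate.from_id("P1-L1"), DiscreteCandidate.from_id("P1-L5")),
        fixed={"t_min": 10.0},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
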