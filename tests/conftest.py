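import numpy as np
import pytest

from spathealth.lifetable import AgeSchedule


@pytest.fixture(scope="session")
def census_schedule() -> AgeSchedule:
    """The published abridged-life-table inputs for one Chinese region:
    exposures and deaths for ages 0, 1–4, 5–9, 10–14 and the 80–84 / 85+
    tail (the intervening rows are not printed)."""
    return AgeSchedule(
        start_ages=[0, 1, 5, 10, 15],
        exposures=[50_138, 198_325, 274_213, 293_296, 293_296],
        deaths=[1_930, 1_024, 423, 328, 328],
    )


@pytest.fixture(scope="session")
def census_tail() -> AgeSchedule:
    """Ages 80–84 and the open 85+ interval of the same published table."""
    return AgeSchedule(start_ages=[80, 85], exposures=[9_260, 4_383], deaths=[861, 455])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
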