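import pytest

from rfdosim.datasets import (published_calibration, published_ladder,
                              published_ladder_table)


@pytest.fixture(scope="session")
def cal():
    return published_calibration()


@pytest.fixture(scope="session")
def ladder():
    return published_ladder()


@pytest.fixture(scope="session")
def ladder_table():
    return published_ladder_table()
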