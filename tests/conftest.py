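import numpy as np
import pytest

from prcmatch import build_condition_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp3_high_ambiguity():
    return build_condition_schedule("exp3", "high_ambiguity", 42)


@pytest.fixture(scope="session")
def exp4_high_interference():
    return build_condition_schedule("exp4", "high_interference", 43)


@pytest.fixture(scope="session")
def exp4_low_interference():
    return build_condition_schedule("exp4", "low_interference", 44)
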