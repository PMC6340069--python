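import numpy as np
import pytest

from gxescore.synthetic import paperlike_config, simulate_cohort


@pytest.fixture(scope="session")
def paperlike_cohort():
    """One study-sized simulated cohort shared across tests (169/421)."""
    return simulate_cohort(paperlike_config(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def two_by_two_design(a: int, b: int, c: int, d: int):
    """Per-sample design/outcome for a 2x2 table: cases a exposed / b
    unexposed, controls c exposed / d unexposed."""
    x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    y = np.r_[np.ones(a + b), np.zeros(c + d)]
    return np.column_stack([np.ones_like(x), x]), y
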