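import numpy as np
import pytest

from triadpoo import FamilyUnit, SimConfig, simulate_case_families


@pytest.fixture(scope="session")
def toy_units():
    """A fixed, hand-written 10-family dataset (9 triads, 1 mother dyad)."""
    rows = [
        (1, 1, 1), (1, 0, 1), (0, 1, 1), (2, 1, 2), (1, 1, 0),
        (1, 1, 2), (2, 2, 2), (0, 0, 0), (1, 2, 1), (1, None, 1),
    ]
    return [FamilyUnit(f"T{i}", child=c, mother=m, father=f) for i, (m, f, c) in enumerate(rows)]


@pytest.fixture(scope="session")
def sim_units_5000():
    """5,000 case triads at a study-scale truth, shared across tests."""
    cfg = SimConfig(p=0.324, rr_cm=1.37, rr_cf=0.81, n_case_families=5000, seed=20240917)
    units, truth = simulate_case_families(cfg)
    return units, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
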