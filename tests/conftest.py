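"""Shared fixtures: worlds, joints, tradeoff curves and a small bank.

Bank-building is the expensive step, so curves and banks are session
scoped.  The bank used for fitting tests spans N = 1..14 with 40 points
per curve — large enough to contain the N* = 10 generating representation
used by the recovery simulations, small enough to keep the suite fast.
"""

import numpy as np
import pytest

from predrep.ib import build_bank, sweep_beta
from predrep.oddball import OddballWorld, joint_suffstat


@pytest.fixture(scope="session")
def world4():
    return OddballWorld(n=4)


@pytest.fixture(scope="session")
def world10():
    return OddballWorld(n=10)


@pytest.fixture(scope="session")
def joint4(world4):
    return joint_suffstat(world4)


@pytest.fixture(scope="session")
def joint10(world10):
    return joint_suffstat(world10)


@pytest.fixture(scope="session")
def curve4(joint4):
    """Full-resolution tradeoff curve for N = 4."""
    return sweep_beta(joint4, n_points=200)


@pytest.fixture(scope="session")
def curve10(joint10):
    """Full-resolution tradeoff curve for N = 10."""
    return sweep_beta(joint10, n_points=200)


@pytest.fixture(scope="session")
def bank14():
    """Compact representation bank for fitting and recovery tests."""
    return build_bank(n_max=14, n_beta=40)


@pytest.fixture(scope="session")
def bank10():
    """Even smaller bank for the permutation-calibration simulation."""
    return build_bank(n_max=10, n_beta=20)
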