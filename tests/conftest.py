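import random

import pytest

from chemlike.fixtures import builtin_fixture
from chemlike.network import StoichiometricMatrix


@pytest.fixture
def eq23():
    return builtin_fixture("eq23").network


@pytest.fixture
def eq23_S(eq23):
    return eq23.stoichiometric_matrix()


@pytest.fixture
def fig2():
    return builtin_fixture("fig2_substrate_cycle").network


@pytest.fixture
def eq27_S():
    return builtin_fixture("eq27").network.stoichiometric_matrix()


@pytest.fixture
def eq26_S():
    return builtin_fixture("eq26").network.stoichiometric_matrix()


def random_matrix(rng: random.Random, n_sp=4, n_rx=6, lo=-2, hi=2):
    """Small random integer matrix with no all-zero columns."""
    while True:
        entries = [
            [rng.randint(lo, hi) for _ in range(n_rx)] for _ in range(n_sp)
        ]
        if all(any(entries[i][j] for i in range(n_sp)) for j in range(n_rx)):
            return StoichiometricMatrix(
                entries,
                [f"x{i}" for i in range(n_sp)],
                [f"r{j}" for j in range(n_rx)],
            )
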