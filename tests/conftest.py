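import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from micov import (
    SimulationSpec,
    blosum62_background,
    group_background,
    simulate_msa,
    taylor_groups,
    toy_msa,
)


@pytest.fixture(scope="session")
def toy():
    return toy_msa()


@pytest.fixture(scope="session")
def q():
    return blosum62_background()


@pytest.fixture(scope="session")
def scheme():
    return taylor_groups()


@pytest.fixture(scope="session")
def qp(scheme, q):
    return group_background(scheme, q)


def random_alignment(seed, n_sequences=30, n_columns=6, **kwargs):
    """Small random alignment drawn from the background distribution."""
    return simulate_msa(
        SimulationSpec(
            n_sequences=n_sequences, n_columns=n_columns, seed=seed, **kwargs
        )
    )
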