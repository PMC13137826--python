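import numpy as np
import pytest

from trsaxs import debye, pool as pool_mod


@pytest.fixture(scope="session")
def q_grid():
    return debye.DEFAULT_Q_GRID


@pytest.fixture(scope="session")
def small_pool():
    """300-conformer pool: fast, still covers compact through extended."""
    return pool_mod.generate_pool(300, seed=42)


@pytest.fixture(scope="session")
def small_profiles(small_pool, q_grid):
    return debye.pool_profiles(small_pool, q_grid, method="exact")


@pytest.fixture(scope="session")
def big_pool():
    """Full desk-scale pool used by the parameter-recovery checks."""
    return pool_mod.generate_pool(10_000, seed=11)


@pytest.fixture(scope="session")
def big_profiles(big_pool, q_grid):
    return debye.pool_profiles(big_pool, q_grid, method="histogram")
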