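import numpy as np
import pytest

from hwematch.likelihood import BlockCounts, PopulationParams
from hwematch.simulate import SimulationScenario, build_population


@pytest.fixture(scope="session")
def pop_mid() -> PopulationParams:
    """Population with f_D = f_T = 0.3 and positively associated T, D."""
    return PopulationParams(k00=0.55, k10=0.15, k01=0.15, k11=0.15)


@pytest.fixture(scope="session")
def hwp_blocks() -> BlockCounts:
    """Four identical blocks exactly at HWP proportions (p = 0.6)."""
    return BlockCounts.from_array([[360, 480, 160]] * 4)


@pytest.fixture(scope="session")
def small_pool():
    """A 200k-person population pool under the default scenario (MAF 0.4).

    Session-scoped: building and calibrating the pool costs a fraction of a
    second but several test modules reuse it.
    """
    scn = SimulationScenario(pool_size=200_000)
    pool, pop, scn_cal = build_population(scn, np.random.default_rng(2024))
    return pool, pop, scn_cal
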