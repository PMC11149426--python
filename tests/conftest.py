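"""Shared fixtures.

The desk-scale continuous-paradigm run is the single expensive fixture
(~30 optimized saccades through the full two-loop controller); it is built
once per session and shared by the accuracy, kinematics and synergy tests.
"""

import numpy as np
import pytest

from bioeye.experiments import ParadigmConfig, run_continuous
from bioeye.plant import default_plant


@pytest.fixture(scope="session")
def plant():
    return default_plant()


@pytest.fixture(scope="session")
def continuous_run(plant):
    """Desk-scale continuous paradigm: 30 chained optimal saccades."""
    cfg = ParadigmConfig("continuous", n=30, seed=2024)
    return run_continuous(cfg, plant=plant)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
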