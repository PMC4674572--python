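import numpy as np
import pytest

import leakfire as lf
from leakfire.protocol_engine import DEFAULT_GL_GRID_NS


@pytest.fixture(scope="session")
def base_params():
    """The published parameter set (Kdr-only, gL = 7.4 nS, bushy-cell Na)."""
    return lf.ncm_model_params()


@pytest.fixture(scope="session")
def kdr_sweep(base_params):
    """Default leak sweep of the Kdr-only model, shared across tests."""
    return lf.run_leak_sweep(base_params)


@pytest.fixture(scope="session")
def variant_sweeps(base_params):
    """Leak sweeps with each added K current, shared across tests."""
    return lf.run_leak_sweep(base_params,
                             variants=("ka", "klt20", "klt200", "kht"))


@pytest.fixture(scope="session")
def default_grid():
    return np.asarray(DEFAULT_GL_GRID_NS)


@pytest.fixture()
def passive_params(base_params):
    """Leak-only cell: all voltage-gated conductances removed."""
    import dataclasses
    return dataclasses.replace(base_params, gNa=0.0, gKdr=0.0, gKlt=0.0,
                               gKht=0.0, gKa=0.0)
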