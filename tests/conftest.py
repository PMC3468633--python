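import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from iporangaia import default_layout
from iporangaia.synthetic_data import SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def constant_truth(layout):
    """Constant-rate study conditions with known truth, shared across tests."""
    t = layout.n_primary
    phi = np.vstack([np.full(t - 1, 0.75)] * 2 + [np.full(t - 1, 0.9)])
    p = np.full((3, t), 0.4)
    psi = np.vstack([np.full(t - 1, 0.25), np.full(t - 1, 0.30)])
    return {"phi": phi, "p": p, "psi": psi,
            "phi_NC": 0.75, "phi_C": 0.9, "p_all": 0.4,
            "psi_NC": 0.25, "psi_CN": 0.30}


@pytest.fixture(scope="session")
def constant_population(layout, constant_truth):
    """One medium simulated dataset under the constant-rate conditions."""
    cfg = SimulationConfig(
        seed=7, phi=constant_truth["phi"], p=constant_truth["p"],
        psi=constant_truth["psi"],
        recruitment_males=(500,) + (0,) * (layout.n_primary - 1),
        recruitment_females=(300,) + (0,) * (layout.n_primary - 1),
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def default_population():
    """A dataset under the default (time-varying) study conditions."""
    return simulate_population(SimulationConfig(seed=21))
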