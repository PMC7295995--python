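"""Shared fixtures: scaled library, trained bank, reference phantoms.

The expensive fixtures are session-scoped so the full suite trains the
network bank exactly once.
"""

import numpy as np
import pytest

from octflow import network as net
from octflow import phantom as ph
from octflow import simulator as sim

#: seed for every session fixture
SEED = 0


@pytest.fixture(scope="session")
def scaled_spec() -> sim.LibrarySpec:
    return sim.LibrarySpec.scaled_default(seed=SEED)


@pytest.fixture(scope="session")
def scaled_library(scaled_spec) -> sim.SignalLibrary:
    return sim.build_library(scaled_spec)


@pytest.fixture(scope="session")
def trained_bank(scaled_library) -> net.NetworkBank:
    cfg = net.TrainingConfig(epochs=30, seed=SEED)
    return net.train_bank(scaled_library, cfg)


@pytest.fixture(scope="session")
def untrained_bank(scaled_spec) -> net.NetworkBank:
    """Bank of initialized (not trained) networks for shape/purity tests."""
    nets = {
        snr: net.build_network(n_classes=scaled_spec.grid.n_classes, seed=SEED)
        for snr in scaled_spec.snr_levels_db
    }
    return net.NetworkBank(nets, scaled_spec.grid)


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise-free 125-um tube at 85 deg, 50 uL/min: the Doppler oracle case."""
    spec = ph.PhantomSpec(doppler_angle_deg=85.0, pump_rate_ul_min=50.0,
                          snr_db=None, seed=SEED)
    return ph.synth_stepped_mscan(spec), spec


@pytest.fixture(scope="session")
def noisy_phantom_20db():
    spec = ph.PhantomSpec(doppler_angle_deg=85.0, pump_rate_ul_min=50.0,
                          snr_db=20.0, seed=SEED)
    return ph.synth_stepped_mscan(spec), spec


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
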