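import numpy as np
import pytest

from schnorb_lite.chem import build_orbital_index
from schnorb_lite.model import ModelConfig, init_params
from schnorb_lite.reference import (generate_dataset, h2_system, make_record,
                                    water_like_system)


@pytest.fixture(scope="session")
def h2():
    mol, basis, params, n_el = h2_system()
    return {"mol": mol, "basis": basis, "params": params, "n_el": n_el,
            "index": build_orbital_index(mol, basis)}


@pytest.fixture(scope="session")
def water():
    mol, basis, params, n_el = water_like_system()
    return {"mol": mol, "basis": basis, "params": params, "n_el": n_el,
            "index": build_orbital_index(mol, basis)}


@pytest.fixture(scope="session")
def water_record(water):
    return make_record(water["mol"], water["basis"], water["params"], water["n_el"])


@pytest.fixture(scope="session")
def water_records_small(water):
    """24 distorted water-like reference samples (shared; treat as read-only)."""
    return generate_dataset(water["mol"], 24, 0.05, seed=7, basis=water["basis"],
                            params=water["params"], n_electrons=water["n_el"])


@pytest.fixture(scope="session")
def tiny_model(water):
    """Randomly initialized desk-scale model on the water-like basis."""
    cfg = ModelConfig.from_basis(water["basis"], B=16, T=1, n_hidden=16)
    params = init_params(cfg, seed=3)
    return cfg, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
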