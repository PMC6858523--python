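import numpy as np
import pytest

from schnorb_lite import autodiff as ad
from schnorb_lite.chem import ConfigurationError, Molecule, build_orbital_index
from schnorb_lite.model import (Forward, ModelConfig, init_params, predict, ssp)
from schnorb_lite.rotations import random_rotation


def test_ssp_values_and_monotonicity():
    x = ad.tensor(np.array([0.0, 50.0, -50.0]))
    y = ssp(x).value
    assert np.isclose(y[0], 0.0, atol=1e-12)                 # ln 1
    assert np.isclose(y[1] - 50.0, -np.log(2.0), atol=1e-9)  # asymptote x - ln 2
    assert y[2] > -np.log(2.0) - 1e-9                        # bounded below
    grid = ssp(ad.tensor(np.linspace(-5, 5, 101))).value
    assert np.all(np.diff(grid) > 0)


def _forward(water, tiny_model, positions=None, mol=None):
    cfg, params = tiny_model
    m = mol if mol is not None else water["mol"]
    if positions is not None:
        m = m.with_positions(positions)
    return Forward(params, cfg, m, build_orbital_index(m, water["basis"]))


def test_radial_filter_vanishes_beyond_cutoff(water, tiny_model):
    cfg, params = tiny_model
    far = np.array([[0.0, 0, 0], [cfg.r_c + 1.0, 0, 0]])
    mol = Molecule([1, 1], far)
    fwd = Forward(params, cfg, mol,
                  build_orbital_index(mol, water["basis"]))
    # no pairs inside cutoff: representations equal the raw embeddings refined
    # only by (empty) convolution sums -> both atoms identical
    assert np.allclose(fwd.x.value[0], fwd.x.value[1], atol=1e-14)
    # off-site H block of a beyond-cutoff pair is exactly zero
    n = water["basis"].n_ao(1)
    assert np.allclose(fwd.H.value[:n, n:], 0.0)


def test_cutoff_function_half_at_half_radius():
    # f_cutoff(r) = 0.5 (1 + cos(pi r / r_c)) -> 0.5 at r_c/2, 0 at r_c
    r_c = 5.0
    f = lambda r: 0.5 * (1 + np.cos(np.pi * r / r_c)) * (r < r_c)
    assert np.isclose(f(r_c / 2), 0.5)
    assert f(r_c) == 0.0


def test_forward_deterministic_and_symmetric(water, tiny_model):
    fwd1, fwd2 = _forward(water, tiny_model), _forward(water, tiny_model)
    assert np.array_equal(fwd1.H.value, fwd2.H.value)
    assert np.array_equal(fwd1.S.value, fwd2.S.value)
    assert np.abs(fwd1.H.value - fwd1.H.value.T).max() == 0.0
    assert np.abs(fwd1.S.value - fwd1.S.value.T).max() == 0.0
    assert fwd1.H.value.shape == (water["index"].n_orbitals,) * 2


def test_atom_representations_rotation_invariant(water, tiny_model):
    rot = random_rotation(17)
    f0 = _forward(water, tiny_model)
    f1 = _forward(water, tiny_model,
                  positions=water["mol"].positions @ rot.R.T)
    assert np.abs(f0.x.value - f1.x.value).max() < 1e-6
    assert abs(f0.E.value - f1.E.value) < 1e-6


def test_pair_coefficients_rotation_invariant(water, tiny_model):
    """Omega^0 (the lambda = 0 slice) must be unchanged under rotation."""
    rot = random_rotation(18)
    f0 = _forward(water, tiny_model)
    f1 = _forward(water, tiny_model,
                  positions=water["mol"].positions @ rot.R.T)
    assert np.abs(f0.Omega[0].value - f1.Omega[0].value).max() < 1e-6


def test_omega0_constant_across_directions(water, tiny_model):
    cfg, _ = tiny_model
    f = _forward(water, tiny_model)
    om0 = f.Omega[0].value.reshape(-1, cfg.B, cfg.D)
    assert np.abs(om0 - om0[:, :, :1]).max() == 0.0


def test_permutation_equivariance_full_forward(water, tiny_model):
    cfg, params = tiny_model
    mol = water["mol"]
    pred = predict(params, cfg, mol, water["index"])
    perm = [0, 2, 1]                       # swap the two H atoms
    mp = Molecule([mol.atomic_numbers[p] for p in perm], mol.positions[perm])
    predp = predict(params, cfg, mp, build_orbital_index(mp, water["basis"]))
    po = [0, 1, 2, 3, 5, 4]                # orbital permutation (O block first)
    assert np.abs(predp.H - pred.H[np.ix_(po, po)]).max() < 1e-8
    assert np.abs(predp.S - pred.S[np.ix_(po, po)]).max() < 1e-8
    assert np.abs(predp.F - pred.F[perm]).max() < 1e-8
    assert abs(predp.E - pred.E) < 1e-8


def test_forces_are_exact_energy_gradients(water, tiny_model):
    cfg, params = tiny_model
    mol = water["mol"]
    pred = predict(params, cfg, mol, water["index"])
    assert np.abs(pred.F.sum(axis=0)).max() < 1e-6       # translation invariance
    d = 1e-4
    for i, c in [(0, 0), (1, 1), (2, 2), (0, 2)]:
        p1, p2 = mol.positions.copy(), mol.positions.copy()
        p1[i, c] += d
        p2[i, c] -= d
        fd = -(predict(params, cfg, mol.with_positions(p1), water["index"]).E
               - predict(params, cfg, mol.with_positions(p2), water["index"]).E) / (2 * d)
        assert abs(fd - pred.F[i, c]) < 1e-4


def test_onsite_overlap_blocks_shared_per_element(water, tiny_model):
    cfg, params = tiny_model
    mol = water["mol"]
    fwd = _forward(water, tiny_model)
    S = fwd.S.value
    # the two H atoms (1 AO each) must carry identical on-site entries
    assert S[4, 4] == S[5, 5] == 1.0       # initialized to unit self-overlap


def test_unseen_element_raises(tiny_model):
    cfg, params = tiny_model
    mol = Molecule([79], np.zeros((1, 3)))
    with pytest.raises(ConfigurationError):
        Forward(params, cfg, mol)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        ModelConfig(elements=(1,), n_ao={1: 1}, L=5)
    with pytest.raises(ConfigurationError):
        ModelConfig(elements=(1,), n_ao={1: 1}, L=1, r_c=-1.0)
    cfg = ModelConfig(elements=(1, 8), n_ao={1: 1, 8: 4}, L=1)
    assert cfg.n_orders == 3               # 2L + 1 interaction orders
    assert cfg.n_ao_max == 4
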