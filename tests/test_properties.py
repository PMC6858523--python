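import numpy as np
import pytest
import scipy.linalg

from schnorb_lite.chem import build_orbital_index
from schnorb_lite.estimator import ModelProvider
from schnorb_lite.integrals import overlap_and_moments
from schnorb_lite.properties import (ConditioningError, DegeneracyError,
                                     SpectrumResult, density_matrix, dos_curve,
                                     gap_gradient, homo_lumo_gap,
                                     loewdin_analysis, multipole_moments,
                                     orbital_energy_gradient, solve_orbitals)
from schnorb_lite.reference import HueckelReference, hueckel_hamiltonian


def _random_pencil(rng, n=8):
    A = rng.normal(size=(n, n))
    H = A + A.T
    B = rng.normal(size=(n, n))
    S = B @ B.T + n * np.eye(n)
    d = 1 / np.sqrt(np.diag(S))
    return H, d[:, None] * S * d[None, :]


def test_solve_orbitals_identity_overlap_matches_eigh(rng):
    H, _ = _random_pencil(rng)
    spec = solve_orbitals(H, np.eye(8), 4)
    w = np.linalg.eigvalsh(H)
    assert np.allclose(spec.epsilon, w, atol=1e-10)


def test_solve_orbitals_h2_closed_form(h2):
    ref = HueckelReference(h2["basis"], h2["params"], 2)
    H, S = ref.matrices(h2["mol"])
    spec = solve_orbitals(H, S, 2)
    s, h, K = S[0, 1], h2["params"].h[(1, 0)], h2["params"].K
    expect = sorted([h * (1 + K * s) / (1 + s), h * (1 - K * s) / (1 - s)])
    assert np.allclose(spec.epsilon, expect, atol=1e-10)
    assert homo_lumo_gap(spec) == pytest.approx(expect[1] - expect[0], abs=1e-10)


def test_solve_orbitals_contracts_on_random_instances(rng):
    for _ in range(20):
        H, S = _random_pencil(rng)
        spec = solve_orbitals(H, S, 6)
        assert np.abs(H @ spec.C - S @ spec.C @ np.diag(spec.epsilon)).max() < 1e-7
        assert np.abs(spec.C.T @ S @ spec.C - np.eye(len(spec.epsilon))).max() < 1e-8
        assert np.all(np.diff(spec.epsilon) >= -1e-12)


def test_solve_orbitals_deterministic_under_degeneracy():
    H = np.diag([-2.0, -1.0, -1.0, 3.0])
    spec1 = solve_orbitals(H, np.eye(4), 2)
    spec2 = solve_orbitals(H.copy(), np.eye(4), 2)
    assert np.array_equal(spec1.C, spec2.C)
    assert np.abs(spec1.C.T @ spec1.C - np.eye(4)).max() < 1e-12


def test_indefinite_overlap_raises():
    with pytest.raises(ConditioningError):
        solve_orbitals(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 2)


def test_density_matrix_identities(water, water_record):
    spec = solve_orbitals(water_record.H, water_record.S, water["n_el"])
    P = density_matrix(spec)
    S = water_record.S
    assert np.trace(P @ S) == pytest.approx(water["n_el"], abs=1e-8)
    assert np.abs(P @ S @ P - 2 * P).max() < 1e-8        # closed-shell projector
    empty = density_matrix(SpectrumResult(spec.epsilon, spec.C,
                                          np.zeros_like(spec.occupation), 0))
    assert np.allclose(empty, 0.0)


def test_loewdin_h2_symmetric(h2):
    ref = HueckelReference(h2["basis"], h2["params"], 2)
    H, S = ref.matrices(h2["mol"])
    spec = solve_orbitals(H, S, 2)
    pop = loewdin_analysis(density_matrix(spec), S, h2["index"],
                           h2["params"].n_valence, h2["mol"].atomic_numbers)
    assert np.allclose(pop.charges, 0.0, atol=1e-10)
    assert pop.bond_orders[0, 1] == pytest.approx(1.0, abs=1e-10)


def test_loewdin_charge_sum_identity(water, water_records_small):
    nv = water["params"].n_valence
    for rec in water_records_small[:5]:
        spec = solve_orbitals(rec.H, rec.S, water["n_el"])
        pop = loewdin_analysis(density_matrix(spec), rec.S, water["index"],
                               nv, rec.molecule.atomic_numbers)
        total_val = sum(nv[z] for z in rec.molecule.atomic_numbers)
        assert pop.charges.sum() == pytest.approx(total_val - water["n_el"], abs=1e-8)
        assert np.allclose(pop.bond_orders, pop.bond_orders.T)


def test_separated_fragments_have_zero_bond_order(h2):
    mol = h2["mol"].with_positions(np.array([[0, 0, 0], [0, 0, 40.0]]))
    ref = HueckelReference(h2["basis"], h2["params"], 2)
    H, S = ref.matrices(mol)
    idx = build_orbital_index(mol, h2["basis"])
    spec = solve_orbitals(H, S, 2)
    pop = loewdin_analysis(density_matrix(spec), S, idx,
                           h2["params"].n_valence, mol.atomic_numbers)
    assert pop.bond_orders[0, 1] < 1e-12


def test_dipole_zero_for_symmetric_h2(h2):
    ref = HueckelReference(h2["basis"], h2["params"], 2)
    H, S = ref.matrices(h2["mol"])
    spec = solve_orbitals(H, S, 2)
    P = density_matrix(spec)
    _, m = overlap_and_moments(h2["mol"], h2["basis"], orders=(1, 2))
    mom = multipole_moments(P, S, {k: m[k] for k in "xyz"},
                            {k: m[k] for k in m if len(k) == 2},
                            h2["mol"], h2["params"].n_valence)
    assert np.abs(mom.dipole).max() < 1e-10


def test_dipole_origin_independent_for_neutral_system(water, water_record):
    spec = solve_orbitals(water_record.H, water_record.S, water["n_el"])
    P = density_matrix(spec)
    _, m = overlap_and_moments(water["mol"], water["basis"], orders=(1, 2))
    m1 = {k: m[k] for k in "xyz"}
    m2 = {k: m[k] for k in m if len(k) == 2}
    nv = water["params"].n_valence
    a = multipole_moments(P, water_record.S, m1, m2, water["mol"], nv)
    b = multipole_moments(P, water_record.S, m1, m2, water["mol"], nv,
                          origin=(1.7, -0.3, 2.2))
    assert np.abs(a.dipole - b.dipole).max() < 1e-8


def test_single_center_moment_consistency():
    """One-orbital atom: electronic dipole = P * position, nuclear = n_val * r."""
    from schnorb_lite.chem import BasisSet, GaussianShell, Molecule
    basis = BasisSet({1: [GaussianShell(0, [0.9], [1.0])]})
    r = np.array([0.5, -0.3, 0.8])
    mol = Molecule([1], [r])
    S, m = overlap_and_moments(mol, basis, orders=(1, 2))
    P = np.array([[2.0]])
    mom = multipole_moments(P, S, {k: m[k] for k in "xyz"},
                            {k: m[k] for k in m if len(k) == 2},
                            mol, {1: 1})
    assert np.allclose(mom.dipole / 4.803204, (1 - 2) * r, atol=1e-10)


def test_dos_normalization_and_broadening():
    grid = np.linspace(-20, 20, 4001)
    dg = grid[1] - grid[0]
    one = dos_curve([[0.0]], sigma=0.4, grid=grid)
    assert np.trapezoid(one, dx=dg) == pytest.approx(1.0, abs=1e-6)
    assert grid[np.argmax(one)] == pytest.approx(0.0, abs=dg)
    two_frames = dos_curve([[-1.0, 1.0], [-2.0, 2.0]], sigma=0.4, grid=grid)
    assert np.trapezoid(two_frames, dx=dg) == pytest.approx(2.0, abs=1e-6)
    # combined spread exceeds a single frame's
    var = np.trapezoid(two_frames * grid ** 2, dx=dg) / 2
    var_single = np.trapezoid(dos_curve([[-1.0, 1.0]], 0.4, grid) * grid ** 2, dx=dg)
    assert var > var_single
    with pytest.raises(ValueError):
        dos_curve([], 0.4, grid)


def test_homo_lumo_gap_arithmetic():
    spec = SpectrumResult(np.array([-10.0, -5.0, 1.0]), np.eye(3),
                          np.array([2.0, 2.0, 0.0]), 4)
    assert homo_lumo_gap(spec) == pytest.approx(6.0)
    degen = SpectrumResult(np.array([-5.0, -5.0, -5.0]), np.eye(3),
                           np.array([2.0, 0.0, 0.0]), 2)
    assert homo_lumo_gap(degen) == pytest.approx(0.0)
    full = SpectrumResult(np.array([-1.0]), np.eye(1), np.array([2.0]), 2)
    with pytest.raises(ValueError):
        homo_lumo_gap(full)


@pytest.mark.parametrize("kind", ["generator", "model"])
def test_orbital_gradient_matches_finite_differences(kind, water, tiny_model):
    mol = water["mol"]
    if kind == "generator":
        provider = HueckelReference(water["basis"], water["params"], water["n_el"])
    else:
        cfg, params = tiny_model
        provider = ModelProvider(params, cfg, water["basis"])
    m = 2
    g = orbital_energy_gradient(provider, mol, m)
    assert np.abs(g.sum(axis=0)).max() < 1e-6            # translation invariance
    d = 1e-4
    for i, c in [(0, 0), (1, 1), (2, 2)]:
        p1, p2 = mol.positions.copy(), mol.positions.copy()
        p1[i, c] += d
        p2[i, c] -= d
        e1 = scipy.linalg.eigh(*provider.matrices(mol.with_positions(p1)),
                               eigvals_only=True)[m]
        e2 = scipy.linalg.eigh(*provider.matrices(mol.with_positions(p2)),
                               eigvals_only=True)[m]
        assert abs((e1 - e2) / (2 * d) - g[i, c]) < 1e-4


def test_orbital_gradient_degeneracy_guard(water):
    provider = HueckelReference(water["basis"], water["params"], water["n_el"])
    # the p-dominated levels 2 and 3 of the relaxed template are near-degenerate
    H, S = provider.matrices(water["mol"])
    w = scipy.linalg.eigh(H, S, eigvals_only=True)
    gaps = np.diff(w)
    m = int(np.argmin(gaps))
    with pytest.raises(DegeneracyError):
        orbital_energy_gradient(provider, water["mol"], m,
                                degeneracy_threshold=float(gaps.min() * 10))


def test_properties_rotation_invariant(water, water_record):
    from schnorb_lite.rotations import random_rotation, rotate_record
    rot = random_rotation(77)
    rec_r = rotate_record(water_record, rot, water["index"])
    nv = water["params"].n_valence
    out = {}
    for tag, rec, mol in (("o", water_record, water["mol"]),
                          ("r", rec_r, rec_r.molecule)):
        spec = solve_orbitals(rec.H, rec.S, water["n_el"])
        P = density_matrix(spec)
        pop = loewdin_analysis(P, rec.S, water["index"], nv, mol.atomic_numbers)
        _, m = overlap_and_moments(mol, water["basis"], orders=(1, 2))
        mom = multipole_moments(P, rec.S, {k: m[k] for k in "xyz"},
                                {k: m[k] for k in m if len(k) == 2}, mol, nv)
        out[tag] = (spec.epsilon, pop.charges, pop.bond_orders,
                    np.linalg.norm(mom.dipole), homo_lumo_gap(spec))
    for a, b in zip(out["o"], out["r"]):
        assert np.abs(np.asarray(a) - np.asarray(b)).max() < 1e-8
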