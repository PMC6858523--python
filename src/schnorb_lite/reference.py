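"""Synthetic quantum-chemistry reference data: an extended-Hueckel-style model.

The generator supplies the same (H, S, E, F) interface as an ab-initio code,
at a tiny fraction of the cost, while being smooth in the geometry and
*exactly* rotationally covariant: every shell-pair block of H and S transforms
under the real Wigner matrices because H is built from the analytic overlap.

Model:
    H_mumu = h_mu                                   (on-site orbital energy, eV)
    H_munu = K/2 (h_mu + h_nu) S_munu,  mu != nu    (Wolfsberg-Helmholz)
    E      = 2 sum_occ eps_m + sum_i<j a exp(-d_ij / d0)
    F      = -grad E by central finite differences (step 1e-4 Angstrom)

with eps_m the generalized eigenvalues of (H, S).  This is not a quantitative
electronic-structure method -- it is a well-behaved stand-in with the right
symmetries, used to exercise and test the learning pipeline end to end.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .chem import (BasisSet, ConfigurationError, ElectronicRecord, GaussianShell,
                   Molecule, build_orbital_index)
from .integrals import overlap_and_moments

FD_STEP = 1e-4          # Angstrom, central differences for reference forces
MIN_DISTANCE = 0.5      # Angstrom, geometry rejection threshold


class DegenerateReferenceError(RuntimeError):
    """HOMO-LUMO degeneracy makes the reference energy/forces ill-defined."""


class GeometryGenerationError(RuntimeError):
    """Too many rejected random distortions in a row."""


@dataclasses.dataclass
class HueckelParams:
    """Parameters of the synthetic one-electron model."""

    h: dict                      # (element Z, shell index) -> on-site energy, eV
    n_valence: dict              # element Z -> valence electron count
    K: float = 1.75              # Wolfsberg-Helmholz constant
    repulsion_a: float = 150.0   # pair repulsion amplitude, eV
    repulsion_d: float = 0.35    # pair repulsion length scale, Angstrom

    def __post_init__(self):
        if self.K <= 0 or self.repulsion_d <= 0:
            raise ValueError("K and repulsion_d must be positive")
        if any(v < 1 for v in self.n_valence.values()):
            raise ValueError("valence counts must be >= 1")

    def onsite_vector(self, mol: Molecule, basis: BasisSet) -> np.ndarray:
        index = build_orbital_index(mol, basis)
        h = np.empty(index.n_orbitals)
        for k, (atom, shell, l, m) in enumerate(index.orbital_labels):
            z = mol.atomic_numbers[atom]
            try:
                h[k] = self.h[(z, shell)]
            except KeyError:
                raise ConfigurationError(
                    f"no on-site energy for element Z={z}, shell {shell}") from None
        return h

    def to_json_dict(self) -> dict:
        return {
            "h": [[z, s, v] for (z, s), v in self.h.items()],
            "n_valence": {str(z): v for z, v in self.n_valence.items()},
            "K": self.K, "repulsion_a": self.repulsion_a,
            "repulsion_d": self.repulsion_d,
        }

    @classmethod
    def from_json_dict(cls, raw: dict) -> "HueckelParams":
        return cls(h={(int(z), int(s)): float(v) for z, s, v in raw["h"]},
                   n_valence={int(z): int(v) for z, v in raw["n_valence"].items()},
                   K=float(raw.get("K", 1.75)),
                   repulsion_a=float(raw.get("repulsion_a", 150.0)),
                   repulsion_d=float(raw.get("repulsion_d", 0.35)))


def hueckel_hamiltonian(mol: Molecule, basis: BasisSet, params: HueckelParams,
                        S: np.ndarray = None, h_vec: np.ndarray = None) -> np.ndarray:
    """Wolfsberg-Helmholz Hamiltonian (eV) in the normalized AO basis."""
    if S is None:
        S, _ = overlap_and_moments(mol, basis)
    h = params.onsite_vector(mol, basis) if h_vec is None else h_vec
    H = 0.5 * params.K * (h[:, None] + h[None, :]) * S
    np.fill_diagonal(H, h)
    return H


def _electronic_energy(mol, basis, params, n_electrons, gap_floor=1e-8, h_vec=None):
    S, _ = overlap_and_moments(mol, basis)
    H = hueckel_hamiltonian(mol, basis, params, S, h_vec)
    eps = scipy.linalg.eigh(H, S, eigvals_only=True)
    n_occ = n_electrons // 2
    if n_occ < len(eps) and eps[n_occ] - eps[n_occ - 1] < gap_floor:
        raise DegenerateReferenceError(
            f"HOMO-LUMO gap {eps[n_occ] - eps[n_occ - 1]:.2e} eV below {gap_floor:.0e}")
    return 2.0 * eps[:n_occ].sum()


def _repulsion(mol: Molecule, params: HueckelParams) -> float:
    d = np.linalg.norm(mol.positions[:, None] - mol.positions[None, :], axis=-1)
    iu = np.triu_indices(mol.n_atoms, k=1)
    return float(np.sum(params.repulsion_a * np.exp(-d[iu] / params.repulsion_d)))


def reference_energy(mol: Molecule, basis: BasisSet, params: HueckelParams,
                     n_electrons: int, h_vec: np.ndarray = None) -> float:
    """Total energy (eV): doubly occupied orbital sum plus pair repulsion."""
    if n_electrons % 2 or n_electrons < 2:
        raise ValueError("n_electrons must be a positive even integer")
    return _electronic_energy(mol, basis, params, n_electrons, h_vec=h_vec) \
        + _repulsion(mol, params)


def reference_energy_forces(mol: Molecule, basis: BasisSet, params: HueckelParams,
                            n_electrons: int):
    """(E, F) with forces from central finite differences of the total energy."""
    h_vec = params.onsite_vector(mol, basis)     # composition-fixed; hoisted
    E = reference_energy(mol, basis, params, n_electrons, h_vec)
    F = np.zeros((mol.n_atoms, 3))
    pos = mol.positions
    for i in range(mol.n_atoms):
        for c in range(3):
            for sign in (+1, -1):
                p = pos.copy()
                p[i, c] += sign * FD_STEP
                F[i, c] -= sign * reference_energy(mol.with_positions(p), basis,
                                                   params, n_electrons, h_vec)
    F /= 2.0 * FD_STEP
    return E, F


def make_record(mol: Molecule, basis: BasisSet, params: HueckelParams,
                n_electrons: int) -> ElectronicRecord:
    """Full reference sample (H, S, E, F) for one geometry."""
    S, _ = overlap_and_moments(mol, basis)
    H = hueckel_hamiltonian(mol, basis, params, S)
    E, F = reference_energy_forces(mol, basis, params, n_electrons)
    return ElectronicRecord(mol, H, S, E, F, n_electrons)


def generate_dataset(template: Molecule, n: int, sigma: float, seed: int,
                     basis: BasisSet, params: HueckelParams, n_electrons: int):
    """Randomly distorted copies of ``template`` with full reference labels.

    Each geometry adds i.i.d. Gaussian displacements of scale ``sigma``
    (Angstrom) to every coordinate; geometries with atoms closer than 0.5 A or
    a (near-)degenerate frontier gap are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    records = []
    rejected = 0
    while len(records) < n:
        if rejected >= 100:
            raise GeometryGenerationError(
                "100 consecutive rejections; reduce sigma or change the template")
        pos = template.positions + rng.normal(scale=sigma, size=template.positions.shape) \
            if sigma > 0 else template.positions.copy()
        mol = template.with_positions(pos)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        iu = np.triu_indices(mol.n_atoms, k=1)
        if np.any(d[iu] < MIN_DISTANCE):
            rejected += 1
            continue
        try:
            records.append(make_record(mol, basis, params, n_electrons))
        except DegenerateReferenceError:
            rejected += 1
            continue
        rejected = 0
    return records


class HueckelReference:
    """Force/matrix provider facade over the synthetic model (one system)."""

    def __init__(self, basis: BasisSet, params: HueckelParams, n_electrons: int):
        self.basis = basis
        self.params = params
        self.n_electrons = n_electrons
        self._h_cache = {}

    def _h_vec(self, mol: Molecule) -> np.ndarray:
        key = tuple(mol.atomic_numbers)
        if key not in self._h_cache:
            self._h_cache[key] = self.params.onsite_vector(mol, self.basis)
        return self._h_cache[key]

    def matrices(self, mol: Molecule):
        S, _ = overlap_and_moments(mol, self.basis)
        return hueckel_hamiltonian(mol, self.basis, self.params, S,
                                   self._h_vec(mol)), S

    def energy(self, mol: Molecule) -> float:
        return reference_energy(mol, self.basis, self.params, self.n_electrons,
                                self._h_vec(mol))

    def energy_forces(self, mol: Molecule):
        return reference_energy_forces(mol, self.basis, self.params, self.n_electrons)


# -- built-in toy systems ----------------------------------------------

def h2_system():
    """H2 in a contracted s basis: the smallest closed-form test case.

    The repulsion amplitude is chosen so the shipped template is (close to) a
    mechanical equilibrium of the synthetic surface; template geometries were
    relaxed once on that surface.
    """
    basis = BasisSet({1: [GaussianShell(0, [3.42525091, 0.62391373, 0.16885540],
                                        [0.15432897, 0.53532814, 0.44463454])]},
                     name="toy-h")
    params = HueckelParams(h={(1, 0): -13.6}, n_valence={1: 1},
                           repulsion_a=39.2, repulsion_d=0.20)
    mol = Molecule([1, 1], [[0.0, 0.0, -0.37], [0.0, 0.0, 0.37]], "H2 template")
    return mol, basis, params, 2


def water_like_system():
    """Bent 3-atom molecule, s+p valence on the heavy atom (water-like)."""
    o_exp = [5.033151, 1.169596, 0.380389]
    basis = BasisSet({
        8: [GaussianShell(0, o_exp, [-0.09996723, 0.39951283, 0.70011547]),
            GaussianShell(1, o_exp, [0.15591627, 0.60768372, 0.39195739])],
        1: [GaussianShell(0, [3.42525091, 0.62391373, 0.16885540],
                          [0.15432897, 0.53532814, 0.44463454])],
    }, name="toy-sp")
    params = HueckelParams(h={(8, 0): -32.38, (8, 1): -14.8, (1, 0): -13.6},
                           n_valence={8: 6, 1: 1},
                           repulsion_a=67.5, repulsion_d=0.20)
    mol = Molecule([8, 1, 1],
                   [[-0.0969, -0.1251, 0.0], [0.7613, -0.4898, 0.0],
                    [-0.6643, 0.6149, 0.0]],
                   "water-like template")
    return mol, basis, params, 8


def chain4_system():
    """Planar 4-atom zig-zag chain with an s+p carbon-like basis."""
    c_exp = [2.941249, 0.683483, 0.22229]
    basis = BasisSet({
        6: [GaussianShell(0, c_exp, [-0.09996723, 0.39951283, 0.70011547]),
            GaussianShell(1, c_exp, [0.15591627, 0.60768372, 0.39195739])],
    }, name="toy-chain")
    params = HueckelParams(h={(6, 0): -21.4, (6, 1): -11.4}, n_valence={6: 4},
                           repulsion_a=732.8, repulsion_d=0.20)
    mol = Molecule([6, 6, 6, 6],
                   [[-1.9184, -0.2327, 0.0], [-0.8399, 0.155, 0.0],
                    [0.8399, -0.155, 0.0], [1.9184, 0.2327, 0.0]],
                   "4-atom chain template")
    return mol, basis, params, 16


TOY_SYSTEMS = {"h2": h2_system, "water": water_like_system, "chain4": chain4_system}
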