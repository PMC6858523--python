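"""Everything derived from (H, S): spectra, populations, moments, DOS, gradients.

The molecular orbitals come from the generalized symmetric eigenproblem
H c_m = eps_m S c_m; the coefficient matrix is S-orthonormal (C^T S C = I).
Downstream quantities -- closed-shell density matrix, Loewdin charges and bond
orders, dipole/quadrupole moments, broadened density of states, HOMO-LUMO gap
and analytic orbital-energy gradients -- all consume the same SpectrumResult.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from . import autodiff as ad
from .chem import Molecule, OrbitalIndex

EA_TO_DEBYE = 4.803204        # 1 e*Angstrom in Debye


class ConditioningError(np.linalg.LinAlgError):
    """Overlap matrix not safely positive definite."""


class DegeneracyError(RuntimeError):
    """Requested quantity is ill-defined for (near-)degenerate orbitals."""


@dataclasses.dataclass
class SpectrumResult:
    epsilon: np.ndarray          # ascending orbital energies, eV
    C: np.ndarray                # column m = coefficient vector c_m, C^T S C = I
    occupation: np.ndarray       # 2 for occupied, 0 for virtual
    n_electrons: int


@dataclasses.dataclass
class PopulationResult:
    charges: np.ndarray          # per-atom Loewdin partial charge, e
    bond_orders: np.ndarray      # symmetric per-atom-pair matrix


@dataclasses.dataclass
class Moments:
    dipole: np.ndarray           # Debye
    quadrupole: np.ndarray       # symmetric 3x3, Debye * Angstrom
    origin: np.ndarray           # Angstrom


def _sqrt_spd(S: np.ndarray, floor: float = 1e-10):
    w, V = np.linalg.eigh(S)
    if w[0] < floor:
        raise ConditioningError(f"overlap eigenvalue {w[0]:.2e} below {floor:.0e}")
    return (V * np.sqrt(w)) @ V.T, (V / np.sqrt(w)) @ V.T


def _fix_orientation(eps: np.ndarray, C: np.ndarray, tol: float = 1e-9):
    """Deterministic orientation of eigenvectors (degenerate blocks included).

    Within each degenerate block the coefficients are rotated to a triangular
    form by a QR factorization, then every column's leading nonzero entry is
    made positive.  S-orthonormality is preserved (the rotation is orthogonal).
    """
    n = len(eps)
    start = 0
    while start < n:
        stop = start + 1
        while stop < n and eps[stop] - eps[stop - 1] < tol:
            stop += 1
        if stop - start > 1:
            block = C[:, start:stop]
            q, _ = np.linalg.qr(block.T)        # block.T = q r  ->  block @ q triangular
            C[:, start:stop] = block @ q
        start = stop
    for m in range(n):
        lead = np.flatnonzero(np.abs(C[:, m]) > 1e-12)
        if lead.size and C[lead[0], m] < 0:
            C[:, m] *= -1.0
    return C


def solve_orbitals(H: np.ndarray, S: np.ndarray, n_electrons: int) -> SpectrumResult:
    """Generalized symmetric eigensolve via the S^(-1/2) transformation."""
    if n_electrons % 2:
        raise ValueError("closed-shell electron counts only")
    _, S_inv_half = _sqrt_spd(S)
    Ht = S_inv_half @ (0.5 * (H + H.T)) @ S_inv_half
    eps, V = np.linalg.eigh(0.5 * (Ht + Ht.T))
    C = S_inv_half @ V
    C = _fix_orientation(eps, C)
    occ = np.zeros(len(eps))
    occ[:n_electrons // 2] = 2.0
    return SpectrumResult(eps, C, occ, n_electrons)


def density_matrix(spec: SpectrumResult) -> np.ndarray:
    """Closed-shell density matrix P = 2 sum_occ c_m c_m^T."""
    occ = spec.occupation > 0
    Cocc = spec.C[:, occ]
    return 2.0 * Cocc @ Cocc.T


def loewdin_analysis(P: np.ndarray, S: np.ndarray, index: OrbitalIndex,
                     n_valence, atomic_numbers) -> PopulationResult:
    """Loewdin partial charges and bond orders from P^L = S^1/2 P S^1/2."""
    S_half, _ = _sqrt_spd(S)
    PL = S_half @ P @ S_half
    n_atoms = len(index.atom_counts)
    charges = np.empty(n_atoms)
    bo = np.zeros((n_atoms, n_atoms))
    slices = [index.atom_slice(i) for i in range(n_atoms)]
    for i in range(n_atoms):
        charges[i] = n_valence[atomic_numbers[i]] - np.trace(PL[slices[i], slices[i]])
        for j in range(i + 1, n_atoms):
            bo[i, j] = bo[j, i] = np.sum(PL[slices[i], slices[j]] ** 2)
    return PopulationResult(charges, bo)


def multipole_moments(P: np.ndarray, S: np.ndarray, moments1: dict, moments2: dict,
                      mol: Molecule, n_valence, origin=(0.0, 0.0, 0.0)) -> Moments:
    """Dipole (Debye) and second moment (Debye*Angstrom) about ``origin``.

    Nuclear contributions use the valence charge of each atom, consistent with
    a valence-electron-only density matrix; electronic contributions are
    -sum_{mu nu} P_{mu nu} M_{nu mu} for each moment operator.
    """
    o = np.asarray(origin, float)
    q = np.array([n_valence[z] for z in mol.atomic_numbers], float)
    rel = mol.positions - o
    dip = (q[:, None] * rel).sum(axis=0)
    for c, key in enumerate(("x", "y", "z")):
        M_shift = moments1[key] - o[c] * S
        dip[c] -= np.sum(P * M_shift)
    quad = np.zeros((3, 3))
    axes = "xyz"
    for a in range(3):
        for b in range(a, 3):
            key = axes[min(a, b)] + axes[max(a, b)]
            M = (moments2[key] - o[a] * moments1[axes[b]] - o[b] * moments1[axes[a]]
                 + o[a] * o[b] * S)
            val = np.sum(q * rel[:, a] * rel[:, b]) - np.sum(P * M)
            quad[a, b] = quad[b, a] = val
    return Moments(dip * EA_TO_DEBYE, quad * EA_TO_DEBYE, o)


def traceless_quadrupole(m: Moments) -> np.ndarray:
    """Buckingham-convention traceless form 1/2 (3 Q - tr(Q) I)."""
    Q = m.quadrupole
    return 0.5 * (3.0 * Q - np.trace(Q) * np.eye(3))


def dos_curve(epsilon_frames, sigma: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian-broadened density of states averaged over frames.

    Each orbital energy contributes a unit-area Gaussian of width ``sigma``
    (eV); the result is divided by the number of frames.
    """
    if sigma <= 0:
        raise ValueError("broadening sigma must be positive")
    frames = [np.asarray(e, float).ravel() for e in epsilon_frames]
    if not frames:
        raise ValueError("no orbital-energy frames given")
    grid = np.asarray(grid, float)
    out = np.zeros_like(grid)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for eps in frames:
        out += norm * np.exp(-0.5 * ((grid[:, None] - eps[None, :]) / sigma) ** 2).sum(1)
    return out / len(frames)


def homo_lumo_gap(spec: SpectrumResult) -> float:
    """eps_LUMO - eps_HOMO (eV), >= 0 for an ascending spectrum."""
    n_occ = spec.n_electrons // 2
    if n_occ < 1:
        raise ValueError("need at least one occupied orbital")
    if n_occ >= len(spec.epsilon):
        raise ValueError("all orbitals occupied; no LUMO exists")
    return float(spec.epsilon[n_occ] - spec.epsilon[n_occ - 1])


# -- orbital-energy gradients ------------------------------------------

def _check_isolated(eps, m, threshold):
    lo = eps[m] - eps[m - 1] if m > 0 else np.inf
    hi = eps[m + 1] - eps[m] if m + 1 < len(eps) else np.inf
    if min(lo, hi) < threshold:
        raise DegeneracyError(
            f"orbital {m} separated by {min(lo, hi):.2e} eV < {threshold:.0e}; "
            "its gradient is ill-defined")


def orbital_energy_gradient(provider, mol: Molecule, m: int,
                            degeneracy_threshold: float = 1e-6) -> np.ndarray:
    """Gradient of orbital energy eps_m w.r.t. atomic positions (eV/Angstrom).

    First-order perturbation theory: d eps_m = c_m^T (dH - eps_m dS) c_m for an
    S-normalized eigenvector.  ``provider`` must implement ``matrices(mol)``;
    if it also implements ``matrices_forward`` (the neural network), dH/dr and
    dS/dr come from the autodiff graph, otherwise from central finite
    differences of the analytic matrices.
    """
    H, S = provider.matrices(mol)
    w, V = scipy.linalg.eigh(0.5 * (H + H.T), 0.5 * (S + S.T))
    _check_isolated(w, m, degeneracy_threshold)
    c = V[:, m]
    c = c / np.sqrt(c @ S @ c)
    eps_m = w[m]

    if hasattr(provider, "matrices_forward"):
        fwd = provider.matrices_forward(mol)
        C2 = ad.constant(np.outer(c, c))
        scalar = ad.tsum(fwd.H * C2) - eps_m * ad.tsum(fwd.S * C2)
        return ad.grad(scalar, [fwd.pos])[0].value

    step = 1e-4
    grad = np.zeros((mol.n_atoms, 3))
    for i in range(mol.n_atoms):
        for cc in range(3):
            acc = 0.0
            for sign in (+1, -1):
                p = mol.positions.copy()
                p[i, cc] += sign * step
                Hd, Sd = provider.matrices(mol.with_positions(p))
                acc += sign * (c @ (Hd - eps_m * Sd) @ c)
            grad[i, cc] = acc / (2.0 * step)
    return grad


def gap_gradient(provider, mol: Molecule, n_electrons: int,
                 degeneracy_threshold: float = 1e-6) -> np.ndarray:
    """Gradient of the HOMO-LUMO gap: grad eps_LUMO - grad eps_HOMO."""
    n_occ = n_electrons // 2
    g_lumo = orbital_energy_gradient(provider, mol, n_occ, degeneracy_threshold)
    g_homo = orbital_energy_gradient(provider, mol, n_occ - 1, degeneracy_threshold)
    return g_lumo - g_homo
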