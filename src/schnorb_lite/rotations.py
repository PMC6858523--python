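"""Proper rotations, real Wigner-D matrices (l <= 3) and record rotation.

Rotating a molecule rotates positions and forces by R while every shell-pair
block of the Hamiltonian and overlap matrices transforms as

    M_block  ->  D^(l_mu)  M_block  D^(l_nu)^T

with D^(l) the real Wigner rotation matrix.  The transpose on the right factor
is fixed by requiring that the analytic overlap of a rotated geometry equal
the rotated overlap of the original geometry (checked in the test suite).

D^(l) for l >= 2 is built by the Ivanic-Ruedenberg recursion directly in the
real-harmonic basis, avoiding complex arithmetic and phase conventions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .chem import ElectronicRecord, OrbitalIndex

MAX_L = 3


@dataclasses.dataclass
class Rotor:
    """A proper rotation of 3-space."""

    R: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=1e-12):
            raise ValueError("matrix is not orthogonal")
        if not np.isclose(np.linalg.det(self.R), 1.0, atol=1e-12):
            raise ValueError("matrix is not a proper rotation (det != +1)")

    def compose(self, other: "Rotor") -> "Rotor":
        """Rotation applying ``other`` first, then ``self``."""
        return Rotor(self.R @ other.R)


def random_rotation(seed) -> Rotor:
    """Haar-uniform rotation from a normalized Gaussian quaternion draw."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return Rotor(R)


def _d1(rot: Rotor) -> np.ndarray:
    """D^(1) in real-harmonic ordering m = -1, 0, 1  <->  (y, z, x)."""
    perm = (1, 2, 0)
    R = rot.R
    return np.array([[R[perm[a], perm[b]] for b in range(3)] for a in range(3)])


def _ir_step(prev: np.ndarray, r: np.ndarray, l: int) -> np.ndarray:
    """One Ivanic-Ruedenberg recursion step: D^(l) from D^(l-1) and D^(1)."""

    def R1(i, m):                      # D^(1) element, indices in -1..1
        return r[i + 1, m + 1]

    def Dprev(a, b):                   # D^(l-1) element, indices in -(l-1)..(l-1)
        return prev[a + l - 1, b + l - 1]

    def P(i, a, b):
        if b == l:
            return R1(i, 1) * Dprev(a, l - 1) - R1(i, -1) * Dprev(a, -l + 1)
        if b == -l:
            return R1(i, 1) * Dprev(a, -l + 1) + R1(i, -1) * Dprev(a, l - 1)
        return R1(i, 0) * Dprev(a, b)

    D = np.empty((2 * l + 1, 2 * l + 1))
    for m in range(-l, l + 1):
        for n in range(-l, l + 1):
            denom = (l + n) * (l - n) if abs(n) < l else (2 * l) * (2 * l - 1)
            u = np.sqrt((l + m) * (l - m) / denom)
            v = 0.5 * np.sqrt((1 + (m == 0)) * (l + abs(m) - 1) * (l + abs(m)) / denom) \
                * (1 - 2 * (m == 0))
            w = -0.5 * np.sqrt(max((l - abs(m) - 1) * (l - abs(m)), 0) / denom) * (1 - (m == 0))
            val = 0.0
            if u != 0.0:
                val += u * P(0, m, n)
            if v != 0.0:
                if m == 0:
                    V = P(1, 1, n) + P(-1, -1, n)
                elif m > 0:
                    V = P(1, m - 1, n) * np.sqrt(1 + (m == 1)) \
                        - P(-1, -m + 1, n) * (1 - (m == 1))
                else:
                    V = P(1, m + 1, n) * (1 - (m == -1)) \
                        + P(-1, -m - 1, n) * np.sqrt(1 + (m == -1))
                val += v * V
            if w != 0.0:
                W = (P(1, m + 1, n) + P(-1, -m - 1, n)) if m > 0 else \
                    (P(1, m - 1, n) - P(-1, -m + 1, n))
                val += w * W
            D[m + l, n + l] = val
    return D


def wigner_d_real(l: int, rot: Rotor) -> np.ndarray:
    """Real Wigner matrix D^(l)(R): S_lm(R r) = sum_m' D_{m m'} S_lm'(r)."""
    if not 0 <= l <= MAX_L:
        raise ValueError(f"angular momentum {l} unsupported (0..{MAX_L})")
    if l == 0:
        return np.ones((1, 1))
    D = _d1(rot)
    for ll in range(2, l + 1):
        D = _ir_step(D, _d1(rot), ll)
    return D


def wigner_blocks(rot: Rotor, lmax: int = MAX_L) -> dict:
    return {l: wigner_d_real(l, rot) for l in range(lmax + 1)}


def _full_transform(index: OrbitalIndex, rot: Rotor) -> np.ndarray:
    """Block-diagonal matrix of D^(l) blocks, one per shell, in orbital order."""
    blocks = {}
    n = index.n_orbitals
    D = np.zeros((n, n))
    k = 0
    while k < n:
        _, _, l, m = index.orbital_labels[k]
        assert m == -l, "orbital labels are not shell-contiguous"
        if l not in blocks:
            blocks[l] = wigner_d_real(l, rot)
        D[k:k + 2 * l + 1, k:k + 2 * l + 1] = blocks[l]
        k += 2 * l + 1
    return D


def rotate_record(rec: ElectronicRecord, rot: Rotor, index: OrbitalIndex) -> ElectronicRecord:
    """Rotate geometry, forces and the H/S matrix blocks consistently; E unchanged."""
    if index.n_orbitals != rec.H.shape[0]:
        raise ValueError("orbital index does not match the record's matrix dimension")
    D = _full_transform(index, rot)
    mol = rec.molecule.with_positions(rec.molecule.positions @ rot.R.T)
    return ElectronicRecord(
        molecule=mol,
        H=D @ rec.H @ D.T,
        S=D @ rec.S @ D.T,
        E=rec.E,
        F=rec.F @ rot.R.T,
        n_electrons=rec.n_electrons,
    )
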