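"""Analytic overlap and multipole-moment integrals over contracted Gaussians.

One-electron integrals are assembled from 1-D Obara-Saika recurrences over
Cartesian primitives, transformed shell-pair-wise to real solid harmonics, and
finally renormalized so every contracted atomic orbital has unit self-overlap
(diag(S) = 1 exactly).  Moment integrals use the same normalization, so all
matrices refer to one consistent AO basis.

Geometry enters in Angstrom and is converted to Bohr internally (exponents are
in Bohr^-2); moment integrals are returned in Angstrom^order.
"""

from __future__ import annotations

import warnings
from functools import lru_cache
from math import comb

import numpy as np

from .chem import BOHR_ANGSTROM, BasisSet, Molecule, build_orbital_index
from .harmonics import cart_monomials, cart_to_spherical


class ConditioningWarning(UserWarning):
    """Overlap matrix close to linear dependence."""


_MOMENT_KEYS = {1: ("x", "y", "z"), 2: ("xx", "xy", "xz", "yy", "yz", "zz")}
_MOMENT_POWERS = {
    "x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1),
    "xx": (2, 0, 0), "xy": (1, 1, 0), "xz": (1, 0, 1),
    "yy": (0, 2, 0), "yz": (0, 1, 1), "zz": (0, 0, 2),
}


def _dfact(n: int) -> int:
    out = 1
    while n > 1:
        out, n = out * n, n - 2
    return out


def _prim_norm(alpha: np.ndarray, l: int) -> np.ndarray:
    """Self-normalization of a solid-harmonic primitive of angular momentum l."""
    return np.sqrt((2 * alpha / np.pi) ** 1.5 * (4 * alpha) ** l / _dfact(2 * l - 1))


def _os_table(na: int, nb: int, PA, PB, oo2p):
    """1-D overlap recurrence S[i, j] (i <= na, j <= nb) per primitive pair."""
    S = np.zeros((na + 1, nb + 1) + PA.shape)
    S[0, 0] = 1.0
    for i in range(na):
        S[i + 1, 0] = PA * S[i, 0] + (i * oo2p * S[i - 1, 0] if i else 0.0)
    for j in range(nb):
        for i in range(na + 1):
            S[i, j + 1] = PB * S[i, j] + (j * oo2p * S[i, j - 1] if j else 0.0)
            if i:
                S[i, j + 1] += i * oo2p * S[i - 1, j]
    return S


@lru_cache(maxsize=None)
def _mono_idx(l: int):
    return np.array(cart_monomials(l), dtype=int)


def _shell_static(shell):
    """Cached per-shell static data: normalized contraction weights."""
    cn = getattr(shell, "_cn", None)
    if cn is None:
        cn = shell.coefficients * _prim_norm(shell.exponents, shell.l)
        object.__setattr__(shell, "_cn", cn)
    return cn


def _shell_pair_blocks(shell_a, shell_b, A, B, powers_list):
    """Contracted Cartesian blocks <a| x^e y^f z^g |b> for each power triple.

    A, B in Bohr; returns one (ncart_a, ncart_b) array per entry of powers_list.
    """
    la, lb = shell_a.l, shell_b.l
    al = shell_a.exponents[:, None]
    be = shell_b.exponents[None, :]
    p = (al + be).ravel()
    mu = (al * be / (al + be)).ravel()
    w = (_shell_static(shell_a)[:, None] * _shell_static(shell_b)[None, :]).ravel()
    AB = A - B
    P = ((al[..., None] * A + be[..., None] * B) / (al + be)[..., None]).reshape(-1, 3)
    pref = w * (np.pi / p) ** 1.5 * np.exp(-mu * (AB @ AB))
    oo2p = 0.5 / p
    maxpow = max(max(e, f, g) for (e, f, g) in powers_list)
    # one recurrence for all three dimensions at once: tables (ia, ib, 3, npair)
    tabs = _os_table(la + maxpow, lb, (P - A).T, (P - B).T, oo2p)
    ia, ib = _mono_idx(la), _mono_idx(lb)
    out = []
    for (e, f, g) in powers_list:
        block = np.zeros((len(ia), len(ib)))
        for kx in range(e + 1):
            for ky in range(f + 1):
                for kz in range(g + 1):
                    c = (comb(e, kx) * comb(f, ky) * comb(g, kz)
                         * A[0] ** (e - kx) * A[1] ** (f - ky) * A[2] ** (g - kz))
                    if c == 0.0:
                        continue
                    sx = tabs[ia[:, 0, None] + kx, ib[None, :, 0], 0]
                    sy = tabs[ia[:, 1, None] + ky, ib[None, :, 1], 1]
                    sz = tabs[ia[:, 2, None] + kz, ib[None, :, 2], 2]
                    block += c * ((sx * sy * sz) @ pref)
        out.append(block)
    return out


def _assemble(mol: Molecule, basis: BasisSet, powers_list):
    """Raw (unnormalized) spherical-AO matrices for each operator power triple."""
    index = build_orbital_index(mol, basis)
    n = index.n_orbitals
    mats = [np.zeros((n, n)) for _ in powers_list]
    pos_bohr = mol.positions / BOHR_ANGSTROM
    shells = []                     # (global offset, atom, shell)
    off = 0
    for i, z in enumerate(mol.atomic_numbers):
        for shell in basis.shells_for(z):
            shells.append((off, i, shell))
            off += shell.n_orbitals
    for a, (offa, ia, sa) in enumerate(shells):
        Ta = cart_to_spherical(sa.l)
        for b, (offb, ib, sb) in enumerate(shells):
            if b < a:
                continue
            blocks = _shell_pair_blocks(sa, sb, pos_bohr[ia], pos_bohr[ib], powers_list)
            Tb = cart_to_spherical(sb.l)
            for mat, blk in zip(mats, blocks):
                sph = Ta @ blk @ Tb.T
                mat[offa:offa + sa.n_orbitals, offb:offb + sb.n_orbitals] = sph
                if b != a:
                    mat[offb:offb + sb.n_orbitals, offa:offa + sa.n_orbitals] = sph.T
    return mats


def overlap_and_moments(mol: Molecule, basis: BasisSet, orders=()):
    """Normalized overlap matrix plus moment matrices for the requested orders."""
    keys = [k for order in orders for k in _MOMENT_KEYS[order]]
    powers = [(0, 0, 0)] + [_MOMENT_POWERS[k] for k in keys]
    mats = _assemble(mol, basis, powers)
    S_raw = mats[0]
    d = 1.0 / np.sqrt(np.diag(S_raw))
    S = d[:, None] * S_raw * d[None, :]
    S = 0.5 * (S + S.T)
    moments = {}
    for k, raw in zip(keys, mats[1:]):
        m = d[:, None] * raw * d[None, :]
        moments[k] = 0.5 * (m + m.T) * BOHR_ANGSTROM ** len(k)
    return S, moments


def overlap_matrix(mol: Molecule, basis: BasisSet) -> np.ndarray:
    """Overlap S_{mu nu} = <phi_mu | phi_nu> with unit diagonal."""
    S, _ = overlap_and_moments(mol, basis)
    if np.linalg.eigvalsh(S)[0] < 1e-8:
        warnings.warn("overlap matrix is nearly linearly dependent",
                      ConditioningWarning, stacklevel=2)
    return S


def moment_integrals(mol: Molecule, basis: BasisSet, order: int) -> dict:
    """Multipole matrices <phi_mu| x^e y^f z^g |phi_nu> (origin at 0, Angstrom^order)."""
    if order not in (1, 2):
        raise ValueError("moment order must be 1 or 2")
    _, moments = overlap_and_moments(mol, basis, orders=(order,))
    return moments


# -- numerical quadrature reference ------------------------------------

def ao_values_on_grid(mol: Molecule, basis: BasisSet, pts_bohr: np.ndarray) -> np.ndarray:
    """Unnormalized spherical AO values at the given points (Bohr); (n_ao, N)."""
    vals = []
    for zi, A in zip(mol.atomic_numbers, mol.positions / BOHR_ANGSTROM):
        for sh in basis.shells_for(zi):
            T = cart_to_spherical(sh.l)
            d = pts_bohr - A
            monos = np.stack([d[:, 0] ** i * d[:, 1] ** j * d[:, 2] ** k
                              for (i, j, k) in cart_monomials(sh.l)])
            r2 = np.einsum("ij,ij->i", d, d)
            rad = sum(c * _prim_norm(np.array([a]), sh.l)[0] * np.exp(-a * r2)
                      for a, c in zip(sh.exponents, sh.coefficients))
            vals.append(T @ (monos * rad))
    return np.concatenate(vals, axis=0)


def matrices_by_quadrature(mol: Molecule, basis: BasisSet, orders=(),
                           n_points: int = 120, padding: float = 8.0):
    """Brute-force tensor-grid quadrature reference for overlap and moments.

    Independent of the analytic recursion path: AOs are evaluated pointwise on
    a uniform grid enclosing the molecule and integrated by the midpoint rule
    (superalgebraically accurate for Gaussians).  Intended for tests and
    self-checks on small systems only.
    """
    pos = mol.positions / BOHR_ANGSTROM
    lo, hi = pos.min() - padding, pos.max() + padding
    g = np.linspace(lo, hi, n_points)
    w = (g[1] - g[0]) ** 3
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    V = ao_values_on_grid(mol, basis, pts)
    V /= np.sqrt((V * V).sum(axis=1) * w)[:, None]     # normalize contracted AOs
    S = (V * w) @ V.T
    moments = {}
    for order in orders:
        for key in _MOMENT_KEYS[order]:
            p = _MOMENT_POWERS[key]
            f = pts[:, 0] ** p[0] * pts[:, 1] ** p[1] * pts[:, 2] ** p[2]
            moments[key] = (V * (w * f)) @ V.T * BOHR_ANGSTROM ** order
    return S, moments
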