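"""Real spherical/solid harmonics and Cartesian-to-spherical transforms.

The package uses real spherical harmonics without the Condon-Shortley phase,
with magnetic index ordering m = -l ... +l.  For p functions this is the
(y, z, x) ordering.  The Cartesian-to-spherical coefficient matrices are
obtained by exact least-squares projection of the degree-l monomial basis onto
sampled solid harmonics: a solid harmonic of degree l is a polynomial of
degree l, so the fit is exact to rounding error and no hand-typed coefficient
table is needed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y


def real_sph_harm(l: int, m: int, points: np.ndarray) -> np.ndarray:
    """Real spherical harmonic S_lm (orthonormal on the sphere, no CS phase)
    evaluated at Cartesian ``points`` (..., 3), interpreted as directions."""
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(pts[..., 2] / np.where(r == 0, 1.0, r), -1, 1))
    phi = np.arctan2(pts[..., 1], pts[..., 0])
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return y.real
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * y.real
    return np.sqrt(2.0) * (-1.0) ** m * y.imag


def real_solid_harm(l: int, m: int, points: np.ndarray) -> np.ndarray:
    """Solid harmonic r^l S_lm(theta, phi) at Cartesian ``points``."""
    pts = np.asarray(points, dtype=float)
    if l == 0:
        return np.full(pts.shape[:-1], 0.5 / np.sqrt(np.pi))
    r = np.linalg.norm(pts, axis=-1)
    return r ** l * real_sph_harm(l, m, pts)


@lru_cache(maxsize=None)
def cart_monomials(l: int):
    """Canonical ordering of Cartesian exponent triples with i + j + k = l."""
    return tuple((i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1))


@lru_cache(maxsize=None)
def cart_to_spherical(l: int) -> np.ndarray:
    """Matrix T with solid_harm_lm = sum_c T[m, c] * monomial_c, rows m = -l..l."""
    monos = cart_monomials(l)
    rng = np.random.default_rng(2 ** l)            # any fixed points work
    pts = rng.normal(size=(max(4 * len(monos), 32), 3))
    A = np.stack([pts[:, 0] ** i * pts[:, 1] ** j * pts[:, 2] ** k
                  for (i, j, k) in monos], axis=1)
    T = np.empty((2 * l + 1, len(monos)))
    for row, m in enumerate(range(-l, l + 1)):
        b = real_solid_harm(l, m, pts)
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        coef[np.abs(coef) < 1e-12] = 0.0
        T[row] = coef
    return T
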