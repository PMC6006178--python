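"""Real spherical harmonics, quadrature, and real Wigner-D rotations.

The 3D scattering intensity of a real electron density is real and
Friedel-symmetric, I(k) = I(-k), so its shell-wise expansion only contains
even orders l.  Throughout the package the intensity is stored in the real,
orthonormal spherical-harmonic basis without the Condon-Shortley phase:

    R_{l0}          = Y_l^0
    R_{lm}  (m > 0) = sqrt(2) (-1)^m Re Y_l^m
    R_{l,-m}(m > 0) = sqrt(2) (-1)^m Im Y_l^m

where Y_l^m are the complex orthonormal harmonics (scipy convention,
including Condon-Shortley).  In this basis rotations act by real orthogonal
block matrices D_l, which is what makes the per-order rotation search of the
three-photon inversion well-posed.

Packed coefficient layout for even-only expansions up to order L:
blocks l = 0, 2, ..., L, within each block m = -l ... l.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import special as _sp

__all__ = [
    "even_orders",
    "n_even_coeffs",
    "packed_slice",
    "real_sh_mode",
    "real_sh_block",
    "real_sh_matrix",
    "sh_synthesis",
    "real_to_complex_matrix",
    "sphere_quadrature",
    "real_wigner_d",
    "rotate_even_coeffs",
    "vectors_to_angles",
    "angles_to_vectors",
]

_SQRT2 = np.sqrt(2.0)


def even_orders(L: int) -> list[int]:
    """Even orders 0, 2, ..., L."""
    if L < 0 or L % 2:
        raise ValueError(f"expansion order must be even and >= 0, got {L}")
    return list(range(0, L + 1, 2))


def n_even_coeffs(L: int) -> int:
    """Number of real coefficients of an even-only expansion, (L^2+3L+2)/2."""
    return sum(2 * l + 1 for l in even_orders(L))


@lru_cache(maxsize=None)
def packed_offset(l: int) -> int:
    """Start index of order ``l`` in the even-packed coefficient vector."""
    if l % 2:
        raise ValueError("even orders only")
    return sum(2 * q + 1 for q in range(0, l, 2))


@lru_cache(maxsize=None)
def packed_slice(l: int) -> slice:
    """Slice of the even-packed coefficient vector holding order ``l``."""
    if l % 2:
        raise ValueError("even orders only")
    start = sum(2 * q + 1 for q in range(0, l, 2))
    return slice(start, start + 2 * l + 1)


def real_sh_mode(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Evaluate one real spherical harmonic R_{lm}(theta, phi).

    Memory-light building block: O(npts), no (l, m) tables are materialized.
    """
    am = abs(m)
    theta = np.asarray(theta, dtype=float)
    # scipy: sph_harm_y(l, m, theta, phi) = sph_legendre_p(l, m, theta) e^{i m phi}
    # (sph_legendre_p may prepend degree/order axes; squeeze them away)
    p = np.asarray(_sp.sph_legendre_p(l, am, theta)).reshape(theta.shape)
    if m == 0:
        return p
    sign = -1.0 if am % 2 else 1.0
    if m > 0:
        return _SQRT2 * sign * p * np.cos(am * np.asarray(phi, dtype=float))
    return _SQRT2 * sign * p * np.sin(am * np.asarray(phi, dtype=float))


def real_sh_block(l: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """All R_{lm} for one order; shape (2l+1, npts), m = -l..l."""
    theta = np.asarray(theta, dtype=float)
    out = np.empty((2 * l + 1, theta.size), dtype=float)
    for m in range(-l, l + 1):
        out[m + l] = real_sh_mode(l, m, theta.ravel(), np.asarray(phi, dtype=float).ravel())
    return out


def real_sh_matrix(L: int, theta, phi, even_only: bool = True) -> np.ndarray:
    """Design matrix of real harmonics, shape (ncoef, npts).

    With ``even_only`` the rows follow the packed even layout; otherwise all
    orders 0..L are included (used by quadrature and Wigner-D construction).
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).ravel()
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).ravel()
    orders = even_orders(L) if even_only else list(range(L + 1))
    rows = [real_sh_block(l, theta, phi) for l in orders]
    return np.concatenate(rows, axis=0)


def sh_synthesis(coeffs: np.ndarray, L: int, theta, phi) -> np.ndarray:
    """Evaluate sum_lm c_lm R_lm at the given angles (even-packed coeffs)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != n_even_coeffs(L):
        raise ValueError("coefficient length does not match order L")
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).ravel()
    phi = np.atleast_1d(np.asarray(phi, dtype=float)).ravel()
    out = np.zeros(theta.shape, dtype=float)
    for l in even_orders(L):
        sl = packed_slice(l)
        block = coeffs[..., sl]
        for m in range(-l, l + 1):
            out += block[..., m + l] * real_sh_mode(l, m, theta, phi)
    return out


@lru_cache(maxsize=None)
def real_to_complex_matrix(l: int) -> np.ndarray:
    """Unitary T_l with a_l = T_l c_l mapping real coefficients (m=-l..l) to
    complex ones such that sum_m a_lm Y_l^m = sum_m c_lm R_lm."""
    n = 2 * l + 1
    T = np.zeros((n, n), dtype=complex)
    T[l, l] = 1.0
    for m in range(1, l + 1):
        s = (-1.0) ** m
        # row for +m, row for -m; columns: c_{+m} at l+m, c_{-m} at l-m
        T[l + m, l + m] = s / _SQRT2
        T[l + m, l - m] = -1j * s / _SQRT2
        T[l - m, l + m] = 1.0 / _SQRT2
        T[l - m, l - m] = 1j / _SQRT2
    return T


def sphere_quadrature(n_theta: int, n_phi: int):
    """Gauss-Legendre x uniform-azimuth product grid.

    Returns (theta, phi, weights) flattened; exact for integrands that are
    band-limited at degree 2*n_theta - 1 in theta and below n_phi in the
    azimuthal harmonics.  Weights sum to 4*pi.
    """
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    w = np.repeat(wx, n_phi) * (2.0 * np.pi / n_phi)
    return th.ravel(), ph.ravel(), w


@lru_cache(maxsize=None)
def _quad_cache(l: int):
    th, ph, w = sphere_quadrature(l + 1, 2 * l + 1)
    Y = real_sh_block(l, th, ph)
    pts = angles_to_vectors(th, ph)
    return Y * w, pts  # (2l+1, npts) weighted, (npts, 3)


def real_wigner_d(l: int, rotation: np.ndarray) -> np.ndarray:
    """Real Wigner-D matrix of order l for a 3x3 proper rotation.

    D[m', m] = integral R_{lm'}(x) R_{lm}(R^{-1} x) dOmega, computed by exact
    spherical quadrature; orthogonal with det +1 for even l.  Coefficients of
    a function rotated by R (f -> f(R^{-1} x)) transform as c' = D c.
    """
    R = np.asarray(rotation, dtype=float)
    Yw, pts = _quad_cache(l)
    back = pts @ R  # row-vectors: R^{-1} x = R^T x
    th, ph = vectors_to_angles(back)
    Yrot = real_sh_block(l, th, ph)
    return Yw @ Yrot.T


def real_wigner_d_batch(l: int, rotations: np.ndarray) -> np.ndarray:
    """Real Wigner-D matrices for a stack of rotations, shape (n, 2l+1, 2l+1).

    Same construction as `real_wigner_d` but with one batched spherical-
    harmonic evaluation, which is what makes grid searches over SO(3)
    affordable.
    """
    Rs = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
    Yw, pts = _quad_cache(l)
    # back[n, p, :] = pts[p] @ Rs[n]  (i.e. R^{-1} x for row vectors)
    back = np.einsum("pj,nji->npi", pts, Rs)
    th, ph = vectors_to_angles(back.reshape(-1, 3))
    Yrot = real_sh_block(l, th, ph).reshape(2 * l + 1, Rs.shape[0], pts.shape[0])
    return np.einsum("mp,qnp->nmq", Yw, Yrot)


def rotate_even_coeffs(coeffs: np.ndarray, L: int, rotation: np.ndarray) -> np.ndarray:
    """Apply the block-diagonal real Wigner-D rotation to even-packed
    coefficients (last axis = coefficient axis or first? -- coefficient axis
    must be axis 0; trailing axes, e.g. shells, are carried along)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[0] != n_even_coeffs(L):
        raise ValueError("coefficient axis does not match order L")
    out = np.empty_like(coeffs)
    for l in even_orders(L):
        sl = packed_slice(l)
        D = real_wigner_d(l, rotation)
        out[sl] = np.tensordot(D, coeffs[sl], axes=(1, 0))
    return out


def fast_even_synthesis(L: int, theta: np.ndarray, phi: np.ndarray, coef) -> np.ndarray:
    """Accumulate sum_{even l <= L, m} c_lm(pt) R_lm(pt) without mode tables.

    ``coef(l, m)`` must return the per-point coefficient array (or a scalar).
    Uses the standard stable recursion for the fully normalized associated
    Legendre functions (Condon-Shortley-free), so memory stays O(npts)
    regardless of L -- this is the photon-simulator hot path.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    ct, st = np.cos(theta), np.sin(theta)
    acc = np.zeros(theta.shape)
    qmm = np.full(theta.shape, 1.0 / np.sqrt(4.0 * np.pi))  # Q_00
    for m in range(L + 1):
        if m > 0:
            qmm = qmm * st * np.sqrt((2.0 * m + 1.0) / (2.0 * m))
        if m == 0:
            cosm = 1.0
            sinm = 0.0
        else:
            cosm = np.cos(m * phi)
            sinm = np.sin(m * phi)
        qprev = qmm
        qprev2 = None
        for l in range(m, L + 1):
            if l == m:
                q = qmm
            elif l == m + 1:
                q = np.sqrt(2.0 * m + 3.0) * ct * qmm
            else:
                a = np.sqrt((4.0 * l * l - 1.0) / (l * l - m * m))
                b = np.sqrt(((l - 1.0) ** 2 - m * m) / (4.0 * (l - 1.0) ** 2 - 1.0))
                q = a * (ct * qprev - b * qprev2)
            qprev2, qprev = qprev, q
            if l % 2 == 0:
                if m == 0:
                    acc += coef(l, 0) * q
                else:
                    acc += _SQRT2 * q * (coef(l, m) * cosm + coef(l, -m) * sinm)
    return acc


def vectors_to_angles(v: np.ndarray):
    """Cartesian (n,3) -> (theta, phi) with theta the polar angle from +z."""
    v = np.asarray(v, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    r = np.where(r == 0.0, 1.0, r)
    theta = np.arccos(np.clip(v[..., 2] / r, -1.0, 1.0))
    phi = np.mod(np.arctan2(v[..., 1], v[..., 0]), 2.0 * np.pi)
    return theta, phi


def angles_to_vectors(theta, phi) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)
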