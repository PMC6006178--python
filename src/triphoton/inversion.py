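"""Kam inversion of the two-photon correlation.

The two-photon correlation of a shell model is a Legendre series in the
Ewald-corrected angle alpha*, with per-order coefficients

    C_l(k1, k2) = sum_m A_lm(k1) A_lm(k2),

the Gram matrices of the coefficient vectors across shells.  Eigen-
decomposing each K x K matrix C_l (positive semidefinite, rank <= 2l+1)
yields coefficient vectors A0_l(k) that reproduce the two-photon data but
are determined only up to an orthogonal rotation U_l per order:
A_l(k) = U_l A0_l(k).  Searching over the rotations {U_l} instead of the raw
coefficients shrinks the unknown count from K (L^2+3L+2)/2 (4940 at L=18,
K=26) to sum_l l(2l+1) = (L^3 + 15/4 L^2 + 7/2 L)/3 rotation angles (2370
at L=18).
"""

from __future__ import annotations

import dataclasses
import logging

import h5py
import numpy as np
from scipy import special as _sp

from . import sphharm
from .correlate import DoubletHistogram, ewald_alpha_star
from .intensity import ShellGrid, ShellIntensityModel

__all__ = [
    "OrderCorrelationMatrix",
    "EigenBasis",
    "analytic_order_matrices",
    "legendre_project",
    "invert_two_point",
    "count_rotation_parameters",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class OrderCorrelationMatrix:
    """Per-order K x K two-photon matrices C_l, keyed by even l."""

    grid: ShellGrid
    L: int
    matrices: dict[int, np.ndarray]

    def __post_init__(self):
        for l, C in self.matrices.items():
            if C.shape != (self.grid.K, self.grid.K):
                raise ValueError(f"C_{l} has wrong shape {C.shape}")


@dataclasses.dataclass
class EigenBasis:
    """Unaligned coefficient vectors A0_l(k), shape (2l+1, K) per even l.

    The Gram matrix A0_l^T A0_l (over the m-axis) equals C_l; the physical
    coefficients are A_l = U_l A0_l for unknown orthogonal U_l.
    """

    grid: ShellGrid
    L: int
    blocks: dict[int, np.ndarray]
    wavelength: float | None = None

    def __post_init__(self):
        for l, b in self.blocks.items():
            if b.shape != (2 * l + 1, self.grid.K):
                raise ValueError(f"A0_{l} has wrong shape {b.shape}")

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("radii", data=self.grid.radii)
            f.attrs["L"] = self.L
            if self.wavelength is not None:
                f.attrs["wavelength"] = self.wavelength
            for l, b in self.blocks.items():
                f.create_dataset(f"A0_{l}", data=b)

    @classmethod
    def load(cls, path) -> "EigenBasis":
        with h5py.File(path, "r") as f:
            grid = ShellGrid(f["radii"][...])
            L = int(f.attrs["L"])
            wl = f.attrs.get("wavelength")
            blocks = {l: f[f"A0_{l}"][...] for l in range(0, L + 1, 2)}
            return cls(grid, L, blocks, None if wl is None else float(wl))


def analytic_order_matrices(model: ShellIntensityModel) -> OrderCorrelationMatrix:
    """C_l directly from a model's coefficients (forward reference path)."""
    mats = {l: model.block(l).T @ model.block(l)
            for l in sphharm.even_orders(model.L)}
    return OrderCorrelationMatrix(model.grid, model.L, mats)


def count_rotation_parameters(L: int) -> int:
    """Annealing search-space size: sum over even l in 2..L of dim SO(2l+1)
    = l(2l+1); equals (L^3 + 15/4 L^2 + 7/2 L)/3 -- 2370 for L = 18."""
    if L < 0 or L % 2:
        raise ValueError("need even L >= 0")
    return sum(l * (2 * l + 1) for l in range(2, L + 1, 2))


def _doublet_c_estimate(hist: DoubletHistogram):
    """Empirical two-photon correlation values at bin centers.

    Returns (c_hat (K, K, n_alpha) symmetric in the shell axes, weights)
    where c_hat is proportional to the underlying correlation (unknown
    global scale) and weights ~ inverse variance (counts).
    """
    b = hist.binning
    measure = b.doublet_bin_measure()
    c = hist.counts / measure
    w = np.maximum(hist.counts, 1.0)
    # mirror to full (s1, s2) symmetry
    c = c + np.transpose(c, (1, 0, 2))
    w = w + np.transpose(w, (1, 0, 2))
    d = np.arange(b.grid.K)
    c[d, d] /= 2.0
    w[d, d] /= 2.0
    return c, w


def legendre_project(data, geometry_wavelength: float | None = None,
                     L: int | None = None,
                     n_nodes: int = 64,
                     deconvolve_radial: bool = True) -> OrderCorrelationMatrix:
    """Project two-photon correlations onto per-order matrices C_l.

    ``data`` is either a DoubletHistogram (empirical path) or a
    ShellIntensityModel (analytic path; equivalent to `analytic_order_matrices`
    but exercised through the same continuous-angle projection).

    The detector angle alpha is first mapped to the Ewald-corrected alpha*;
    cos(alpha*) only covers [cos(th1+th2), cos(th1-th2)], so the even-l
    Legendre coefficients are recovered by least squares of the sampled
    correlation against P_l(cos alpha*) on the accessible interval -- exact
    for band-limited input, increasingly ill-conditioned for large L on
    short intervals (an error is raised if the fit is unusable).

    Binned doublets estimate radial profiles averaged over each shell's
    capture annulus; with ``deconvolve_radial`` the averaging matrix of the
    shell grid is inverted so the recovered C_l refer to shell-point values,
    matching the analytic path (mild noise amplification, cond(M) ~ few).
    """
    from .correlate import analytic_two_point  # cycle guard

    if isinstance(data, ShellIntensityModel):
        model = data
        wl = geometry_wavelength or model.wavelength
        grid, Lmax = model.grid, (L or model.L)
        alphas = np.linspace(0.0, np.pi, max(4 * Lmax + 8, n_nodes))
        get = lambda s1, s2: (analytic_two_point(
            model, grid.radii[s1], grid.radii[s2], alphas, wavelength=wl),
            np.ones_like(alphas))
    elif isinstance(data, DoubletHistogram):
        wl = geometry_wavelength or data.binning.wavelength
        grid = data.binning.grid
        if L is None:
            raise ValueError("L required for the empirical path")
        Lmax = L
        alphas = data.binning.alpha_centers_half
        c_hat, w_hat = _doublet_c_estimate(data)
        get = lambda s1, s2: (c_hat[s1, s2], w_hat[s1, s2])
    else:
        raise TypeError("data must be a DoubletHistogram or ShellIntensityModel")
    if wl is None:
        raise ValueError("wavelength required")
    if Lmax % 2:
        raise ValueError("L must be even")
    if alphas.size < Lmax // 2 + 2:
        raise ValueError("too few angle samples for the Legendre projection")

    K = grid.K
    evens = sphharm.even_orders(Lmax)
    mats = {l: np.zeros((K, K)) for l in evens}
    for s1 in range(K):
        for s2 in range(s1, K):
            astar = ewald_alpha_star(grid.radii[s1], grid.radii[s2], alphas, wl)
            x = np.cos(astar)
            design = np.stack([_sp.eval_legendre(l, x) for l in evens], axis=1)
            vals, w = get(s1, s2)
            sw = np.sqrt(w)
            A = design * sw[:, None]
            cond = np.linalg.cond(A)
            if cond > 1e8:
                raise ValueError(
                    f"Legendre projection ill-conditioned (cond={cond:.2g}) "
                    f"for shells ({s1},{s2}); use more angle bins or lower L")
            sol, *_ = np.linalg.lstsq(A, np.asarray(vals) * sw, rcond=None)
            for i, l in enumerate(evens):
                mats[l][s1, s2] = mats[l][s2, s1] = 4.0 * np.pi * sol[i]
    if isinstance(data, DoubletHistogram) and deconvolve_radial:
        Minv = np.linalg.inv(grid.radial_average_matrix())
        mats = {l: Minv @ C @ Minv.T for l, C in mats.items()}
    return OrderCorrelationMatrix(grid, Lmax, mats)


def invert_two_point(C: OrderCorrelationMatrix, tol: float = 1e-9) -> EigenBasis:
    """Eigendecompose each C_l into unaligned coefficient vectors A0_l.

    A0_l rows are sqrt(lambda_i) v_i^T for the top min(2l+1, K) eigenpairs
    (remaining rows zero); eigenvector signs are fixed by making the first
    component of largest magnitude positive, and the l = 0 profile is taken
    nonnegative.  Small negative eigenvalues (truncation/statistical noise)
    are clamped to zero with a warning when they exceed tol x trace.
    """
    blocks = {}
    for l in sphharm.even_orders(C.L):
        M = 0.5 * (C.matrices[l] + C.matrices[l].T)
        vals, vecs = np.linalg.eigh(M)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        trace = max(vals.sum(), 0.0)
        if vals.min() < -tol * max(trace, 1e-300):
            log.warning("C_%d has negative eigenvalue %.3g (trace %.3g); clamping",
                        l, vals.min(), trace)
        vals = np.clip(vals, 0.0, None)
        r = min(2 * l + 1, C.grid.K)
        rank = int((vals[:r] > tol * max(trace, 1e-300)).sum())
        if l == 0:
            # C_0 is rank one with nonnegative profile A_00(k) (isotropic
            # intensity average); top eigenpair, oriented nonnegative.
            v = vecs[:, 0]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            if (v < -1e-8).any():
                log.warning("l=0 profile has negative entries; noisy input?")
            blocks[0] = (np.sqrt(vals[0]) * v)[None, :]
            continue
        A0 = np.zeros((2 * l + 1, C.grid.K))
        for i in range(r):
            v = vecs[:, i]
            j = np.argmax(np.abs(v))
            if v[j] < 0:
                v = -v
            A0[i] = np.sqrt(vals[i]) * v
        if rank > 2 * l + 1:
            log.warning("C_%d rank %d exceeds 2l+1 = %d", l, rank, 2 * l + 1)
        blocks[l] = A0
    return EigenBasis(C.grid, C.L, blocks)
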