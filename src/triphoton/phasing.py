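"""Iterative phase retrieval: shell model -> Fourier grid -> real density.

Because single-molecule intensities are continuous in reciprocal space, the
measured modulus can be oversampled and the phases recovered with standard
projection algorithms.  Here the recovered shell model is evaluated on a
cubic Fourier grid and phased with relaxed averaged alternating reflections
(RAAR),

    x_{n+1} = beta/2 (R_S R_M + I) x_n + (1 - beta) P_M x_n,

with the modulus projector P_M (replace Fourier amplitudes by sqrt(I) inside
the measured band, keep phases; leave the unmeasured region free) and the
support projector P_S (zero outside a centred ball, optional positivity).
Independent random-phase restarts are averaged in real space after mutual
alignment (translation + inversion), following the multi-repeat averaging
strategy of the correlation pipeline.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .evaluate import align_density_translation
from .intensity import AtomSet, ShellIntensityModel, structure_factor

__all__ = [
    "IntensityGrid",
    "DensityGrid",
    "model_to_grid",
    "raar_phase",
    "average_densities",
    "reference_density_from_atoms",
]

log = logging.getLogger(__name__)


def _kgrid(n: int, dk: float):
    f = np.fft.fftfreq(n) * n * dk
    kx, ky, kz = np.meshgrid(f, f, f, indexing="ij")
    return kx, ky, kz, np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)


@dataclasses.dataclass
class IntensityGrid:
    """Cubic Fourier-space intensity in FFT (unshifted) voxel layout.

    ``mask`` marks the measured band (innermost shell to k_cut); outside it
    the phasing leaves the Fourier coefficients unconstrained.
    """

    data: np.ndarray
    dk: float
    mask: np.ndarray
    k_cut: float

    def __post_init__(self):
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError("intensity grid must be cubic")
        if (self.data[self.mask] < 0).any():
            raise ValueError("negative intensity inside the measured mask")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def dx(self) -> float:
        """Real-space voxel size 2 pi / (n dk) in A."""
        return 2.0 * np.pi / (self.n * self.dk)


@dataclasses.dataclass
class DensityGrid:
    """Real-space electron density map, cubic voxels of ``dx`` A."""

    data: np.ndarray
    dx: float

    def save_ccp4(self, path):
        import gemmi

        n = self.data.shape[0]
        m = gemmi.Ccp4Map()
        m.grid = gemmi.FloatGrid(np.ascontiguousarray(self.data, dtype=np.float32))
        m.grid.unit_cell = gemmi.UnitCell(n * self.dx, n * self.dx, n * self.dx,
                                          90.0, 90.0, 90.0)
        m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def load_ccp4(cls, path) -> "DensityGrid":
        import gemmi

        m = gemmi.read_ccp4_map(str(path))
        data = np.array(m.grid, copy=True)
        dx = m.grid.unit_cell.a / data.shape[0]
        return cls(np.asarray(data, dtype=float), dx)


def model_to_grid(model: ShellIntensityModel, n_voxels: int,
                  dk: float | None = None) -> IntensityGrid:
    """Evaluate a shell model on a cubic Fourier grid.

    Radial linear interpolation between shells; voxels outside the shell
    range are zero and unmeasured.  Small negative truncation artifacts
    inside the band are clamped to zero (logged).  dk defaults to placing
    k_cut just inside the grid Nyquist.
    """
    if n_voxels % 2:
        raise ValueError("n_voxels must be even")
    k_cut = model.grid.k_cut
    if dk is None:
        dk = 2.0 * k_cut / n_voxels * 1.05
    if (n_voxels // 2) * dk < k_cut:
        raise ValueError("grid Nyquist below k_cut; increase n_voxels or dk")
    kx, ky, kz, r = _kgrid(n_voxels, dk)
    pts = np.column_stack([kx.ravel(), ky.ravel(), kz.ravel()])
    vals = model.evaluate(pts, inner="zero").reshape(r.shape)
    neg = vals < 0
    if neg.any():
        log.info("clamping %d negative voxels (%.2g%% of band) from the "
                 "truncated expansion", int(neg.sum()),
                 100.0 * neg.sum() / neg.size)
        vals = np.clip(vals, 0.0, None)
    mask = (r >= model.grid.radii[0]) & (r <= k_cut)
    return IntensityGrid(vals, dk, mask, k_cut)


def raar_phase(intensity: IntensityGrid, support_radius: float,
               beta: float = 0.92, n_iter: int = 400, seed: int | None = None,
               positivity: bool = True, rng=None):
    """Recover a real-space density from Fourier intensities by RAAR.

    ``support_radius`` is the radius (A) of the centred spherical support;
    it should oversample the molecule (support well inside the field of
    view).  Returns (DensityGrid, info) where info carries the Fourier
    residual trace ||F x| - sqrt I|| / ||sqrt I|| (non-convergence is
    reported, not raised).
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = intensity.n
    dx = intensity.dx
    if support_radius >= 0.5 * n * dx:
        raise ValueError("support must be smaller than half the field of view")
    sqrtI = np.sqrt(intensity.data)
    mask = intensity.mask
    norm = np.linalg.norm(sqrtI[mask])

    ax = (np.arange(n) - n // 2) * dx
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = np.fft.ifftshift(X ** 2 + Y ** 2 + Z ** 2 <= support_radius ** 2)

    def P_M(x):
        F = np.fft.fftn(x)
        mag = np.abs(F)
        phase = np.where(mag[mask] > 0, F[mask] / np.maximum(mag[mask], 1e-300), 1.0)
        F = F.copy()
        F[mask] = sqrtI[mask] * phase
        return np.fft.ifftn(F).real, mag

    def P_S(x):
        y = np.where(ball, x, 0.0)
        if positivity:
            y = np.clip(y, 0.0, None)
        return y

    phases = np.exp(2j * np.pi * rng.uniform(size=mask.sum()))
    F0 = np.zeros((n, n, n), dtype=complex)
    F0[mask] = sqrtI[mask] * phases
    x = np.fft.ifftn(F0).real

    errs = []
    for it in range(n_iter):
        pm, mag = P_M(x)
        errs.append(float(np.linalg.norm(mag[mask] - sqrtI[mask]) / max(norm, 1e-300)))
        rm = 2.0 * pm - x
        rs = 2.0 * P_S(rm) - rm
        x = 0.5 * beta * (rs + x) + (1.0 - beta) * pm
    pm, mag = P_M(x)
    err = float(np.linalg.norm(mag[mask] - sqrtI[mask]) / max(norm, 1e-300))
    density = P_S(pm)
    dens = DensityGrid(np.fft.fftshift(density), dx)
    return dens, {"fourier_errors": np.array(errs + [err]),
                  "final_error": err}


def average_densities(densities: list, reference=None,
                      min_correlation: float = 0.2):
    """Voxel-wise mean after mutual alignment (translation + inversion).

    Densities are aligned to ``reference`` (default: the first map); maps
    whose aligned correlation stays below ``min_correlation`` are excluded
    with a warning.
    """
    if not densities:
        raise ValueError("no densities to average")
    grids = [d.data if isinstance(d, DensityGrid) else np.asarray(d)
             for d in densities]
    dx = densities[0].dx if isinstance(densities[0], DensityGrid) else None
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("densities must share the grid")
    ref = grids[0] if reference is None else (
        reference.data if isinstance(reference, DensityGrid) else np.asarray(reference))
    acc, used = np.zeros_like(grids[0]), 0
    for i, g in enumerate(grids):
        moved, shift, flipped, corr = align_density_translation(g, ref)
        if corr < min_correlation:
            log.warning("density %d excluded from average (corr %.3f)", i, corr)
            continue
        acc += moved
        used += 1
    if used == 0:
        raise ValueError("no densities survived alignment")
    mean = acc / used
    return DensityGrid(mean, dx) if dx is not None else mean


def reference_density_from_atoms(atoms: AtomSet, n_voxels: int, dk: float,
                                 k_cut: float) -> DensityGrid:
    """Band-limited reference density from the closed-form complex Fourier
    amplitude of the Gaussian-atom model, cut at k_cut (phases included).

    This is the benchmark a correlation reconstruction is compared against:
    it contains exactly the Fourier information available below the cutoff.
    """
    kx, ky, kz, r = _kgrid(n_voxels, dk)
    pts = np.column_stack([kx.ravel(), ky.ravel(), kz.ravel()])
    F = structure_factor(atoms, pts).reshape(r.shape)
    F = np.where(r <= k_cut, F, 0.0)
    rho = np.fft.ifftn(F).real
    return DensityGrid(np.fft.fftshift(rho), 2.0 * np.pi / (n_voxels * dk))
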