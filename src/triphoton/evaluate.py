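"""Scoring of recovered intensities and densities.

Recovered intensities come out of the annealing in an arbitrary global
orientation, so they are rotationally fitted to a reference before any
comparison.  Densities additionally carry the phase-retrieval ambiguities
(translation and inversion).  Resolution is read off the Fourier shell
correlation at the FSC = 0.5 crossing, Delta r = 2 pi / k_res; phasing
fidelity uses the per-shell intensity correlation (ISC).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import sphharm
from .intensity import ShellIntensityModel

__all__ = [
    "ShellCurve",
    "fsc",
    "isc_grids",
    "isc_models",
    "resolution_at_half",
    "intensity_pearson",
    "align_models",
    "align_density_translation",
    "density_correlation",
    "AlignmentResult",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ShellCurve:
    """Per-shell correlation curve (FSC or ISC) on wavenumbers k (1/A)."""

    k: np.ndarray
    values: np.ndarray
    kind: str = "FSC"


def _radial_shells(shape, voxel_size):
    """Integer shell index per FFT voxel (one-voxel-wide shells) and dk."""
    n = shape[0]
    freqs = np.fft.fftfreq(n, d=voxel_size) * 2.0 * np.pi
    kx, ky, kz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    k = np.sqrt(kx ** 2 + ky ** 2 + kz ** 2)
    dk = 2.0 * np.pi / (n * voxel_size)
    return np.rint(k / dk).astype(np.int64), dk


def fsc(density1: np.ndarray, density2: np.ndarray, voxel_size: float) -> ShellCurve:
    """Fourier shell correlation between two real densities on one grid.

    FSC(k) = sum F1 F2* / sqrt(sum |F1|^2 sum |F2|^2) per one-voxel shell;
    the real part is reported (imaginary parts cancel for real inputs up to
    rounding).  Empty shells are skipped.
    """
    density1 = np.asarray(density1, dtype=float)
    density2 = np.asarray(density2, dtype=float)
    if density1.shape != density2.shape:
        raise ValueError("densities must share the grid")
    F1 = np.fft.fftn(density1)
    F2 = np.fft.fftn(density2)
    sh, dk = _radial_shells(density1.shape, voxel_size)
    nmax = sh.max() + 1
    num = np.bincount(sh.ravel(), weights=(F1 * F2.conj()).real.ravel(), minlength=nmax)
    d1 = np.bincount(sh.ravel(), weights=np.abs(F1.ravel()) ** 2, minlength=nmax)
    d2 = np.bincount(sh.ravel(), weights=np.abs(F2.ravel()) ** 2, minlength=nmax)
    npx = np.bincount(sh.ravel(), minlength=nmax)
    good = (npx > 0) & (d1 > 0) & (d2 > 0)
    ks = np.arange(nmax) * dk
    vals = np.zeros(nmax)
    vals[good] = num[good] / np.sqrt(d1[good] * d2[good])
    return ShellCurve(ks[good], np.clip(vals[good], -1.0, 1.0), "FSC")


def isc_grids(intensity1: np.ndarray, intensity2: np.ndarray,
              voxel_size: float) -> ShellCurve:
    """Per-shell Pearson correlation of two intensity grids (shell means
    subtracted); constant shells are skipped."""
    sh, dk = _radial_shells(intensity1.shape, voxel_size)
    return _shell_pearson(sh.ravel(), intensity1.ravel(), intensity2.ravel(), dk)


def _shell_pearson(sh, v1, v2, dk) -> ShellCurve:
    nmax = sh.max() + 1
    npx = np.bincount(sh, minlength=nmax).astype(float)
    s1 = np.bincount(sh, weights=v1, minlength=nmax)
    s2 = np.bincount(sh, weights=v2, minlength=nmax)
    s11 = np.bincount(sh, weights=v1 * v1, minlength=nmax)
    s22 = np.bincount(sh, weights=v2 * v2, minlength=nmax)
    s12 = np.bincount(sh, weights=v1 * v2, minlength=nmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = s12 - s1 * s2 / np.maximum(npx, 1)
        var1 = s11 - s1 ** 2 / np.maximum(npx, 1)
        var2 = s22 - s2 ** 2 / np.maximum(npx, 1)
        vals = cov / np.sqrt(var1 * var2)
    good = (npx > 1) & np.isfinite(vals)
    return ShellCurve(np.arange(nmax)[good] * dk,
                      np.clip(vals[good], -1.0, 1.0), "ISC")


def isc_models(model1: ShellIntensityModel, model2: ShellIntensityModel,
               n_dirs: int = 0) -> ShellCurve:
    """ISC between two shell models, evaluated on a common quadrature grid."""
    if model1.grid != model2.grid:
        raise ValueError("models must share the shell grid")
    L = max(model1.L, model2.L)
    th, ph, w = sphharm.sphere_quadrature(L + 2, 2 * L + 3)
    vals = np.empty(model1.grid.K)
    for s in range(model1.grid.K):
        v1 = model1.evaluate_on_shell(s, th, ph)
        v2 = model2.evaluate_on_shell(s, th, ph)
        v1 = v1 - np.average(v1, weights=w)
        v2 = v2 - np.average(v2, weights=w)
        denom = np.sqrt((w * v1 ** 2).sum() * (w * v2 ** 2).sum())
        vals[s] = (w * v1 * v2).sum() / denom if denom > 0 else np.nan
    good = np.isfinite(vals)
    return ShellCurve(model1.grid.radii[good], np.clip(vals[good], -1, 1), "ISC")


def resolution_at_half(curve: ShellCurve):
    """Resolution Delta r = 2 pi / k_res from the first downward 0.5 crossing.

    Returns (resolution_A, crossed); without a crossing the band-limit
    resolution 2 pi / k_max is returned with crossed = False.
    """
    k, v = np.asarray(curve.k, dtype=float), np.asarray(curve.values, dtype=float)
    pos = k > 0
    k, v = k[pos], v[pos]
    below = np.flatnonzero((v[:-1] >= 0.5) & (v[1:] < 0.5))
    if below.size == 0:
        if (v < 0.5).all():
            return 2.0 * np.pi / k[0], True
        return 2.0 * np.pi / k[-1], False
    i = below[0]
    f = (v[i] - 0.5) / (v[i] - v[i + 1])
    k_res = k[i] + f * (k[i + 1] - k[i])
    return 2.0 * np.pi / k_res, True


# --------------------------------------------------------------------------
# rotational alignment of shell models

def _model_samples(model: ShellIntensityModel, th, ph):
    return np.concatenate([model.evaluate_on_shell(s, th, ph)
                           for s in range(model.grid.K)])


def intensity_pearson(model1: ShellIntensityModel,
                      model2: ShellIntensityModel) -> float:
    """Global Pearson correlation of two intensities over (shell, direction)
    samples with uniform sphere weighting (no alignment applied)."""
    L = max(model1.L, model2.L)
    th, ph, w = sphharm.sphere_quadrature(L + 2, 2 * L + 3)
    v1 = _model_samples(model1, th, ph)
    v2 = _model_samples(model2, th, ph)
    W = np.tile(w, model1.grid.K)
    v1 = v1 - np.average(v1, weights=W)
    v2 = v2 - np.average(v2, weights=W)
    return float((W * v1 * v2).sum()
                 / np.sqrt((W * v1 ** 2).sum() * (W * v2 ** 2).sum()))


@dataclasses.dataclass
class AlignmentResult:
    aligned: object
    rotation: np.ndarray
    score: float
    degenerate: bool = False
    hand_flipped: bool = False


def _coarse_rotations(n: int) -> np.ndarray:
    # deterministic quasi-uniform cover of SO(3)
    return Rotation.random(n, rng=np.random.default_rng(1234567)).as_matrix()


def align_models(model: ShellIntensityModel, reference: ShellIntensityModel,
                 n_coarse: int = 4608, refine: bool = True) -> AlignmentResult:
    """Rotationally fit a shell model to a reference.

    Maximizes the Pearson correlation of the intensities over SO(3): a
    coarse quasi-uniform grid ranked by the anisotropic coefficient overlap
    sum_l <D_l(R), M_l>, then Nelder-Mead refinement in rotation-vector
    coordinates.  Intensities are Friedel-symmetric (even l), so enantiomers
    of the underlying density produce rotationally equivalent intensities and
    no hand search is needed at this stage.
    """
    if model.grid != reference.grid:
        raise ValueError("models must share the shell grid")
    L = min(model.L, reference.L)
    orders = [l for l in sphharm.even_orders(L) if l >= 2]
    aniso = sum(float((model.block(l) ** 2).sum()) for l in orders)
    total = float((model.coeffs ** 2).sum())
    if aniso < 1e-12 * total or not orders:
        log.warning("alignment degenerate: model is (near) isotropic")
        return AlignmentResult(model, np.eye(3),
                               intensity_pearson(model, reference),
                               degenerate=True)
    M = {l: reference.block(l) @ model.block(l).T for l in orders}
    Rs = _coarse_rotations(n_coarse)
    score = np.zeros(len(Rs))
    for l in orders:
        D = sphharm.real_wigner_d_batch(l, Rs)
        score += np.einsum("nmq,mq->n", D, M[l])
    best = Rs[int(np.argmax(score))]

    def neg_pearson(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return -intensity_pearson(model.rotated(R), reference)

    x0 = Rotation.from_matrix(best).as_rotvec()
    if refine:
        res = minimize(neg_pearson, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400})
        R = Rotation.from_rotvec(res.x).as_matrix()
        sc = -res.fun
    else:
        R = best
        sc = -neg_pearson(x0)
    if sc < 0.2:
        log.warning("alignment score low (%.3f)", sc)
    return AlignmentResult(model.rotated(R), R, float(sc))


# --------------------------------------------------------------------------
# density alignment (translation + hand)

def align_density_translation(density: np.ndarray, reference: np.ndarray,
                              try_inversion: bool = True,
                              upsample: int = 8):
    """Align a density to a reference by translation (and optional inversion).

    Returns (aligned, shift, hand_flipped, correlation); subpixel shifts via
    phase cross-correlation, applied with Fourier shifting.
    """
    from scipy.ndimage import fourier_shift
    from skimage.registration import phase_cross_correlation

    best = None
    for flip in ([False, True] if try_inversion else [False]):
        cand = density[::-1, ::-1, ::-1].copy() if flip else density
        shift, _, _ = phase_cross_correlation(reference, cand,
                                              upsample_factor=upsample,
                                              normalization=None)
        moved = np.fft.ifftn(fourier_shift(np.fft.fftn(cand), shift)).real
        corr = density_correlation(moved, reference)
        if best is None or corr > best[3]:
            best = (moved, shift, flip, corr)
    return best


def density_correlation(d1: np.ndarray, d2: np.ndarray) -> float:
    """Pearson cross-correlation of two real-space maps."""
    a = d1.ravel() - d1.mean()
    b = d2.ravel() - d2.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))
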