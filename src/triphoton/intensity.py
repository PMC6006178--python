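"""Gaussian-atom scattering intensities and their shell-wise SH expansion.

The molecule is modelled as a sum of isotropic Gaussians centred at the atom
positions (one Gaussian per atom, height and width set by the element).  The
3D intensity is the modulus squared of the closed-form Fourier transform,

    I(k) = | sum_j h_j exp(-sigma_j^2 |k|^2 / 2) exp(i k . x_j) |^2,

and is represented on K concentric reciprocal-space shells by real
spherical-harmonic coefficients A_lm(k), even orders only (Friedel symmetry).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import h5py
import numpy as np

from . import sphharm
from .sphharm import packed_offset

__all__ = [
    "AtomSet",
    "BeamGeometry",
    "ShellGrid",
    "ShellIntensityModel",
    "intensity_from_atoms",
    "structure_factor",
    "expand_on_shells",
    "ewald_theta",
    "count_basis_coefficients",
    "DEFAULT_ATOM_TABLE",
]

# Single-Gaussian stand-ins for atomic form factors: height ~ electron count,
# width in Angstrom.  Hydrogens are excluded by default (negligible signal).
DEFAULT_ATOM_TABLE = {
    "C": (6.0, 0.90),
    "N": (7.0, 0.85),
    "O": (8.0, 0.80),
    "S": (16.0, 1.05),
    "P": (15.0, 1.00),
}


@dataclasses.dataclass(frozen=True)
class AtomSet:
    """Gaussian pseudo-atoms: positions (n, 3) in A, heights, widths in A."""

    positions: np.ndarray
    heights: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        h = np.atleast_1d(np.asarray(self.heights, dtype=float))
        w = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if pos.size == 0:
            raise ValueError("empty atom set")
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if not (np.isfinite(pos).all() and np.isfinite(h).all() and np.isfinite(w).all()):
            raise ValueError("non-finite atom parameters")
        if h.shape[0] != pos.shape[0] or w.shape[0] != pos.shape[0]:
            raise ValueError("heights/widths must match number of atoms")
        if (w <= 0).any():
            raise ValueError("widths must be positive")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "widths", w)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def diameter(self) -> float:
        """Largest inter-atomic distance (A); used to size support masks."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return float(np.sqrt((d ** 2).sum(-1)).max())

    def centered(self) -> "AtomSet":
        return AtomSet(self.positions - self.positions.mean(axis=0),
                       self.heights, self.widths)

    @classmethod
    def from_pdb(cls, path, table: dict | None = None, exclude=("H",)) -> "AtomSet":
        """Read atoms from a PDB/mmCIF file (first model, first conformer)."""
        import gemmi

        table = DEFAULT_ATOM_TABLE if table is None else table
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        pos, hgt, wid = [], [], []
        model = st[0]
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "A"):
                        continue
                    el = atom.element.name
                    if el in exclude:
                        continue
                    h, w = table.get(el, (float(atom.element.atomic_number), 0.9))
                    pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    hgt.append(h)
                    wid.append(w)
        if not pos:
            raise ValueError(f"no usable atoms found in {path}")
        return cls(np.array(pos), np.array(hgt), np.array(wid)).centered()


@dataclasses.dataclass(frozen=True)
class BeamGeometry:
    """X-ray beam: wavelength (A) and reciprocal-space cutoff k_cut (1/A)."""

    wavelength: float
    k_cut: float

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (0.0 < self.k_cut <= 2.0 * self.k_in):
            raise ValueError("need 0 < k_cut <= 2 k_in")

    @property
    def k_in(self) -> float:
        """Incident wavenumber 2 pi / lambda (1/A)."""
        return 2.0 * np.pi / self.wavelength


def ewald_theta(k, wavelength: float):
    """Polar angle of the Ewald sphere point at radial wavenumber k.

    theta = arccos(k lambda / 4 pi); pi/2 at the beam axis (k = 0),
    0 at backscattering (k = 4 pi / lambda).
    """
    k = np.asarray(k, dtype=float)
    x = k * wavelength / (4.0 * np.pi)
    if np.any(k < 0) or np.any(x > 1.0 + 1e-12):
        raise ValueError("k outside [0, 4 pi / lambda]")
    return np.arccos(np.clip(x, -1.0, 1.0))


class ShellGrid:
    """K strictly increasing shell radii in (0, k_cut]; nearest-radius binning."""

    def __init__(self, radii: Sequence[float]):
        radii = np.asarray(radii, dtype=float)
        if radii.ndim != 1 or radii.size < 1:
            raise ValueError("radii must be a 1D nonempty array")
        if (radii <= 0).any() or (np.diff(radii) <= 0).any():
            raise ValueError("radii must be positive and strictly increasing")
        self.radii = radii
        self.K = radii.size
        self.k_cut = float(radii[-1])
        mid = 0.5 * (radii[:-1] + radii[1:])
        self._edges = np.concatenate([[0.0], mid, [self.k_cut]])

    @classmethod
    def uniform(cls, K: int, k_cut: float) -> "ShellGrid":
        """K equally spaced radii in (0, k_cut], excluding k = 0."""
        if K < 1:
            raise ValueError("need K >= 1")
        return cls(k_cut * np.arange(1, K + 1) / K)

    def assign(self, k):
        """Map |k| values to shell indices; -1 for photons beyond k_cut."""
        k = np.asarray(k, dtype=float)
        idx = np.searchsorted(self._edges[1:-1], k, side="right")
        return np.where(k <= self.k_cut, idx, -1)

    @property
    def annulus_measure(self) -> np.ndarray:
        """Radial bin measure int k dk over each shell's capture annulus."""
        e = self._edges
        return 0.5 * (e[1:] ** 2 - e[:-1] ** 2)

    def radial_average_matrix(self, n_sub: int = 64) -> np.ndarray:
        """Matrix M with (M c)_s = annulus average of the radial profile.

        The profile is the package's radial convention: linear interpolation
        between shell coefficients, clamped below the innermost shell.  The
        average is weighted by the in-plane measure k dk over each shell's
        capture annulus; used to compare shell-wise models with binned
        photon histograms.
        """
        if getattr(self, "_ram", None) is not None:
            return self._ram
        K = self.K
        M = np.zeros((K, K))
        e = self._edges
        for s in range(K):
            ks = np.linspace(e[s], e[s + 1], n_sub + 1)
            ks = 0.5 * (ks[:-1] + ks[1:])
            w = ks * (e[s + 1] - e[s]) / n_sub
            j = np.clip(np.searchsorted(self.radii, ks), 1, K - 1)
            t = np.clip((ks - self.radii[j - 1])
                        / (self.radii[j] - self.radii[j - 1]), 0.0, 1.0)
            np.add.at(M[s], j - 1, w * (1.0 - t))
            np.add.at(M[s], j, w * t)
            M[s] /= w.sum()
        self._ram = M
        return M

    def __eq__(self, other):
        return isinstance(other, ShellGrid) and np.array_equal(self.radii, other.radii)

    def __repr__(self):
        return f"ShellGrid(K={self.K}, k_cut={self.k_cut:g})"


class ShellIntensityModel:
    """Shell-wise real-SH representation of a 3D intensity.

    coeffs has shape (n_even_coeffs(L), K): packed even-l blocks along axis 0,
    shells along axis 1.
    """

    def __init__(self, grid: ShellGrid, L: int, coeffs: np.ndarray,
                 wavelength: float | None = None):
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape != (sphharm.n_even_coeffs(L), grid.K):
            raise ValueError(
                f"coeffs must be ({sphharm.n_even_coeffs(L)}, {grid.K}), got {coeffs.shape}")
        self.grid = grid
        self.L = L
        self.coeffs = coeffs
        self.wavelength = wavelength

    def block(self, l: int) -> np.ndarray:
        """Coefficients of order l, shape (2l+1, K)."""
        return self.coeffs[sphharm.packed_slice(l)]

    # -- evaluation ---------------------------------------------------------

    def _radial_weights(self, r: np.ndarray, inner: str):
        """Linear interpolation weights between neighbouring shells."""
        radii = self.grid.radii
        j = np.clip(np.searchsorted(radii, r), 1, self.grid.K - 1)
        r0, r1 = radii[j - 1], radii[j]
        t = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
        inside = r <= self.grid.k_cut + 1e-12
        below = r < radii[0]
        if inner == "clamp":
            t = np.where(below, 0.0, t)
            scale = np.where(inside, 1.0, 0.0)
        elif inner == "zero":
            scale = np.where(inside & ~below, 1.0, 0.0)
            # taper linearly from 0 at k=0 to the first shell
            t = np.where(below, 0.0, t)
            scale = np.where(below, 0.0, scale)
        else:
            raise ValueError("inner must be 'clamp' or 'zero'")
        return j, t, scale

    def evaluate(self, points: np.ndarray, inner: str = "clamp",
                 chunk: int = 200_000) -> np.ndarray:
        """Evaluate the model intensity at 3D reciprocal-space points (n, 3).

        Radially the coefficients are linearly interpolated between shells;
        beyond k_cut the intensity is 0; below the innermost shell it is
        clamped to the innermost shell ('clamp') or set to 0 ('zero').
        Accumulates mode-by-mode, so memory stays O(chunk).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = points.shape[0]
        out = np.empty(n, dtype=float)
        for s in range(0, n, chunk):
            pts = points[s:s + chunk]
            r = np.linalg.norm(pts, axis=1)
            theta, phi = sphharm.vectors_to_angles(pts)
            j, t, scale = self._radial_weights(r, inner)
            coeffs = self.coeffs

            def coef(l, m, _j=j, _t=t):
                row = coeffs[packed_offset(l) + l + m]
                return row[_j - 1] * (1.0 - _t) + row[_j] * _t

            acc = sphharm.fast_even_synthesis(self.L, theta, phi, coef)
            out[s:s + chunk] = acc * scale
        return out

    def evaluate_on_shell(self, shell: int, theta, phi) -> np.ndarray:
        return sphharm.sh_synthesis(self.coeffs[:, shell], self.L, theta, phi)

    def rotated(self, rotation: np.ndarray) -> "ShellIntensityModel":
        """Model of the rotated intensity I(R^-1 k)."""
        return ShellIntensityModel(
            self.grid, self.L,
            sphharm.rotate_even_coeffs(self.coeffs, self.L, rotation),
            self.wavelength)

    # -- persistence --------------------------------------------------------

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("radii", data=self.grid.radii)
            f.create_dataset("coeffs", data=self.coeffs)
            f.attrs["L"] = self.L
            if self.wavelength is not None:
                f.attrs["wavelength"] = self.wavelength

    @classmethod
    def load(cls, path) -> "ShellIntensityModel":
        with h5py.File(path, "r") as f:
            grid = ShellGrid(f["radii"][...])
            wl = f.attrs.get("wavelength")
            return cls(grid, int(f.attrs["L"]), f["coeffs"][...],
                       None if wl is None else float(wl))


def structure_factor(atoms: AtomSet, points: np.ndarray) -> np.ndarray:
    """Closed-form complex Fourier amplitude of the Gaussian-atom density."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    k2 = (points ** 2).sum(axis=1)
    phase = points @ atoms.positions.T          # (npts, natoms)
    env = atoms.heights * np.exp(-0.5 * atoms.widths ** 2 * k2[:, None])
    return (env * np.exp(1j * phase)).sum(axis=1)


def intensity_from_atoms(atoms: AtomSet, points: np.ndarray) -> np.ndarray:
    """Exact intensity |FT[rho]|^2 at the given reciprocal-space points."""
    f = structure_factor(atoms, points)
    return (f * f.conj()).real


def expand_on_shells(evaluator: Callable[[np.ndarray], np.ndarray],
                     grid: ShellGrid, L: int,
                     n_theta: int | None = None, n_phi: int | None = None,
                     wavelength: float | None = None) -> ShellIntensityModel:
    """Project an intensity evaluator onto shell-wise real-SH coefficients.

    The quadrature (Gauss-Legendre x uniform azimuth) is exact for inputs
    band-limited at order L when n_theta >= L+1 and n_phi >= 2L+1; defaults
    carry a margin (2L+2, 4L+4) to suppress aliasing of non-band-limited
    inputs such as atom intensities.
    """
    if L % 2:
        raise ValueError("expansion order L must be even")
    n_theta = 2 * L + 2 if n_theta is None else n_theta
    n_phi = max(4 * L + 4, 8) if n_phi is None else n_phi
    if n_theta < L + 1 or n_phi < 2 * L + 1:
        raise ValueError("quadrature insufficient for degree 2L products")
    theta, phi, w = sphharm.sphere_quadrature(n_theta, n_phi)
    Y = sphharm.real_sh_matrix(L, theta, phi, even_only=True)
    dirs = sphharm.angles_to_vectors(theta, phi)
    coeffs = np.empty((sphharm.n_even_coeffs(L), grid.K))
    for s, r in enumerate(grid.radii):
        vals = np.asarray(evaluator(r * dirs), dtype=float)
        coeffs[:, s] = Y @ (w * vals)
    return ShellIntensityModel(grid, L, coeffs, wavelength=wavelength)


def count_basis_coefficients(L: int, K: int) -> int:
    """Number of real SH unknowns, K (L^2 + 3L + 2) / 2 (even orders only)."""
    if L < 0 or L % 2 or K < 1:
        raise ValueError("need even L >= 0 and K >= 1")
    return K * (L * L + 3 * L + 2) // 2
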