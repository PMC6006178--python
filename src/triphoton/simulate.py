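"""Synthetic few-photon scattering images.

Each image is one XFEL shot of a randomly (Haar-uniformly) oriented molecule:
the photon positions on the detector are i.i.d. draws from the Ewald slice of
the rotated 3D intensity, restricted to |k| <= k_cut.  Sampling uses rejection
from an isotropic 2D Gaussian proposal (width 1.05 1/A by default) against a
precomputed global envelope bound, which preserves the target distribution
exactly.  An optional noise channel replaces (or appends) photons with draws
from an isotropic radial Gaussian G(k, sigma) of fraction gamma, emulating
incoherent scattering and similar diffuse backgrounds.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterator

import h5py
import numpy as np
from scipy.spatial.transform import Rotation

from .intensity import BeamGeometry, ShellIntensityModel, ewald_theta
from . import sphharm

__all__ = [
    "NoiseModel",
    "PhotonImage",
    "PhotonDataset",
    "random_rotation",
    "ewald_project",
    "simulate_image",
    "simulate_dataset",
]

log = logging.getLogger(__name__)

PROPOSAL_SIGMA = 1.05  # width of the 2D Gaussian proposal, 1/A


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Radial Gaussian noise channel G(k, sigma) with photon fraction gamma."""

    gamma: float
    sigma: float
    mode: str = "substitute"  # or "append"

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mode not in ("substitute", "append"):
            raise ValueError("mode must be 'substitute' or 'append'")

    def draw(self, n: int, k_cut: float, rng) -> np.ndarray:
        """n detector positions from the 2D Gaussian law, truncated at k_cut."""
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = n - filled
            r = self.sigma * np.sqrt(-2.0 * np.log(rng.uniform(size=2 * m + 8)))
            r = r[r <= k_cut][:m]
            phi = rng.uniform(0.0, 2.0 * np.pi, size=r.size)
            out[filled:filled + r.size, 0] = r * np.cos(phi)
            out[filled:filled + r.size, 1] = r * np.sin(phi)
            filled += r.size
        return out


@dataclasses.dataclass
class PhotonImage:
    """One shot: (n, 2) detector-plane wavevectors, optional truth rotation."""

    photons: np.ndarray
    truth_rotation: np.ndarray | None = None

    def __post_init__(self):
        self.photons = np.asarray(self.photons, dtype=float).reshape(-1, 2)

    def __len__(self):
        return self.photons.shape[0]


class PhotonDataset:
    """Dataset of images stored as a flat photon table with per-image offsets."""

    def __init__(self, photons: np.ndarray, offsets: np.ndarray,
                 rotations: np.ndarray | None = None, meta: dict | None = None):
        self.photons = np.asarray(photons, dtype=float).reshape(-1, 2)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.rotations = rotations
        self.meta = dict(meta or {})
        if self.offsets[0] != 0 or self.offsets[-1] != len(self.photons):
            raise ValueError("offsets must start at 0 and end at photon count")

    @property
    def n_images(self) -> int:
        return len(self.offsets) - 1

    @property
    def counts(self) -> np.ndarray:
        return np.diff(self.offsets)

    def __iter__(self) -> Iterator[PhotonImage]:
        for i in range(self.n_images):
            rot = None if self.rotations is None else self.rotations[i]
            yield PhotonImage(self.photons[self.offsets[i]:self.offsets[i + 1]], rot)

    def __getitem__(self, i) -> PhotonImage:
        rot = None if self.rotations is None else self.rotations[i]
        return PhotonImage(self.photons[self.offsets[i]:self.offsets[i + 1]], rot)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("photons", data=self.photons)
            f.create_dataset("offsets", data=self.offsets)
            if self.rotations is not None:
                f.create_dataset("rotations", data=self.rotations)
            for k, v in self.meta.items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "PhotonDataset":
        with h5py.File(path, "r") as f:
            rot = f["rotations"][...] if "rotations" in f else None
            return cls(f["photons"][...], f["offsets"][...], rot, dict(f.attrs))

    def export_text(self, path):
        """Flat text export: one photon per line, 'image_id k_x k_y'."""
        ids = np.repeat(np.arange(self.n_images), self.counts)
        np.savetxt(path, np.column_stack([ids, self.photons]),
                   fmt=["%d", "%.8g", "%.8g"])


def random_rotation(rng, n: int | None = None) -> np.ndarray:
    """Haar-uniform rotation matrices; (3,3) or (n,3,3)."""
    if n is None:
        return Rotation.random(rng=rng).as_matrix()
    return Rotation.random(n, rng=rng).as_matrix()


def ewald_project(photons: np.ndarray, wavelength: float) -> np.ndarray:
    """Lift detector-plane wavevectors (n, 2) onto the Ewald sphere (n, 3).

    A photon at radial wavenumber k and detector azimuth phi maps to the 3D
    point k (sin th cos phi, sin th sin phi, cos th) with th = arccos(k
    lambda / 4 pi); the flat-detector limit lambda -> 0 gives th = pi/2.
    """
    photons = np.atleast_2d(np.asarray(photons, dtype=float))
    k = np.hypot(photons[:, 0], photons[:, 1])
    th = ewald_theta(k, wavelength)
    phi = np.arctan2(photons[:, 1], photons[:, 0])
    st = np.sin(th)
    return np.column_stack([k * st * np.cos(phi), k * st * np.sin(phi), k * np.cos(th)])


class _RejectionSampler:
    """Rejection sampler for the Ewald-slice photon distribution."""

    def __init__(self, model: ShellIntensityModel, geometry: BeamGeometry,
                 proposal_sigma: float = PROPOSAL_SIGMA, safety: float = 1.5):
        self.model = model
        self.geometry = geometry
        self.sigma = proposal_sigma
        # Orientation-independent envelope: bound I over all directions at each
        # radius, then bound the ratio to the (unnormalized) proposal density.
        radii = np.linspace(1e-4, geometry.k_cut, 96)
        th, ph, _ = sphharm.sphere_quadrature(24, 48)
        dirs = sphharm.angles_to_vectors(th, ph)
        imax = np.empty(radii.size)
        for i, r in enumerate(radii):
            imax[i] = self.model.evaluate(r * dirs).max()
        g = np.exp(-0.5 * radii ** 2 / self.sigma ** 2)
        self.envelope = safety * np.max(imax / g)
        self._acc_est = 0.25

    def _proposals(self, n: int, rng) -> np.ndarray:
        out = rng.normal(scale=self.sigma, size=(int(n * 1.3) + 16, 2))
        out = out[np.hypot(out[:, 0], out[:, 1]) <= self.geometry.k_cut]
        while out.shape[0] < n:
            extra = rng.normal(scale=self.sigma, size=(n, 2))
            extra = extra[np.hypot(extra[:, 0], extra[:, 1]) <= self.geometry.k_cut]
            out = np.concatenate([out, extra])
        return out[:n]

    def sample(self, rotations: np.ndarray, counts: np.ndarray, rng) -> list[np.ndarray]:
        """Draw counts[i] photons for the image with rotation rotations[i]."""
        n_img = len(counts)
        got: list[list[np.ndarray]] = [[] for _ in range(n_img)]
        deficit = np.asarray(counts, dtype=np.int64).copy()
        active = np.flatnonzero(deficit > 0)
        while active.size:
            per = np.maximum((deficit[active] / max(self._acc_est, 0.02)).astype(int) + 4, 8)
            total = int(per.sum())
            props = self._proposals(total, rng)
            img_of = np.repeat(active, per)
            pts3 = ewald_project(props, self.geometry.wavelength)
            # apply each image's molecular rotation: I_omega(K) = I(U K)
            rot = rotations[img_of]
            pts_rot = np.einsum("nij,nj->ni", rot, pts3)
            ivals = np.maximum(self.model.evaluate(pts_rot), 0.0)
            k2 = (props ** 2).sum(axis=1)
            g = np.exp(-0.5 * k2 / self.sigma ** 2)
            ratio = ivals / (self.envelope * g)
            if ratio.max() > 1.0:
                bad = np.unique(img_of[ratio > 1.0])
                self.envelope *= 2.0 * ratio.max()
                log.warning("rejection envelope violated; enlarging bound and "
                            "resampling %d images", bad.size)
                for b in bad:
                    got[b] = []
                    deficit[b] = counts[b]
                continue
            acc = rng.uniform(size=total) < ratio
            self._acc_est = 0.8 * self._acc_est + 0.2 * max(acc.mean(), 1e-3)
            bounds = np.concatenate([[0], np.cumsum(per)])
            for i, idx in enumerate(active):
                sl = slice(bounds[i], bounds[i + 1])
                sel = props[sl][acc[sl]][:deficit[idx]]
                if sel.size:
                    got[idx].append(sel)
                    deficit[idx] -= sel.shape[0]
            active = np.flatnonzero(deficit > 0)
        return [np.concatenate(g_, axis=0) if g_ else np.empty((0, 2)) for g_ in got]


def _apply_noise(photons: np.ndarray, noise: NoiseModel, k_cut: float, rng) -> np.ndarray:
    if noise is None or noise.gamma == 0.0 or photons.shape[0] == 0:
        return photons
    if noise.mode == "substitute":
        mask = rng.uniform(size=photons.shape[0]) < noise.gamma
        if mask.any():
            photons = photons.copy()
            photons[mask] = noise.draw(int(mask.sum()), k_cut, rng)
        return photons
    n_extra = rng.poisson(photons.shape[0] * noise.gamma / (1.0 - noise.gamma))
    if n_extra == 0:
        return photons
    return np.concatenate([photons, noise.draw(n_extra, k_cut, rng)])


def simulate_image(model: ShellIntensityModel, geometry: BeamGeometry,
                   mean_photons: float, rng, noise: NoiseModel | None = None,
                   count_mode: str = "fixed",
                   sampler: _RejectionSampler | None = None) -> PhotonImage:
    """One synthetic shot; see `simulate_dataset` for the batched variant."""
    ds = simulate_dataset(model, geometry, 1, mean_photons, rng, noise=noise,
                          count_mode=count_mode, sampler=sampler)
    return ds[0]


def simulate_dataset(model: ShellIntensityModel, geometry: BeamGeometry,
                     n_images: int, mean_photons: float, rng,
                     noise: NoiseModel | None = None,
                     count_mode: str = "fixed",
                     keep_rotations: bool = False,
                     out=None, batch: int = 4096,
                     sampler: _RejectionSampler | None = None) -> PhotonDataset:
    """Simulate a dataset of independent few-photon images.

    count_mode 'fixed' gives exactly P photons per image; 'poisson' draws the
    per-image count from Poisson(P).  Reproducible given the same rng state.
    """
    if n_images < 1:
        raise ValueError("need n_images >= 1")
    if mean_photons <= 0:
        raise ValueError("need mean_photons > 0")
    if count_mode not in ("fixed", "poisson"):
        raise ValueError("count_mode must be 'fixed' or 'poisson'")
    if sampler is None:
        sampler = _RejectionSampler(model, geometry)
    all_photons, all_offsets, all_rot = [], [0], []
    for start in range(0, n_images, batch):
        nb = min(batch, n_images - start)
        rots = random_rotation(rng, nb)
        if count_mode == "fixed":
            counts = np.full(nb, int(round(mean_photons)), dtype=np.int64)
        else:
            counts = rng.poisson(mean_photons, size=nb).astype(np.int64)
        per_image = sampler.sample(rots, counts, rng)
        for ph in per_image:
            ph = _apply_noise(ph, noise, geometry.k_cut, rng)
            all_photons.append(ph)
            all_offsets.append(all_offsets[-1] + ph.shape[0])
        if keep_rotations:
            all_rot.append(rots)
    photons = (np.concatenate(all_photons, axis=0)
               if all_photons else np.empty((0, 2)))
    meta = {"mean_photons": mean_photons, "count_mode": count_mode,
            "wavelength": geometry.wavelength, "k_cut": geometry.k_cut}
    if noise is not None:
        meta.update(noise_gamma=noise.gamma, noise_sigma=noise.sigma)
    ds = PhotonDataset(photons, np.asarray(all_offsets),
                       np.concatenate(all_rot) if all_rot else None, meta)
    if out is not None:
        ds.save(out)
    return ds
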