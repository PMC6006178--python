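"""Two- and three-photon correlations: extraction and analytic evaluation.

The orientation of the molecule is unknown in every shot, so the photon
images are condensed into orientation-independent summaries: doublets
(k1, k2, alpha) and triplets (k1, k2, k3, alpha, beta), where k_i are the
radial wavenumbers of the photons on the detector and alpha, beta the
azimuthal angles of photons 2 and 3 measured from photon 1.

Analytically, the triple correlation is the orientational (Haar) average

    t(k1, k2, k3, alpha, beta) = < I(R u1) I(R u2) I(R u3) >_R

with u_i the Ewald-sphere liftings of the detector positions.  Expanding
I in spherical harmonics and using the Haar integral of a product of three
Wigner-D matrices gives the double Wigner-3j contraction

    t = sum_{l1 l2 l3} B_{l1 l2 l3}(k1, k2, k3) G_{l1 l2 l3}(k1, k2, k3, a, b)

    B = sum_{m1 m2} a_{l1 m1}(k1) a_{l2 m2}(k2) a_{l3 m3}(k3) (l1 l2 l3; m1 m2 m3)
    G = sum_{m1 m2} (l1 l2 l3; m1 m2 m3) Y_{l1 m1}(th1, 0) Y_{l2 m2}(th2, a)
                                         Y_{l3 m3}(th3, b)

with m3 = -(m1+m2), a_lm the complex coefficients of the (real) intensity
and th_i = ewald_theta(k_i).  B carries the model, G only geometry; the
factorization is what makes the annealing energy affordable: G is
precomputed once per binning, B is refreshed when the model moves.

The two-photon correlation is the Legendre sum

    c(k1, k2, alpha) = (4 pi)^-1 sum_l P_l(cos alpha*) sum_m A_lm(k1) A_lm(k2)

with the Ewald-corrected angle alpha* between the lifted photon directions.

Histogram convention: every unordered photon triple contributes three
ordered triplets (each photon once in the reference role), so P photons give
P(P-1)(P-2)/2 triplets per image -- 360 for P = 10, matching an expected
1.2e12 triplets from 3.3e9 ten-photon images.  The angles are folded by the
joint mirror symmetry (alpha, beta) -> (2pi-alpha, 2pi-beta), which is exact
for Friedel-symmetric intensities, and (k2, alpha) <-> (k3, beta) swaps are
canonicalized; both empirical counts and analytic tables live on the same
canonical bins.
"""

from __future__ import annotations

import dataclasses
import logging

import h5py
import numpy as np
from scipy import special as _sp

from . import sphharm
from .intensity import ShellGrid, ShellIntensityModel, ewald_theta
from .simulate import PhotonDataset, PhotonImage
from .wigner import triangle_ok, wigner_3j

__all__ = [
    "CorrelationBinning",
    "DoubletHistogram",
    "TripletHistogram",
    "extract_doublets",
    "extract_triplets",
    "ewald_alpha_star",
    "analytic_two_point",
    "analytic_three_point",
    "analytic_triplet_table",
    "normalize_correlation",
    "TripleCorrelationEngine",
    "triplets_per_image",
    "doublets_per_image",
    "triplet_budget",
    "images_for_photon_budget",
    "EPS_FLOOR",
]

log = logging.getLogger(__name__)

EPS_FLOOR = 1e-12  # floor for t~, as a fraction of the table maximum


# --------------------------------------------------------------------------
# bookkeeping

def triplets_per_image(p: int) -> int:
    """P(P-1)(P-2)/2 ordered triplets per P-photon image (3 per unordered)."""
    return p * (p - 1) * (p - 2) // 2


def doublets_per_image(p: int) -> int:
    return p * (p - 1) // 2


def triplet_budget(n_images: int, p: int) -> int:
    """Total triplets from n_images fixed-count images of p photons."""
    return n_images * triplets_per_image(p)


def images_for_photon_budget(total_photons: float, p: int) -> int:
    """Images needed to collect a photon budget at p photons per image."""
    return int(round(total_photons / p))


# --------------------------------------------------------------------------
# geometry

def ewald_alpha_star(k1, k2, alpha, wavelength: float):
    """Angle between two Ewald-lifted photons whose detector azimuths differ
    by alpha: cos a* = sin th1 sin th2 cos alpha + cos th1 cos th2."""
    th1 = ewald_theta(np.asarray(k1, dtype=float), wavelength)
    th2 = ewald_theta(np.asarray(k2, dtype=float), wavelength)
    ca = (np.sin(th1) * np.sin(th2) * np.cos(alpha)
          + np.cos(th1) * np.cos(th2))
    return np.arccos(np.clip(ca, -1.0, 1.0))


# --------------------------------------------------------------------------
# binning and canonical folding

class CorrelationBinning:
    """Shell assignment plus angular binning for doublets and triplets.

    Angles live on the full circle in ``A = 2 n_alpha`` uniform bins; the
    mirror fold (alpha, beta) -> (2pi-a, 2pi-b) and the (k2, alpha) <->
    (k3, beta) swap reduce the triplet domain to canonical bins with the
    alpha bin in [0, n_alpha).  Doublet angles are folded to [0, pi] in
    n_alpha bins of the same width.
    """

    def __init__(self, grid: ShellGrid, n_alpha: int = 16,
                 wavelength: float | None = None):
        if n_alpha < 2:
            raise ValueError("need n_alpha >= 2")
        self.grid = grid
        self.n_alpha = int(n_alpha)
        self.A = 2 * self.n_alpha
        self.wavelength = wavelength
        self._build_canonical()

    # angular helpers ------------------------------------------------------

    def angle_bin(self, angles) -> np.ndarray:
        """Full-circle bin index in [0, A) for angles in radians."""
        a = np.mod(np.asarray(angles, dtype=float), 2.0 * np.pi)
        return np.minimum((a / (2.0 * np.pi) * self.A).astype(np.int64), self.A - 1)

    @property
    def alpha_centers_half(self) -> np.ndarray:
        """Centers of the alpha bins on [0, pi] (folded domain)."""
        w = 2.0 * np.pi / self.A
        return (np.arange(self.n_alpha) + 0.5) * w

    @property
    def beta_centers_full(self) -> np.ndarray:
        w = 2.0 * np.pi / self.A
        return (np.arange(self.A) + 0.5) * w

    # canonical folding ----------------------------------------------------

    def _key(self, s2, a, s3, b):
        K, A = self.grid.K, self.A
        return ((s2 * A + a) * K + s3) * A + b

    def _build_canonical(self):
        K, A, H = self.grid.K, self.A, self.n_alpha
        s2, a, s3, b = np.ix_(np.arange(K), np.arange(A), np.arange(K), np.arange(A))
        s2, a, s3, b = np.broadcast_arrays(s2, a, s3, b)

        def fold(s2_, a_, s3_, b_):
            m = a_ >= H
            return (s2_, np.where(m, A - 1 - a_, a_), s3_, np.where(m, A - 1 - b_, b_))

        c1 = fold(s2, a, s3, b)
        c2 = fold(s3, b, s2, a)
        k1 = self._key(*c1)
        k2 = self._key(*c2)
        rep = np.minimum(k1, k2)

        # orbit size: distinct elements among {x, mirror, swap, mirror swap}
        kx = self._key(s2, a, s3, b)
        km = self._key(s2, A - 1 - a, s3, A - 1 - b)
        ks = self._key(s3, b, s2, a)
        kms = self._key(s3, A - 1 - b, s2, A - 1 - a)
        stack = np.stack([kx, km, ks, kms])
        orbit = (np.sort(stack, axis=0)[1:] != np.sort(stack, axis=0)[:-1]).sum(0) + 1

        # compact index over (s2, a<H, s3, b)
        r_s2, rem = np.divmod(rep, A * K * A)
        r_a, rem = np.divmod(rem, K * A)
        r_s3, r_b = np.divmod(rem, A)
        compact = ((r_s2 * H + r_a) * K + r_s3) * A + r_b
        self.n4 = K * H * K * A
        self.canon_idx4 = compact.reshape(K, A, K, A)
        self.canon_list = np.unique(compact)
        orbit4 = np.zeros(self.n4, dtype=np.int64)
        orbit4[compact.reshape(-1)] = orbit.reshape(-1)
        self.orbit4 = orbit4  # orbit size per canonical compact-4 bin
        self.is_rep4 = np.zeros(self.n4, dtype=bool)
        self.is_rep4[self.canon_list] = True

    @property
    def n_canonical_triplet_bins(self) -> int:
        return self.grid.K * self.canon_list.size

    def triplet_bin_measure(self) -> np.ndarray:
        """Measure of each canonical bin: orbit size x product of radial
        annulus measures (angular widths are uniform and cancel).
        Shape (K, n_canon4)."""
        K, H, A = self.grid.K, self.n_alpha, self.A
        mr = self.grid.annulus_measure
        s2 = self.canon_list // (H * K * A)
        s3 = (self.canon_list // A) % K
        w4 = self.orbit4[self.canon_list] * mr[s2] * mr[s3]
        return mr[:, None] * w4[None, :]

    def doublet_bin_measure(self) -> np.ndarray:
        """Measure of (s1 <= s2, alpha) doublet bins, shape (K, K, n_alpha)."""
        mr = self.grid.annulus_measure
        w = mr[:, None] * mr[None, :]
        pairf = np.where(np.eye(self.grid.K, dtype=bool), 1.0, 2.0)
        return (w * pairf)[:, :, None] * np.ones(self.n_alpha)


@dataclasses.dataclass
class DoubletHistogram:
    """Counts over (shell1 <= shell2, folded angle bin)."""

    binning: CorrelationBinning
    counts: np.ndarray  # (K, K, n_alpha), populated for s1 <= s2
    total: int = 0

    @classmethod
    def empty(cls, binning):
        K = binning.grid.K
        return cls(binning, np.zeros((K, K, binning.n_alpha)), 0)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts)
            f.create_dataset("radii", data=self.binning.grid.radii)
            f.attrs["n_alpha"] = self.binning.n_alpha
            f.attrs["total"] = self.total
            if self.binning.wavelength is not None:
                f.attrs["wavelength"] = self.binning.wavelength

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            wl = f.attrs.get("wavelength")
            binning = CorrelationBinning(
                ShellGrid(f["radii"][...]), int(f.attrs["n_alpha"]),
                None if wl is None else float(wl))
            return cls(binning, f["counts"][...], int(f.attrs["total"]))


@dataclasses.dataclass
class TripletHistogram:
    """Counts over canonical triplet bins, dense (K, n_canon4)."""

    binning: CorrelationBinning
    counts: np.ndarray
    total: int = 0

    @classmethod
    def empty(cls, binning):
        return cls(binning, np.zeros((binning.grid.K, binning.canon_list.size)), 0)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("counts", data=self.counts)
            f.create_dataset("radii", data=self.binning.grid.radii)
            f.attrs["n_alpha"] = self.binning.n_alpha
            f.attrs["total"] = self.total
            if self.binning.wavelength is not None:
                f.attrs["wavelength"] = self.binning.wavelength

    @classmethod
    def load(cls, path):
        with h5py.File(path, "r") as f:
            wl = f.attrs.get("wavelength")
            binning = CorrelationBinning(
                ShellGrid(f["radii"][...]), int(f.attrs["n_alpha"]),
                None if wl is None else float(wl))
            return cls(binning, f["counts"][...], int(f.attrs["total"]))


# --------------------------------------------------------------------------
# extraction

def _photon_polar(photons: np.ndarray, binning: CorrelationBinning):
    k = np.hypot(photons[:, 0], photons[:, 1])
    phi = np.arctan2(photons[:, 1], photons[:, 0])
    s = binning.grid.assign(k)
    keep = s >= 0
    return s[keep], phi[keep]


def _grouped_images(images, binning):
    """Yield (shells, azimuths) arrays of shape (n_img, P) grouped by count."""
    if isinstance(images, PhotonImage):
        images = [images]
    if isinstance(images, PhotonDataset):
        s_all, phi_all = _photon_polar(images.photons, binning)
        keep = binning.grid.assign(
            np.hypot(images.photons[:, 0], images.photons[:, 1])) >= 0
        counts = np.zeros(images.n_images, dtype=np.int64)
        img_of = np.repeat(np.arange(images.n_images), images.counts)[keep]
        np.add.at(counts, img_of, 1)
        order = np.argsort(img_of, kind="stable")
        s_all, phi_all = s_all[order], phi_all[order]
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for p in np.unique(counts):
            if p < 2:
                continue
            sel = np.flatnonzero(counts == p)
            idx = (offsets[sel][:, None] + np.arange(p)[None, :]).ravel()
            yield s_all[idx].reshape(-1, p), phi_all[idx].reshape(-1, p)
    else:
        for im in images:
            s, phi = _photon_polar(np.asarray(im.photons, dtype=float), binning)
            if s.size >= 2:
                yield s.reshape(1, -1), phi.reshape(1, -1)


def extract_triplets(images, binning: CorrelationBinning,
                     hist: TripletHistogram | None = None) -> TripletHistogram:
    """Accumulate the canonical triplet histogram from images.

    Images with fewer than three in-range photons contribute nothing.
    """
    if hist is None:
        hist = TripletHistogram.empty(binning)
    K, H, A = binning.grid.K, binning.n_alpha, binning.A
    n4 = binning.n4
    flat = np.zeros(K * n4, dtype=np.float64)
    total = 0
    for S, PHI in _grouped_images(images, binning):
        p = S.shape[1]
        if p < 3:
            continue
        # each unordered triple {u,v,w}: three refs, pair = the other two
        ref, p2, p3 = [], [], []
        for u in range(p):
            others = [x for x in range(p) if x != u]
            ii, jj = np.triu_indices(p - 1, k=1)
            ref.extend([u] * len(ii))
            p2.extend([others[i] for i in ii])
            p3.extend([others[j] for j in jj])
        ref = np.array(ref); p2 = np.array(p2); p3 = np.array(p3)
        a = np.mod(PHI[:, p2] - PHI[:, ref], 2.0 * np.pi)
        b = np.mod(PHI[:, p3] - PHI[:, ref], 2.0 * np.pi)
        abin = binning.angle_bin(a)
        bbin = binning.angle_bin(b)
        s1 = S[:, ref]; s2 = S[:, p2]; s3 = S[:, p3]
        c4 = binning.canon_idx4[s2, abin, s3, bbin]
        codes = (s1 * n4 + c4).ravel()
        flat += np.bincount(codes, minlength=K * n4)
        total += codes.size
    hist.counts += flat.reshape(K, n4)[:, binning.canon_list]
    hist.total += total
    return hist


def extract_doublets(images, binning: CorrelationBinning,
                     hist: DoubletHistogram | None = None) -> DoubletHistogram:
    """Accumulate the doublet histogram (one entry per unordered pair)."""
    if hist is None:
        hist = DoubletHistogram.empty(binning)
    K, H = binning.grid.K, binning.n_alpha
    flat = np.zeros(K * K * H, dtype=np.float64)
    total = 0
    for S, PHI in _grouped_images(images, binning):
        p = S.shape[1]
        iu, ju = np.triu_indices(p, k=1)
        d = np.abs(PHI[:, iu] - PHI[:, ju])
        d = np.minimum(np.mod(d, 2 * np.pi), 2 * np.pi - np.mod(d, 2 * np.pi))
        abin = np.minimum((d / np.pi * H).astype(np.int64), H - 1)
        slo = np.minimum(S[:, iu], S[:, ju])
        shi = np.maximum(S[:, iu], S[:, ju])
        codes = ((slo * K + shi) * H + abin).ravel()
        flat += np.bincount(codes, minlength=K * K * H)
        total += codes.size
    hist.counts += flat.reshape(K, K, H)
    hist.total += total
    return hist


# --------------------------------------------------------------------------
# analytic correlations

def analytic_two_point(model: ShellIntensityModel, k1, k2, alpha,
                       wavelength: float | None = None):
    """Orientational average <I(R u1) I(R u2)>_R at detector separation alpha.

    Equals (4 pi)^-1 sum_l P_l(cos alpha*) sum_m A_lm(k1) A_lm(k2); k1, k2
    must lie on (or is snapped to) the model's shell radii.
    """
    wl = wavelength if wavelength is not None else model.wavelength
    if wl is None:
        raise ValueError("wavelength required for Ewald geometry")
    s1 = int(np.argmin(np.abs(model.grid.radii - k1)))
    s2 = int(np.argmin(np.abs(model.grid.radii - k2)))
    astar = ewald_alpha_star(model.grid.radii[s1], model.grid.radii[s2], alpha, wl)
    x = np.cos(astar)
    out = np.zeros_like(np.asarray(x, dtype=float))
    for l in sphharm.even_orders(model.L):
        cl = float(model.block(l)[:, s1] @ model.block(l)[:, s2])
        out = out + cl * _sp.eval_legendre(l, x)
    return out / (4.0 * np.pi)


def _legendre_theta_table(L: int, thetas: np.ndarray) -> dict:
    """lam[l][m+l, s] = Y_lm(theta_s, 0) (real numbers, scipy CS phase)."""
    lam = {}
    for l in range(L + 1):
        t = np.empty((2 * l + 1, thetas.size))
        for m in range(0, l + 1):
            p = np.asarray(_sp.sph_legendre_p(l, m, thetas)).reshape(thetas.shape)
            t[l + m] = p
            if m:
                t[l - m] = (-1.0) ** m * p
        lam[l] = t
    return lam


class TripleCorrelationEngine:
    """Evaluator of the analytic triple correlation on a fixed binning.

    Precomputes the geometry factor of the B x G factorization (see module
    docstring) for every canonical bin; ``table(model_coeffs)`` then returns
    the analytic t at all canonical bins, and ``point`` evaluates single
    arguments.  Intended for the moderate orders used in the annealing search
    (the precomputed term table scales as O(#l-triples x (2L+1)^2 x K^3)).
    """

    def __init__(self, grid: ShellGrid, L: int, binning: CorrelationBinning,
                 wavelength: float, bin_averaged: bool = True):
        if L % 2:
            raise ValueError("L must be even")
        self.grid, self.L, self.binning, self.wavelength = grid, L, binning, wavelength
        self.bin_averaged = bin_averaged
        self._radavg = grid.radial_average_matrix() if bin_averaged else None
        self.thetas = ewald_theta(grid.radii, wavelength)
        self.lam = _legendre_theta_table(L, self.thetas)
        evens = sphharm.even_orders(L)
        self.l_triples = [(l1, l2, l3)
                          for l1 in evens for l2 in evens for l3 in evens
                          if triangle_ok(l1, l2, l3)]
        self._build_B_tables()
        self._build_G_terms()

    # --- model side (B) ---------------------------------------------------

    def _build_B_tables(self):
        self._w3j_B = []
        for (l1, l2, l3) in self.l_triples:
            m1 = np.arange(-l1, l1 + 1)
            m2 = np.arange(-l2, l2 + 1)
            M1, M2 = np.meshgrid(m1, m2, indexing="ij")
            M3 = -(M1 + M2)
            ok = np.abs(M3) <= l3
            W = np.zeros(M1.shape)
            it = np.nditer([M1, M2], flags=["multi_index"])
            for a, b in it:
                if ok[it.multi_index]:
                    W[it.multi_index] = wigner_3j(l1, l2, l3, int(a), int(b), -int(a + b))
            self._w3j_B.append((W, np.clip(M3 + l3, 0, 2 * l3), ok))

    def _complex_blocks(self, coeffs: np.ndarray) -> dict:
        """Real packed (ncoef, K) -> complex a_l blocks, keyed by l."""
        out = {}
        for l in sphharm.even_orders(self.L):
            C = coeffs[sphharm.packed_slice(l)]
            out[l] = sphharm.real_to_complex_matrix(l) @ C
        return out

    def B_blocks(self, coeffs: np.ndarray) -> list[np.ndarray]:
        """B_{l1 l2 l3}(s1, s2, s3) for every l-triple; complex (K, K, K)."""
        a = self._complex_blocks(coeffs)
        out = []
        for (l1, l2, l3), (W, m3idx, ok) in zip(self.l_triples, self._w3j_B):
            a3g = a[l3][m3idx]                    # (2l1+1, 2l2+1, K)
            D = np.where(ok[..., None], W[..., None] * a3g, 0.0)
            B = np.einsum("ms,nt,mnu->stu", a[l1], a[l2], D, optimize=True)
            out.append(B)
        return out

    # --- geometry side (G) ------------------------------------------------

    def _build_G_terms(self):
        K, H, A = self.grid.K, self.binning.n_alpha, self.binning.A
        L = self.L
        terms = []  # (lt_index, m2, m3, V1 (K,), V2 (K,), V3 (K,))
        for it, (l1, l2, l3) in enumerate(self.l_triples):
            for m2 in range(-l2, l2 + 1):
                for m3 in range(-l3, l3 + 1):
                    m1 = -(m2 + m3)
                    if abs(m1) > l1:
                        continue
                    w = wigner_3j(l1, l2, l3, m1, m2, m3)
                    if w == 0.0:
                        continue
                    terms.append((it, m2, m3,
                                  w * self.lam[l1][l1 + m1],
                                  self.lam[l2][l2 + m2],
                                  self.lam[l3][l3 + m3]))
        mcode = np.array([(m2 + L) * (2 * L + 1) + (m3 + L) for _, m2, m3, *_ in terms])
        order = np.argsort(mcode, kind="stable")
        self._terms_lt = np.array([terms[i][0] for i in order])
        self._terms_mcode = mcode[order]
        V1 = np.stack([terms[i][3] for i in order])
        V2 = np.stack([terms[i][4] for i in order])
        V3 = np.stack([terms[i][5] for i in order])
        # W[j, s1, s2, s3] = V1[j,s1] V2[j,s2] V3[j,s3]
        self._W = (V1[:, :, None, None] * V2[:, None, :, None]
                   * V3[:, None, None, :])
        self._group_starts = np.concatenate(
            [[0], 1 + np.flatnonzero(np.diff(self._terms_mcode))])
        self._group_codes = self._terms_mcode[self._group_starts]
        # Fourier phase matrices at bin centers; with bin averaging each
        # harmonic picks up the exact factor sin(m w/2)/(m w/2)
        m = np.arange(-L, L + 1)
        self._E2 = np.exp(1j * np.outer(m, self.binning.alpha_centers_half))
        self._E3 = np.exp(1j * np.outer(m, self.binning.beta_centers_full))
        if self.bin_averaged:
            w = 2.0 * np.pi / A
            sinc = np.sinc(m * w / (2.0 * np.pi))
            self._E2 = self._E2 * sinc[:, None]
            self._E3 = self._E3 * sinc[:, None]

    def table(self, coeffs: np.ndarray) -> np.ndarray:
        """Analytic t at every canonical bin; shape (K, n_canon4), real.

        Negative values from the truncated expansion are preserved here;
        `normalize_correlation` applies the positivity floor.  With
        ``bin_averaged`` the table is the (near-exact) average of t over each
        bin -- the angular average via the sinc factors, the radial one by
        annulus-averaging the coefficients (the three radial factors of t are
        independent, so the average of the product factorizes).
        """
        K, H, A, L = self.grid.K, self.binning.n_alpha, self.binning.A, self.L
        if self.bin_averaged:
            coeffs = coeffs @ self._radavg.T
        B = self.B_blocks(coeffs)
        Bstack = np.stack(B)                       # (n_lt, K, K, K)
        P = Bstack[self._terms_lt] * self._W       # (n_terms, K, K, K)
        Fg = np.add.reduceat(P, self._group_starts, axis=0)
        F = np.zeros(((2 * L + 1) ** 2, K, K, K), dtype=complex)
        F[self._group_codes] = Fg
        F = F.reshape(2 * L + 1, 2 * L + 1, K, K, K)
        # t[s1, s2, s3, a, b] = Re sum_{m2 m3} F e^{i m2 a} e^{i m3 b}
        G1 = np.tensordot(F, self._E2, axes=([0], [0]))      # (2L+1, K,K,K, H)
        t = np.tensordot(G1, self._E3, axes=([0], [0]))      # (K,K,K,H,A)
        t = np.ascontiguousarray(t.real.transpose(0, 1, 3, 2, 4))  # s1,s2,a,s3,b
        return t.reshape(K, -1)[:, self.binning.canon_list]

    def point(self, coeffs: np.ndarray, s1: int, s2: int, s3: int,
              alpha, beta):
        """Analytic t(k_s1, k_s2, k_s3, alpha, beta) at arbitrary angles."""
        alpha = np.asarray(alpha, dtype=float)
        beta = np.asarray(beta, dtype=float)
        B = self.B_blocks(coeffs)
        out = np.zeros(np.broadcast(alpha, beta).shape, dtype=complex)
        for (l1, l2, l3), Bl in zip(self.l_triples, B):
            acc = 0.0
            for m2 in range(-l2, l2 + 1):
                for m3 in range(-l3, l3 + 1):
                    m1 = -(m2 + m3)
                    if abs(m1) > l1:
                        continue
                    w = wigner_3j(l1, l2, l3, m1, m2, m3)
                    if w == 0.0:
                        continue
                    acc = acc + (w * self.lam[l1][l1 + m1][s1]
                                 * self.lam[l2][l2 + m2][s2]
                                 * self.lam[l3][l3 + m3][s3]
                                 * np.exp(1j * (m2 * alpha + m3 * beta)))
            out = out + Bl[s1, s2, s3] * acc
        return out.real


def analytic_three_point(model: ShellIntensityModel, k1, k2, k3, alpha, beta,
                         wavelength: float | None = None,
                         engine: TripleCorrelationEngine | None = None):
    """Triple correlation t(k1, k2, k3, alpha, beta) of a shell model.

    The wavenumbers are snapped to the model's shell radii.  For repeated
    evaluation construct a `TripleCorrelationEngine` once and reuse it.
    """
    wl = wavelength if wavelength is not None else model.wavelength
    if wl is None:
        raise ValueError("wavelength required for Ewald geometry")
    if engine is None:
        binning = CorrelationBinning(model.grid, 2, wl)
        engine = TripleCorrelationEngine(model.grid, model.L, binning, wl,
                                         bin_averaged=False)
    s = [int(np.argmin(np.abs(model.grid.radii - k))) for k in (k1, k2, k3)]
    return engine.point(model.coeffs, s[0], s[1], s[2], alpha, beta)


def analytic_triplet_table(model: ShellIntensityModel,
                           binning: CorrelationBinning,
                           engine: TripleCorrelationEngine | None = None,
                           total: float = 1.0) -> TripletHistogram:
    """Expected ('infinite photon') triplet histogram of a model.

    Returns a TripletHistogram whose counts are the analytic bin
    probabilities scaled to ``total`` triplets.
    """
    wl = binning.wavelength or model.wavelength
    if engine is None:
        engine = TripleCorrelationEngine(model.grid, model.L, binning, wl)
    t = engine.table(model.coeffs)
    p = normalize_correlation(t, binning)
    return TripletHistogram(binning, p * total, total=total)


def normalize_correlation(t: np.ndarray, binning: CorrelationBinning) -> np.ndarray:
    """Turn a canonical-bin correlation table into bin probabilities.

    Multiplies by the bin measure (orbit size x radial annulus measures),
    floors slightly negative truncation artifacts at EPS_FLOOR x max, and
    normalizes to sum 1.  Invariant under positive rescaling of t.
    """
    t = np.asarray(t, dtype=float)
    m = t.max()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("correlation table has no positive entries")
    tc = np.maximum(t, EPS_FLOOR * m)
    q = tc * binning.triplet_bin_measure()
    return q / q.sum()
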