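"""Gaussian-atom intensities, shell expansion, and Ewald geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from triphoton import sphharm
from triphoton.intensity import (AtomSet, BeamGeometry, ShellGrid,
                                 count_basis_coefficients, ewald_theta,
                                 expand_on_shells, intensity_from_atoms)

rng = np.random.default_rng(2)


class TestIntensityFromAtoms:
    def test_single_atom_is_gaussian_envelope(self):
        atoms = AtomSet([[0.0, 0.0, 0.0]], [1.0], [0.8])
        pts = rng.normal(size=(20, 3))
        k2 = (pts ** 2).sum(1)
        assert intensity_from_atoms(atoms, pts) == pytest.approx(
            np.exp(-0.64 * k2), rel=1e-12)
        assert intensity_from_atoms(atoms, np.zeros((1, 3)))[0] == pytest.approx(1.0)

    def test_two_atom_interference_zero(self):
        d = 2.0
        atoms = AtomSet([[d / 2, 0, 0], [-d / 2, 0, 0]], [1.0, 1.0], [0.7, 0.7])
        k_zero = np.array([[np.pi / d, 0.0, 0.0]])
        assert intensity_from_atoms(atoms, k_zero)[0] == pytest.approx(0.0, abs=1e-20)
        k_max = np.array([[2 * np.pi / d, 0.0, 0.0]])
        assert intensity_from_atoms(atoms, k_max)[0] > 0

    def test_matches_dft_of_voxelized_density(self, toy_atoms):
        """Closed form vs brute-force DFT of the voxelized Gaussian density."""
        pts = rng.normal(scale=0.4, size=(100, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= 1.0]
        I = intensity_from_atoms(toy_atoms, pts)
        n, box = 64, 28.0
        dx = box / n
        ax = (np.arange(n) - n // 2) * dx
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        rho = np.zeros((n, n, n))
        for p, h, w in zip(toy_atoms.positions, toy_atoms.heights,
                           toy_atoms.widths):
            r2 = (X - p[0]) ** 2 + (Y - p[1]) ** 2 + (Z - p[2]) ** 2
            rho += h * np.exp(-r2 / (2 * w * w)) / (2 * np.pi * w * w) ** 1.5
        vox = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        rv = rho.ravel() * dx ** 3
        I_dft = np.array([np.abs((rv * np.exp(1j * (vox @ k))).sum()) ** 2
                          for k in pts])
        assert np.abs(I_dft - I).max() / I.max() < 1e-2
        assert (np.abs(I_dft - I) / np.maximum(I, 1e-12 * I.max())).max() < 1e-2

    def test_rotation_covariance(self, toy_atoms):
        R = Rotation.random(rng=rng).as_matrix()
        rotated = AtomSet(toy_atoms.positions @ R.T, toy_atoms.heights,
                          toy_atoms.widths)
        pts = rng.normal(scale=0.5, size=(50, 3))
        # intensity(R k) for rotated atoms equals intensity(k) for originals
        assert np.allclose(intensity_from_atoms(rotated, (R @ pts.T).T),
                           intensity_from_atoms(toy_atoms, pts), rtol=1e-10)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            AtomSet(np.empty((0, 3)), [], [])
        with pytest.raises(ValueError):
            AtomSet([[np.nan, 0, 0]], [1.0], [1.0])
        with pytest.raises(ValueError):
            AtomSet([[0, 0, 0]], [1.0], [0.0])


class TestExpandOnShells:
    def test_isotropic_input_only_l0(self):
        grid = ShellGrid.uniform(6, 1.5)
        f = lambda p: np.exp(-np.linalg.norm(p, axis=1) ** 2)
        model = expand_on_shells(f, grid, 4)
        assert model.coeffs[0] == pytest.approx(
            np.sqrt(4 * np.pi) * np.exp(-grid.radii ** 2), rel=1e-12)
        assert np.abs(model.coeffs[1:]).max() < 1e-13

    def test_single_mode_recovered_as_unit_vector(self):
        grid = ShellGrid.uniform(1, 1.0)
        f = lambda p: sphharm.real_sh_mode(
            4, 2, *sphharm.vectors_to_angles(p))
        model = expand_on_shells(f, grid, 6)
        expected = np.zeros(sphharm.n_even_coeffs(6))
        expected[sphharm.packed_offset(4) + 4 + 2] = 1.0
        assert model.coeffs[:, 0] == pytest.approx(expected, abs=1e-12)

    def test_roundtrip_on_band_limited_toy(self, toy_atoms):
        """Expand at L=8 and re-evaluate on random sphere points."""
        grid = ShellGrid.uniform(6, 1.2)
        ev = lambda p: intensity_from_atoms(toy_atoms, p)
        model = expand_on_shells(ev, grid, 8)
        th = rng.uniform(0.05, 3.09, 50)
        ph = rng.uniform(0, 2 * np.pi, 50)
        dirs = sphharm.angles_to_vectors(th, ph)
        for s in [0, 2, 4]:
            direct = ev(grid.radii[s] * dirs)
            via = model.evaluate_on_shell(s, th, ph)
            assert np.abs(direct - via).max() / direct.max() < 1e-2

    def test_parseval_per_shell(self, toy_model):
        th, ph, w = sphharm.sphere_quadrature(20, 41)
        for s in [1, 5]:
            vals = toy_model.evaluate_on_shell(s, th, ph)
            lhs = (w * vals ** 2).sum()
            rhs = (toy_model.coeffs[:, s] ** 2).sum()
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_odd_l_projection_of_friedel_input_vanishes(self, toy_atoms):
        # project the (Friedel-symmetric) intensity on odd harmonics directly
        th, ph, w = sphharm.sphere_quadrature(20, 41)
        dirs = sphharm.angles_to_vectors(th, ph)
        vals = intensity_from_atoms(toy_atoms, 1.1 * dirs)
        for l, m in [(1, 0), (3, 2), (5, -4)]:
            proj = (w * vals * sphharm.real_sh_mode(l, m, th, ph)).sum()
            assert abs(proj) < 1e-10 * vals.max()

    def test_rotating_atoms_rotates_coefficients(self, toy_atoms):
        grid = ShellGrid.uniform(4, 1.2)
        R = Rotation.random(rng=rng).as_matrix()
        # dense quadrature so that aliasing of the non-band-limited input
        # does not mask the covariance identity
        m1 = expand_on_shells(
            lambda p: intensity_from_atoms(toy_atoms, p), grid, 4,
            n_theta=40, n_phi=80)
        rotated = AtomSet(toy_atoms.positions @ R.T, toy_atoms.heights,
                          toy_atoms.widths)
        m2 = expand_on_shells(
            lambda p: intensity_from_atoms(rotated, p), grid, 4,
            n_theta=40, n_phi=80)
        assert np.abs(m2.coeffs - m1.rotated(R).coeffs).max() \
            < 1e-10 * np.abs(m1.coeffs).max()

    def test_odd_L_rejected(self):
        with pytest.raises(ValueError):
            expand_on_shells(lambda p: np.ones(len(p)), ShellGrid.uniform(2, 1.0), 5)

    def test_insufficient_quadrature_rejected(self):
        with pytest.raises(ValueError):
            expand_on_shells(lambda p: np.ones(len(p)),
                             ShellGrid.uniform(2, 1.0), 8, n_theta=4)


class TestGeometry:
    def test_ewald_theta_limits_and_value(self):
        assert ewald_theta(0.0, 2.5) == pytest.approx(np.pi / 2)
        assert ewald_theta(4 * np.pi / 2.5, 2.5) == pytest.approx(0.0)
        assert ewald_theta(2.15, 2.5) == pytest.approx(
            np.arccos(2.15 * 2.5 / (4 * np.pi)), abs=1e-12)
        assert ewald_theta(2.15, 2.5) == pytest.approx(1.1288, abs=5e-4)
        k = np.linspace(0, 4 * np.pi / 2.5, 50)
        assert (np.diff(ewald_theta(k, 2.5)) < 0).all()

    def test_ewald_theta_domain_error(self):
        with pytest.raises(ValueError):
            ewald_theta(6.0, 2.5)
        with pytest.raises(ValueError):
            ewald_theta(-0.1, 2.5)

    def test_beam_geometry_validation(self):
        g = BeamGeometry(2.5, 2.15)
        assert g.k_in == pytest.approx(2 * np.pi / 2.5)
        with pytest.raises(ValueError):
            BeamGeometry(2.5, 2 * g.k_in + 0.1)

    def test_shell_grid_assignment(self):
        grid = ShellGrid.uniform(4, 2.0)
        assert grid.radii == pytest.approx([0.5, 1.0, 1.5, 2.0])
        assert list(grid.assign([0.1, 0.74, 0.76, 1.99, 2.01])) == [0, 0, 1, 3, -1]
        assert grid.annulus_measure.sum() == pytest.approx(2.0)

    def test_radial_average_matrix_rowsums(self, shell_grid):
        M = shell_grid.radial_average_matrix()
        assert M.sum(axis=1) == pytest.approx(np.ones(shell_grid.K), rel=1e-12)
        # constant profile is preserved exactly
        assert M @ np.ones(shell_grid.K) == pytest.approx(np.ones(shell_grid.K))


def test_count_basis_coefficients():
    assert count_basis_coefficients(18, 26) == 4940
    assert count_basis_coefficients(0, 1) == 1
    assert count_basis_coefficients(4, 3) == 45
    # oracle: explicit enumeration
    for L, K in [(2, 2), (6, 5), (10, 3)]:
        n = sum(2 * l + 1 for l in range(0, L + 1, 2)) * K
        assert count_basis_coefficients(L, K) == n
    with pytest.raises(ValueError):
        count_basis_coefficients(3, 2)
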