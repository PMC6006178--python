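"""Doublet/triplet extraction and analytic correlation functions."""

import numpy as np
import pytest
import scipy.stats as st
from scipy.spatial.transform import Rotation

from triphoton import sphharm
from triphoton.correlate import (CorrelationBinning, TripleCorrelationEngine,
                                 analytic_three_point, analytic_triplet_table,
                                 analytic_two_point, doublets_per_image,
                                 ewald_alpha_star, extract_doublets,
                                 extract_triplets, images_for_photon_budget,
                                 normalize_correlation, triplet_budget,
                                 triplets_per_image)
from triphoton.intensity import ShellGrid, ShellIntensityModel
from triphoton.simulate import PhotonImage, ewald_project, simulate_dataset
from tests.conftest import WAVELENGTH


def _image(photons):
    return PhotonImage(np.asarray(photons, dtype=float))


class TestBookkeeping:
    def test_triplet_and_doublet_counts_per_image(self):
        assert triplets_per_image(10) == 360
        assert triplets_per_image(3) == 3
        assert triplets_per_image(2) == 0
        assert doublets_per_image(10) == 45

    def test_reference_scale_budgets(self):
        # 3.3e9 ten-photon images -> 1.2e12 triplets
        assert triplet_budget(3_300_000_000, 10) == 1_188_000_000_000
        # 5.1e7 photons at P = 10 -> 1.8e9 triplets
        n = images_for_photon_budget(5.1e7, 10)
        assert triplet_budget(n, 10) == 1_836_000_000
        # 100 photons/image shrinks a 3.3e10 budget to 3.3e8 photons
        assert images_for_photon_budget(3.3e8, 100) == 3_300_000


class TestExtraction:
    def test_ordered_triplet_multiplicity(self, binning):
        rng = np.random.default_rng(0)
        ph = rng.uniform(-1, 1, (3, 2))
        h = extract_triplets(_image(ph), binning)
        assert h.total == 3
        assert h.counts.sum() == 3
        h2 = extract_triplets(_image(rng.uniform(-1, 1, (10, 2))), binning)
        assert h2.total == 360
        h1 = extract_triplets(_image(rng.uniform(-1, 1, (2, 2))), binning)
        assert h1.total == 0

    def test_doublet_counts_and_zero_angle(self, binning):
        rng = np.random.default_rng(1)
        h = extract_doublets(_image(rng.uniform(-1, 1, (10, 2))), binning)
        assert h.total == 45
        same = _image([[0.5, 0.5], [0.5, 0.5]])
        h0 = extract_doublets(same, binning)
        assert h0.counts[:, :, 0].sum() == 1  # alpha = 0 bin

    def test_photons_beyond_cutoff_discarded(self, binning):
        k_big = binning.grid.k_cut * 1.5
        img = _image([[k_big, 0], [0.5, 0], [0, 0.5], [0.3, 0.3]])
        h = extract_triplets(img, binning)
        assert h.total == triplets_per_image(3)

    def test_dataset_and_image_paths_agree(self, toy_model, geometry, binning):
        ds = simulate_dataset(toy_model, geometry, 50, 7,
                              np.random.default_rng(2))
        h_ds = extract_triplets(ds, binning)
        h_im = None
        for im in ds:
            h_im = extract_triplets(im, binning, h_im)
        assert np.array_equal(h_ds.counts, h_im.counts)

    def test_histogram_io_roundtrip(self, toy_model, geometry, binning, tmp_path):
        ds = simulate_dataset(toy_model, geometry, 30, 6,
                              np.random.default_rng(3))
        h = extract_triplets(ds, binning)
        h.save(tmp_path / "t.h5")
        from triphoton.correlate import TripletHistogram
        back = TripletHistogram.load(tmp_path / "t.h5")
        assert np.array_equal(back.counts, h.counts)
        assert back.total == h.total


class TestEwaldAlphaStar:
    def test_flat_ewald_limit_identity(self):
        a = np.linspace(0, np.pi, 7)
        assert ewald_alpha_star(1.0, 1.3, a, 1e-8) == pytest.approx(a, abs=1e-4)

    def test_zero_separation(self):
        assert ewald_alpha_star(2.15, 2.15, 0.0, 2.5) == pytest.approx(0.0)

    def test_curved_value(self):
        th = np.arccos(2.15 * 2.5 / (4 * np.pi))
        expected = np.arccos(np.cos(th) ** 2)
        got = ewald_alpha_star(2.15, 2.15, np.pi / 2, 2.5)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.3867, abs=2e-3)


class TestAnalyticCorrelations:
    def test_two_point_isotropic_constant(self):
        grid = ShellGrid.uniform(3, 1.0)
        coeffs = np.zeros((1, 3))
        coeffs[0] = [2.0, 1.0, 0.5]
        model = ShellIntensityModel(grid, 0, coeffs, wavelength=2.5)
        a = np.linspace(0, np.pi, 5)
        c = analytic_two_point(model, grid.radii[0], grid.radii[2], a)
        assert np.ptp(c) < 1e-14
        assert c[0] == pytest.approx(2.0 * 0.5 / (4 * np.pi))

    def test_two_point_symmetric_in_shells(self, toy_model_l4):
        r = toy_model_l4.grid.radii
        a = 0.7
        assert analytic_two_point(toy_model_l4, r[1], r[3], a) == pytest.approx(
            analytic_two_point(toy_model_l4, r[3], r[1], a))

    def test_two_point_matches_monte_carlo(self, toy_model_l4):
        """<I(R u1) I(R u2)>_R oracle at a few arguments."""
        rng = np.random.default_rng(4)
        R = Rotation.random(120_000, rng=rng).as_matrix()
        r = toy_model_l4.grid.radii
        for (s1, s2, a) in [(1, 3, 0.7), (2, 2, 2.2), (0, 4, 1.4)]:
            u1 = ewald_project([[r[s1], 0.0]], WAVELENGTH)[0]
            u2 = ewald_project([[r[s2] * np.cos(a), r[s2] * np.sin(a)]],
                               WAVELENGTH)[0]
            vals = (toy_model_l4.evaluate(R @ u1) * toy_model_l4.evaluate(R @ u2))
            mc, se = vals.mean(), vals.std() / np.sqrt(len(vals))
            an = analytic_two_point(toy_model_l4, r[s1], r[s2], a)
            assert abs(an - mc) < 3 * se

    def test_three_point_isotropic_independent_of_angles(self):
        grid = ShellGrid.uniform(3, 1.0)
        coeffs = np.zeros((1, 3))
        coeffs[0] = [2.0, 1.0, 0.5]
        model = ShellIntensityModel(grid, 0, coeffs, wavelength=2.5)
        vals = [analytic_three_point(model, 0.33, 0.66, 1.0, a, b)
                for a, b in [(0.1, 0.5), (2.0, 4.0), (3.0, 1.0)]]
        assert np.ptp(vals) < 1e-12 * abs(vals[0])

    def test_three_point_matches_monte_carlo(self, toy_model_l4):
        """Central correctness check: Eq.-style SH contraction vs brute-force
        orientational average (dedicated acceptance test runs 1e6 rotations;
        this unit test uses fewer)."""
        rng = np.random.default_rng(5)
        R = Rotation.random(150_000, rng=rng).as_matrix()
        r = toy_model_l4.grid.radii
        for (s1, s2, s3, a, b) in [(1, 3, 2, 0.7, 2.5), (2, 2, 4, 1.9, 0.9)]:
            u1 = ewald_project([[r[s1], 0.0]], WAVELENGTH)[0]
            u2 = ewald_project([[r[s2] * np.cos(a), r[s2] * np.sin(a)]],
                               WAVELENGTH)[0]
            u3 = ewald_project([[r[s3] * np.cos(b), r[s3] * np.sin(b)]],
                               WAVELENGTH)[0]
            vals = (toy_model_l4.evaluate(R @ u1) * toy_model_l4.evaluate(R @ u2)
                    * toy_model_l4.evaluate(R @ u3))
            mc, se = vals.mean(), vals.std() / np.sqrt(len(vals))
            an = analytic_three_point(toy_model_l4, r[s1], r[s2], r[s3], a, b)
            assert abs(an - mc) < 3 * se

    def test_three_point_invariant_under_global_rotation(self, toy_model_l4):
        R = Rotation.random(rng=np.random.default_rng(6)).as_matrix()
        rot = toy_model_l4.rotated(R)
        r = toy_model_l4.grid.radii
        a0 = analytic_three_point(toy_model_l4, r[1], r[2], r[3], 0.8, 2.0)
        a1 = analytic_three_point(rot, r[1], r[2], r[3], 0.8, 2.0)
        assert a1 == pytest.approx(a0, rel=1e-10)

    def test_three_point_swap_symmetry(self, toy_model_l4):
        r = toy_model_l4.grid.radii
        assert analytic_three_point(toy_model_l4, r[1], r[2], r[3], 0.8, 2.0) \
            == pytest.approx(
                analytic_three_point(toy_model_l4, r[1], r[3], r[2], 2.0, 0.8),
                rel=1e-10)

    def test_table_matches_point_evaluation(self, toy_model_l4):
        grid = toy_model_l4.grid
        binning = CorrelationBinning(grid, n_alpha=6, wavelength=WAVELENGTH)
        eng = TripleCorrelationEngine(grid, 4, binning, WAVELENGTH,
                                      bin_averaged=False)
        t = eng.table(toy_model_l4.coeffs)
        cl = binning.canon_list
        K, H, A = grid.K, binning.n_alpha, binning.A
        rng = np.random.default_rng(7)
        for ci in rng.integers(0, cl.size, 6):
            c = cl[ci]
            s2, a = c // (H * K * A), (c // (K * A)) % H
            s3, b = (c // A) % K, c % A
            tp = eng.point(toy_model_l4.coeffs, 1, s2, s3,
                           binning.alpha_centers_half[a],
                           binning.beta_centers_full[b])
            assert t[1, ci] == pytest.approx(float(tp), rel=1e-10)


class TestNormalization:
    def test_scale_invariance(self, toy_model, binning, engine):
        t = engine.table(toy_model.coeffs)
        p1 = normalize_correlation(t, binning)
        p2 = normalize_correlation(13.7 * t, binning)
        assert p1.sum() == pytest.approx(1.0)
        assert np.abs(p1 - p2).max() < 1e-15

    def test_uniform_table_stays_uniform_per_measure(self, binning):
        t = np.ones((binning.grid.K, binning.canon_list.size))
        p = normalize_correlation(t, binning)
        w = binning.triplet_bin_measure()
        assert np.abs(p / (w / w.sum()) - 1).max() < 1e-12

    def test_all_zero_rejected(self, binning):
        with pytest.raises(ValueError):
            normalize_correlation(
                np.zeros((binning.grid.K, binning.canon_list.size)), binning)

    def test_isotropic_model_shell_independence(self):
        """For an isotropic model the triplet probability factorizes into the
        per-shell photon probabilities."""
        grid = ShellGrid.uniform(4, 1.4)
        coeffs = np.sqrt(4 * np.pi) * np.exp(-grid.radii ** 2)[None, :]
        model = ShellIntensityModel(grid, 0, coeffs, wavelength=WAVELENGTH)
        binning = CorrelationBinning(grid, n_alpha=4, wavelength=WAVELENGTH)
        tab = analytic_triplet_table(model, binning)
        # the reference-shell marginal is the single-photon shell law; the
        # joint over (s1, unordered {s2, s3}) factorizes into its products
        K, H, A = grid.K, binning.n_alpha, binning.A
        cl = binning.canon_list
        s2 = cl // (H * K * A)
        s3 = (cl // A) % K
        lo, hi = np.minimum(s2, s3), np.maximum(s2, s3)
        p = tab.counts
        m1 = p.sum(axis=1)
        assert m1.sum() == pytest.approx(1.0)
        for i in range(K):
            for s in range(K):
                for u in range(s, K):
                    joint = p[i, (lo == s) & (hi == u)].sum()
                    mult = 1.0 if s == u else 2.0
                    assert joint == pytest.approx(
                        m1[i] * mult * m1[s] * m1[u] / m1.sum() ** 2, abs=1e-12)


class TestHistogramConsistency:
    def test_multinomial_sampling_matches_table(self, toy_model, binning, engine):
        """Exact chi-square: triplets drawn from t~ land in canonical bins
        with the predicted frequencies (validates folding/canonicalization)."""
        p = normalize_correlation(engine.table(toy_model.coeffs), binning).ravel()
        rng = np.random.default_rng(8)
        n = 400_000
        obs = rng.multinomial(n, p)
        exp = n * p
        mask = exp > 10
        chi2 = ((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum()
        assert st.chi2.sf(chi2, mask.sum() - 1) > 0.01

    def test_simulated_triplets_match_table(self, toy_model, geometry, binning,
                                            engine):
        """Simulator-derived histogram vs the bin-averaged analytic table.
        Within-image photon sharing and per-shot normalization leave a mild
        overdispersion, so the criterion is chi2/dof rather than a strict
        p-value (see methods note)."""
        ds = simulate_dataset(toy_model, geometry, 30_000, 6,
                              np.random.default_rng(9))
        h = extract_triplets(ds, binning)
        p = normalize_correlation(engine.table(toy_model.coeffs), binning)
        exp = p * h.total
        mask = exp > 20
        chi2 = (((h.counts - exp) ** 2 / np.maximum(exp, 1))[mask]).sum()
        assert chi2 / mask.sum() < 1.5

    def test_empirical_isotropic_doublet_angle_marginal(self, geometry):
        """Isotropic model: doublet angle marginal is flat in the flat-Ewald
        sense predicted by the analytic l = 0 correlation."""
        grid = ShellGrid.uniform(4, 1.4)
        coeffs = np.sqrt(4 * np.pi) * np.exp(-grid.radii ** 2)[None, :]
        model = ShellIntensityModel(grid, 0, coeffs, wavelength=WAVELENGTH)
        from triphoton.intensity import BeamGeometry
        geom = BeamGeometry(WAVELENGTH, 1.4)
        binning = CorrelationBinning(grid, n_alpha=8, wavelength=WAVELENGTH)
        ds = simulate_dataset(model, geom, 10_000, 8, np.random.default_rng(10))
        h = extract_doublets(ds, binning)
        marg = h.counts.sum(axis=(0, 1))
        expected = np.full(binning.n_alpha, marg.sum() / binning.n_alpha)
        chi2 = ((marg - expected) ** 2 / expected).sum()
        assert st.chi2.sf(chi2, binning.n_alpha - 1) > 0.01
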