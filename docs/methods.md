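# Methods

This note documents the models, conventions, parameter choices and known
limitations of the triphoton package.

## Scattering model

The molecule is a sum of isotropic Gaussians, one per (non-hydrogen) atom,
with element-dependent height h (≈ electron count) and width σ_a (0.8–1.05 Å
by default). Its intensity has the closed form
I(**k**) = |Σ_j h_j exp(−σ_j²|k|²/2) exp(i**k**·x_j)|², used both directly
and as the evaluator for the shell-wise expansion. Multi-Gaussian form
factors, B-factors, solvent envelopes and anomalous scattering are out of
scope. The default element table is a single-Gaussian stand-in for atomic
form factors; all pipeline experiments are self-consistent against the same
table, so its exact values only set an overall contrast.

Detector geometry is idealized: a photon at radial wavenumber k and azimuth
φ lies on the Ewald sphere at polar angle θ = arccos(kλ/4π) (θ = π/2 at the
beam axis); there is no pixelation, panel gaps or mask. All wavenumbers use
k_in = 2π/λ; the default beam is λ = 2.5 Å (5 keV) with cutoff
k_cut = 2.15 Å⁻¹.

## Spherical-harmonic conventions

Real orthonormal harmonics without the Condon–Shortley phase; the intensity
of a real density is Friedel-symmetric, so only even orders l ≤ L are
stored — (L²+3L+2)/2 real coefficients per shell. Rotations act through
real Wigner-D block matrices computed by exact spherical quadrature
(Gauss–Legendre × uniform azimuth, degree 2l). Shell radii are K equally
spaced wavenumbers in (0, k_cut]; radial behaviour between shells is linear
interpolation, clamped inward of the innermost shell for the simulator and
zero outside the band for phasing.

## Photon simulation

Each image draws a Haar-uniform orientation and exactly P photons (default;
Poisson(P) available) from the Ewald slice of the rotated intensity by
rejection sampling: proposals from a 2D Gaussian of width 1.05 Å⁻¹
truncated at k_cut, accepted with probability I/(M·G). The envelope
constant M is computed numerically from the orientation-*independent*
radial maximum of the model (times a 1.5 safety factor), which guarantees a
valid bound for every orientation at some cost in acceptance ratio; a
detected bound violation enlarges M and resamples the affected images. The
noise channel replaces each photon with probability γ by a draw from the
truncated radial Gaussian G(k, σ) with uniform azimuth ("substitute" mode,
keeping the photon count at P; an "append" mode is provided since either
reading of "a fraction γ of random photons" is defensible).

What the simulator does *not* emulate: beam-fluence fluctuations (the
correlations are insensitive to them by construction), incoherent-
scattering physics beyond the Gaussian radial law, detector noise, and
multi-particle hits.

## Correlation histograms

Every unordered photon triple contributes three ordered triplets — each
photon once in the reference role — giving P(P−1)(P−2)/2 per image (360 for
P = 10; the budget arithmetic follows, e.g. 1.188×10¹²
triplets from 3.3×10⁹ ten-photon images). Angles are binned on the full
circle in 2·n_alpha uniform bins (n_alpha = 16 default on the folded
domain), then folded by the joint mirror (α,β) → (2π−α, 2π−β) — exact for
even-l intensities — and by the (k₂,α) ↔ (k₃,β) relabelling; counts and
analytic tables live on the same canonical bins. Shells are assigned by
nearest radius; photons beyond k_cut are discarded at extraction.

The analytic tables are **bin-averaged**, not bin-center evaluations: the
angular average of each Fourier mode e^{imα} over a bin is an exact
sinc factor, and the radial average over a shell's capture annulus is a
linear map M on the coefficient profiles (the three radial factors of t are
independent, so the average of the product factorizes). This reduced the
systematic histogram/table discrepancy by roughly a factor 7 on the toy
problems. Conversely, the empirical Kam inversion *deconvolves* M
(cond ≈ 2) so that recovered coefficients refer to shell-point values.

Two residual approximations are inherent to the likelihood model and show
up as mild overdispersion (χ²/dof ≈ 1.2–1.8) when comparing simulated
histograms with t̃ at high statistics: triplets within an image share
photons (correlated counts), and photons are drawn from the per-orientation
*normalized* slice while t is the unnormalized average (the slice integral
varies by ~7% rms over orientations on the toy). Neither biases the
location of the likelihood optimum appreciably at the scales tested; the
exact-consistency test therefore samples triplets from t̃ itself, and the
simulator-based test uses a χ²/dof tolerance.

## Kam inversion

c(k₁,k₂,α) is projected on even Legendre polynomials in cos α*. Because the
Ewald curvature restricts cos α* to [cos(θ₁+θ₂), cos(θ₁−θ₂)], the
projection is a least-squares fit on the accessible interval — exact for
band-limited input, and guarded by a conditioning check (error above
cond 10⁸). Each C_l is eigendecomposed; eigenvector signs are fixed
deterministically (largest-magnitude component positive), the l = 0 profile
is taken nonnegative, and rows beyond min(2l+1, K) are zero. Small negative
eigenvalues (noise, truncation) are clamped with a warning.

**Search group.** The per-order transform linking the eigenbasis to the
truth is orthogonal but *not* necessarily special-orthogonal: with a fixed
sign convention the required U_l has det −1 for about half the orders of a
generic problem, and this det signature is invariant under the global
rotations that connect equivalent solutions (all D_l(R) have det +1 on
even-l spaces). The Metropolis chain therefore proposes continuous rotation
steps (the l(2l+1) angles that define the search-space counting) plus
occasional single-eigendirection reflections, i.e. it explores O(2l+1).

## Simulated annealing

E = −Σ_bins count·log t̃ over canonical bins (identical to the per-triplet
sum, O(bins) instead of O(T)). Defaults, all configurable and logged:
T(j) = T_init exp(−j/τ) with T_init calibrated to the energy standard
deviation of 40 random rotation sets and τ = n_steps/10 (the temperature
must decay for annealing; a printed protocol with growing temperature is
treated as a sign slip); Boltzmann acceptance exp(−ΔE/T); all orders
perturbed per step by exp(β_l S_l) with S_l random unit-Frobenius skew
matrices and β_l(0) = 0.3/√(2l+1); β_l × μ^±1 (μ = 1.05) on
acceptance/rejection, clipped to [10⁻⁵, 0.7]; hierarchical freeze-out
multiplies β_l by exp(−j·L/(3τ·l)) so low orders settle first; per-order
reflection proposals with probability 0.1 per step; re-orthonormalization
every 200 steps. On the L = 6, K = 8 toy with the analytic table, 1500
steps converge to aligned intensity Pearson ≥ 0.95 in ≥ 16/20 seeded runs
(typically 20/20 at ≈ 0.99).

## Phasing

The recovered model is evaluated on a 64³ Fourier grid (dk set so k_cut
sits just inside Nyquist; negative truncation artifacts clamped, the region
below the innermost shell and beyond k_cut left unmeasured and
unconstrained). RAAR with β = 0.92, 400 iterations, real nonnegative
density, fixed centred spherical support (default 1.2 × molecule radius
+ 2 Å; no shrinkwrap), 8 random-phase restarts averaged in real space after
translation/inversion alignment. β, the iteration count and the grid were
chosen by a small numerical study phasing both ideal and perturbed toy
intensities; β = 0.87 works, β = 0.92 averaged ≈ 0.01–0.03 higher density
correlations. Non-convergence is reported through the Fourier-residual
trace, never raised.

## Evaluation

Recovered intensities are aligned to the reference by maximizing the
intensity Pearson correlation over SO(3) (4608-rotation coarse grid ranked
by the coefficient overlap Σ_l ⟨D_l(R), M_l⟩, then Nelder–Mead refinement);
even-l intensities carry no hand information, so inversion is only searched
at the density level. FSC uses one-voxel shells and the real part of the
cross-spectrum; resolution is the first downward FSC = 0.5 crossing,
linearly interpolated, Δr = 2π/k_res (band-limit value with a flag when
there is no crossing). ISC is the per-shell Pearson correlation with shell
means removed.

## Toy study conditions and what they show

The acceptance experiments use a 5-atom molecule in a 6 Å box with L = 6,
K = 8, k_cut = 2.15 Å⁻¹ — sized so the recovery order is close to
band-limiting (L ≈ k_cut·R), the same consistency a cluster-scale run
would maintain at L = 18 for a ~20 Å protein; images are generated from an
L = 10 expansion so the generator is strictly richer than the recovery
model. 10⁵ ten-photon images (3.6×10⁷ triplets) give density
cross-correlations ≈ 0.86 and resolutions within ~2% of the band limit;
the infinite-photon control recovers intensities at Pearson ≈ 0.99.
Passing these tests demonstrates the estimator chain end to end at toy
scale; it does not by itself establish the photon counts, noise levels or
angular orders needed for a real protein at near-atomic resolution, which
require cluster-scale statistics.

## Known limitations

- Triple-correlation tables scale as O(#l-triples · (2L+1)² · K³); the
  engine is sized for the annealing regime L ≲ 10, K ≲ 16 on one CPU.
  Cluster-scale L = 18, K = 26 is supported by the analytic machinery but not
  desk-practical for full pipeline runs.
- The likelihood ignores per-shot normalization of the slice density and
  within-image triplet correlations (see above).
- Fixed spherical support and real-space positivity in phasing; no
  shrinkwrap.
- Single-particle images only; mixtures and multi-particle shots are not
  decomposed.
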