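# triphoton

De novo 3D structure determination from single-molecule X-ray scattering
images that contain only a handful of coherently scattered photons each.

## The problem

In single-particle XFEL imaging, a stream of identical molecules in random,
unknown orientations is hit by femtosecond X-ray pulses. For a small protein
at realistic beam fluence, each shot scatters only ~3–100 photons — far too
few to orient individual images. Structural information survives, however,
in photon *correlations* accumulated across billions of shots: pairs and
triples of photons from one shot probe the 3D intensity I(**k**) = |FT[ρ]|²
at two or three points of the same (unknown) Ewald-sphere section. The
two-photon correlation alone does not determine I; the full three-photon
correlation does.

## Method

Each shot's photon triples are reduced to the orientation-independent
summary (k₁, k₂, k₃, α, β): three radial wavenumbers and two detector-plane
angles measured from a reference photon (P photons give P(P−1)(P−2)/2
triplets). With a shell-wise real spherical-harmonic expansion
I(**k**) = Σ A_lm(k) Y_lm(θ, φ) (even l ≤ L on K shells, Friedel symmetry),
the analytic triple correlation is the Haar average

    t(k₁,k₂,k₃,α,β) = ⟨ I(R u₁) I(R u₂) I(R u₃) ⟩_R
                    = Σ_{l₁l₂l₃} B_{l₁l₂l₃}(k₁,k₂,k₃) · G_{l₁l₂l₃}(k₁,k₂,k₃,α,β),

a double Wigner-3j contraction in which B carries the coefficients and G
only Ewald geometry. Recovery proceeds in three stages:

1. **Kam inversion.** The two-photon correlation
   c(k₁,k₂,α) = (4π)⁻¹ Σ_l P_l(cos α*) Σ_m A_lm(k₁)A_lm(k₂), with the
   Ewald-corrected angle α*, is Legendre-projected into per-order Gram
   matrices C_l and eigendecomposed into coefficient vectors A⁰_l(k) known
   up to one orthogonal matrix U_l per order. This shrinks the unknowns
   from K(L²+3L+2)/2 coefficients (4940 at L=18, K=26) to
   Σ_l l(2l+1) = 2370 rotation angles at L=18.
2. **Simulated annealing.** The remaining rotations maximize the triplet
   likelihood: E({U_l}) = −Σ_bins count · log t̃, with t̃ the normalized
   analytic triple correlation of A_l = U_l A⁰_l; Metropolis steps with
   exponentially decaying temperature, adaptive per-order step sizes, and
   hierarchical freeze-out of low orders.
3. **Phasing and scoring.** The recovered intensity is evaluated on a cubic
   Fourier grid and phased by RAAR under a spherical support (several
   random restarts averaged in real space); resolution is read off the
   Fourier shell correlation at FSC = 0.5, Δr = 2π/k_res.

A forward photon simulator (Haar-random orientations, rejection sampling
from the Ewald slice, optional Gaussian noise channel of fraction γ and
width σ) generates the synthetic experiments used by the tests.

## Worked example

```python
import numpy as np
from triphoton import (RunConfig, run_pipeline, make_fixture)

atoms = make_fixture("toy_atoms", seed=11, box=6.0)   # 5 Gaussian atoms
cfg = RunConfig(n_images=100_000, mean_photons=10, L=6, K=8,
                L_generator=10, n_runs=4, anneal_steps=1500, seed=11)
result = run_pipeline(cfg, atoms=atoms)
print(round(result.summary["avg_model_pearson"], 3))
print(round(result.density_cross_correlation, 3))
print(round(result.resolution, 2), "A")
```

prints

```
0.981
0.863
2.96 A
```

meaning: from 10⁵ simulated ten-photon images (10⁶ photons, 3.6×10⁷
triplets) the annealed intensity correlates 0.981 with the ground truth
after rotational alignment, the averaged RAAR density correlates 0.863 with
the band-limited reference density, and the FSC = 0.5 resolution of 2.96 Å
is close to the 2.92 Å band limit set by k_cut = 2.15 Å⁻¹ for this toy.

A command-line interface mirrors the stages
(`triphoton expand | simulate | correlate | invert | anneal | phase |
evaluate | run | fixture`); `triphoton run config.yaml --cluster-scale`
prints the cluster-scale reference parameter set without running it.

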