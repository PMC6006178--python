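"""End-to-end orchestration: simulate -> correlate -> invert -> anneal ->
phase -> evaluate, with seeded reproducibility and a fixture generator.

A single master seed drives every stage through `numpy.random.SeedSequence`
spawning (documented splitting order: simulation, annealing runs, phasing
repeats), so a run is replayable bit-identically from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time

import numpy as np
import yaml

from . import sphharm
from .anneal import AnnealingConfig, anneal
from .correlate import (CorrelationBinning, TripleCorrelationEngine,
                        analytic_triplet_table, extract_doublets,
                        extract_triplets)
from .evaluate import (align_models, fsc, intensity_pearson,
                       resolution_at_half)
from .intensity import (AtomSet, BeamGeometry, ShellGrid, ShellIntensityModel,
                        expand_on_shells, intensity_from_atoms)
from .inversion import invert_two_point, legendre_project
from .phasing import (average_densities, model_to_grid, raar_phase,
                      reference_density_from_atoms)
from .simulate import NoiseModel, simulate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "make_fixture"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full structure-determination run.

    ``analytic_data`` replaces the simulated histograms by the analytic
    ('infinite photon') tables, mirroring the infinite-data control
    experiment.
    """

    wavelength: float = 2.5          # A
    k_cut: float = 2.15              # 1/A
    L: int = 6                       # recovery expansion order (even)
    K: int = 8                       # shells
    L_generator: int = 10            # order of the image-generation model
    n_images: int = 100_000
    mean_photons: float = 10.0
    count_mode: str = "fixed"
    noise_gamma: float = 0.0
    noise_sigma: float = 2.5         # 1/A
    n_alpha: int = 16
    analytic_data: bool = False
    n_runs: int = 4                  # independent annealing runs
    anneal_steps: int = 2000
    phasing_beta: float = 0.92
    phasing_iters: int = 300
    phasing_repeats: int = 8
    n_voxels: int = 64
    support_radius: float | None = None   # A; None -> 1.2 x molecule radius + 2
    seed: int = 0

    def validate(self):
        if self.L % 2 or self.L_generator % 2:
            raise ValueError("expansion orders must be even")
        if self.L_generator < self.L:
            raise ValueError("generator order must be >= recovery order")
        if self.K < 2 or self.n_images < 1 or self.mean_photons <= 0:
            raise ValueError("invalid simulation sizes")
        if not 0 <= self.noise_gamma <= 1:
            raise ValueError("noise_gamma in [0,1]")
        BeamGeometry(self.wavelength, self.k_cut)

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**yaml.safe_load(f))

    @property
    def cluster_scale(self) -> dict:
        """The cluster-scale reference parameter set (printed
        only; never run implicitly)."""
        return {"n_images": 3_300_000_000, "mean_photons": 10, "L": 18,
                "K": 26, "k_cut": 2.15, "wavelength": 2.5, "n_runs": 20,
                "phasing_repeats": 8}


@dataclasses.dataclass
class PipelineResult:
    config: RunConfig
    model: ShellIntensityModel          # averaged aligned recovered intensity
    run_models: list
    density: object                     # averaged phased DensityGrid
    reference_model: ShellIntensityModel
    reference_density: object
    fsc_curve: object
    resolution: float
    resolution_crossed: bool
    density_cross_correlation: float
    run_pearsons: list
    summary: dict

    def save_summary(self, path):
        with open(path, "w") as f:
            json.dump(self.summary, f, indent=2, default=float)


def make_fixture(kind: str, seed: int = 1, box: float = 10.0,
                 wavelength: float = 2.5, k_cut: float = 2.15,
                 L: int = 6, K: int = 8, path=None):
    """Small reproducible inputs for tests and demonstrations.

    toy_atoms: 5 Gaussian pseudo-atoms in a ``box`` A cube (heights 4-9,
        widths 0.7-1.1 A).
    toy_sh_model: random even-l shell model with an l = 0-dominant spectrum,
        rejection-checked for positivity on a dense sphere sample.
    noise_only: parameters for a pure-noise image set (gamma = 1).
    """
    rng = np.random.default_rng(seed)
    if kind == "toy_atoms":
        atoms = AtomSet(rng.uniform(-box / 2, box / 2, (5, 3)),
                        rng.uniform(4.0, 9.0, 5), rng.uniform(0.7, 1.1, 5))
        return atoms
    if kind == "toy_sh_model":
        grid = ShellGrid.uniform(K, k_cut)
        for attempt in range(64):
            coeffs = np.zeros((sphharm.n_even_coeffs(L), grid.K))
            radial = np.exp(-1.5 * (grid.radii / k_cut) ** 2)
            coeffs[0] = np.sqrt(4 * np.pi) * radial
            for l in sphharm.even_orders(L)[1:]:
                sl = sphharm.packed_slice(l)
                coeffs[sl] = (rng.normal(size=(2 * l + 1, grid.K))
                              * 0.25 * radial / (l + 1))
            model = ShellIntensityModel(grid, L, coeffs, wavelength=wavelength)
            th, ph, _ = sphharm.sphere_quadrature(24, 48)
            ok = all(model.evaluate_on_shell(s, th, ph).min() > 0
                     for s in range(grid.K))
            if ok:
                if path is not None:
                    model.save(path)
                return model
        raise RuntimeError("could not build a positive toy model")
    if kind == "noise_only":
        return {"noise": NoiseModel(1.0, 1.0), "mean_photons": 10,
                "wavelength": wavelength, "k_cut": k_cut}
    raise ValueError(f"unknown fixture kind: {kind}")


def run_pipeline(config: RunConfig, atoms: AtomSet | None = None,
                 workdir=None) -> PipelineResult:
    """Execute the full correlation pipeline on a toy molecule.

    Stages: build the truth/generator models from the atoms, simulate photon
    images (or take analytic tables), accumulate doublet/triplet histograms,
    Kam-invert the doublets, run ``n_runs`` independent annealing searches,
    align each recovered intensity to the reference model, phase each with
    ``phasing_repeats`` RAAR restarts averaged in real space, average the
    per-run densities, and score against the band-limited reference density.
    """
    config.validate()
    t_start = time.time()
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_anneal, s_phase = ss.spawn(3)

    if atoms is None:
        atoms = make_fixture("toy_atoms", seed=config.seed + 1, box=6.0)
    geom = BeamGeometry(config.wavelength, config.k_cut)
    grid = ShellGrid.uniform(config.K, config.k_cut)
    evaluator = lambda p: intensity_from_atoms(atoms, p)
    gen_model = expand_on_shells(evaluator, grid, config.L_generator,
                                 wavelength=config.wavelength)
    ref_model = expand_on_shells(evaluator, grid, config.L,
                                 wavelength=config.wavelength)
    binning = CorrelationBinning(grid, config.n_alpha, config.wavelength)
    engine = TripleCorrelationEngine(grid, config.L, binning, config.wavelength)

    # --- data stage -------------------------------------------------------
    if config.analytic_data:
        log.info("stage data: analytic (infinite-photon) tables")
        triplets = analytic_triplet_table(ref_model, binning, engine=engine)
        C = legendre_project(ref_model, config.wavelength)
        n_triplets = None
    else:
        log.info("stage data: simulating %d images (P=%g)", config.n_images,
                 config.mean_photons)
        noise = (NoiseModel(config.noise_gamma, config.noise_sigma)
                 if config.noise_gamma > 0 else None)
        ds = simulate_dataset(gen_model, geom, config.n_images,
                              config.mean_photons,
                              np.random.default_rng(s_sim),
                              noise=noise, count_mode=config.count_mode)
        if workdir is not None:
            ds.save(f"{workdir}/images.h5")
        triplets = extract_triplets(ds, binning)
        doublets = extract_doublets(ds, binning)
        n_triplets = triplets.total
        C = legendre_project(doublets, config.wavelength, L=config.L)

    # --- inversion --------------------------------------------------------
    eigen = invert_two_point(C)
    eigen.wavelength = config.wavelength

    # --- annealing runs ---------------------------------------------------
    run_models, pearsons, energies = [], [], []
    anneal_seeds = s_anneal.spawn(config.n_runs)
    for i in range(config.n_runs):
        cfg = AnnealingConfig(n_steps=config.anneal_steps)
        res = anneal(triplets, eigen, cfg, engine=engine,
                     rng=np.random.default_rng(anneal_seeds[i]))
        al = align_models(res.model, ref_model)
        run_models.append(al.aligned)
        pearsons.append(al.score)
        energies.append(res.energy)
        log.info("run %d: E=%.6g aligned pearson=%.4f", i, res.energy, al.score)

    avg_coeffs = np.mean([m.coeffs for m in run_models], axis=0)
    avg_model = ShellIntensityModel(grid, config.L, avg_coeffs,
                                    wavelength=config.wavelength)

    # --- phasing ----------------------------------------------------------
    supp = (config.support_radius if config.support_radius is not None
            else 0.6 * atoms.diameter * 1.2 + 2.0)
    ig = model_to_grid(avg_model, config.n_voxels)
    ref_density = reference_density_from_atoms(atoms, config.n_voxels,
                                               ig.dk, config.k_cut)
    phase_seeds = s_phase.spawn(config.phasing_repeats)
    repeats = []
    for i in range(config.phasing_repeats):
        d, _ = raar_phase(ig, supp, beta=config.phasing_beta,
                          n_iter=config.phasing_iters,
                          rng=np.random.default_rng(phase_seeds[i]))
        repeats.append(d)
    density = average_densities(repeats, reference=ref_density)

    # --- evaluation -------------------------------------------------------
    curve = fsc(density.data, ref_density.data, density.dx)
    res_A, crossed = resolution_at_half(curve)
    from .evaluate import align_density_translation
    moved, _, _, xcorr = align_density_translation(density.data, ref_density.data)

    summary = {
        "config": dataclasses.asdict(config),
        "n_triplets": n_triplets,
        "run_energies": energies,
        "run_aligned_pearson": pearsons,
        "avg_model_pearson": intensity_pearson(avg_model, ref_model),
        "density_cross_correlation": xcorr,
        "resolution_A": res_A,
        "resolution_crossed": bool(crossed),
        "band_limit_A": 2 * np.pi / config.k_cut,
        "wall_time_s": time.time() - t_start,
    }
    if workdir is not None:
        avg_model.save(f"{workdir}/model.h5")
        density.save_ccp4(f"{workdir}/density.ccp4")
        ref_density.save_ccp4(f"{workdir}/reference_density.ccp4")
        with open(f"{workdir}/summary.json", "w") as f:
            json.dump(summary, f, indent=2, default=float)
    return PipelineResult(config, avg_model, run_models, density, ref_model,
                          ref_density, curve, res_A, crossed, xcorr,
                          pearsons, summary)
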