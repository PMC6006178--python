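"""Monte Carlo simulated annealing over the per-order rotations.

The triplet likelihood is maximized over the unknown rotations {U_l} of the
Kam eigenbasis by Metropolis simulated annealing on the energy

    E = -sum_bins count(bin) log t~(bin | {U_l}),

the negative log-likelihood of the recorded triplets under the normalized
analytic triple correlation of the rotated coefficients A_l = U_l A0_l.
Proposals perturb every order by a small random rotation exp(beta_l S_l)
(S_l skew-symmetric, unit Frobenius norm); an exponentially decaying
temperature T(j) = T_init exp(-j/tau) with Boltzmann acceptance
exp(-dE/T) lets the chain escape local minima; step sizes adapt by a factor
mu on accept/reject, and a hierarchical freeze-out shrinks low-order steps
faster so coarse angular features settle first.  Occasional reflection moves
flip the sign of one eigen-direction (the factorization of the two-photon
matrices leaves a discrete per-order hand freedom that continuous rotations
cannot reach).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.linalg import expm

from . import sphharm
from .correlate import (TripleCorrelationEngine, TripletHistogram,
                        normalize_correlation)
from .intensity import ShellIntensityModel
from .inversion import EigenBasis

__all__ = [
    "RotationSet",
    "AnnealingConfig",
    "AnnealResult",
    "random_rotation_set",
    "apply_rotations",
    "energy",
    "propose_step",
    "anneal",
]

log = logging.getLogger(__name__)


class RotationSet(dict):
    """Orthogonal U_l per even order l in 2..L (plus trivial l = 0)."""

    @property
    def L(self) -> int:
        return max(self.keys()) if self else 0

    def copy(self) -> "RotationSet":
        return RotationSet({l: U.copy() for l, U in self.items()})

    def check(self, tol: float = 1e-10):
        for l, U in self.items():
            err = np.abs(U @ U.T - np.eye(2 * l + 1)).max()
            if err > tol:
                raise ValueError(f"U_{l} not orthogonal (err {err:.2e})")

    def reorthonormalize(self):
        for l, U in self.items():
            q, r = np.linalg.qr(U)
            self[l] = q * np.sign(np.diag(r))


def random_rotation_set(L: int, rng, uniform_hand: bool = True) -> RotationSet:
    """Haar-random orthogonal matrices per even order 2..L.

    With ``uniform_hand`` each U_l is uniform over O(2l+1) (random det);
    otherwise det +1.
    """
    rs = RotationSet()
    for l in range(2, L + 1, 2):
        n = 2 * l + 1
        q, r = np.linalg.qr(rng.normal(size=(n, n)))
        q = q * np.sign(np.diag(r))
        if not uniform_hand and np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        if uniform_hand and rng.uniform() < 0.5:
            q[:, 0] = -q[:, 0]
        rs[l] = q
    return rs


def apply_rotations(eigenbasis: EigenBasis, rotations: RotationSet) -> ShellIntensityModel:
    """Assemble the shell model with coefficients A_l = U_l A0_l.

    The l = 0 block is fixed by the two-photon inversion (no rotation
    freedom); identity is used for any order missing from the rotation set.
    """
    L = eigenbasis.L
    coeffs = np.zeros((sphharm.n_even_coeffs(L), eigenbasis.grid.K))
    for l in sphharm.even_orders(L):
        A0 = eigenbasis.blocks[l]
        if l == 0 or l not in rotations:
            coeffs[sphharm.packed_slice(l)] = A0
            continue
        U = rotations[l]
        if U.shape != (2 * l + 1, 2 * l + 1):
            raise ValueError(f"U_{l} has wrong shape {U.shape}")
        coeffs[sphharm.packed_slice(l)] = U @ A0
    return ShellIntensityModel(eigenbasis.grid, L, coeffs,
                               wavelength=eigenbasis.wavelength)


def energy(triplets: TripletHistogram, eigenbasis: EigenBasis,
           rotations: RotationSet,
           engine: TripleCorrelationEngine | None = None) -> float:
    """Negative log-likelihood of the triplet histogram under {U_l}."""
    if engine is None:
        b = triplets.binning
        engine = TripleCorrelationEngine(eigenbasis.grid, eigenbasis.L, b,
                                         b.wavelength or eigenbasis.wavelength)
    if not np.array_equal(engine.grid.radii, eigenbasis.grid.radii):
        raise ValueError("histogram/model shell grids differ")
    model = apply_rotations(eigenbasis, rotations)
    t = engine.table(model.coeffs)
    tt = normalize_correlation(t, triplets.binning)
    E = -float((triplets.counts * np.log(tt)).sum())
    if not np.isfinite(E):
        raise FloatingPointError("non-finite annealing energy")
    return E


def propose_step(rotations: RotationSet, beta_l: dict, rng) -> RotationSet:
    """Perturb each U_l by exp(beta_l S_l) with S_l random unit-norm skew."""
    out = RotationSet()
    for l, U in rotations.items():
        b = beta_l.get(l, 0.0)
        if b == 0.0:
            out[l] = U.copy()
            continue
        n = 2 * l + 1
        S = rng.normal(size=(n, n))
        S = S - S.T
        S /= np.linalg.norm(S)
        out[l] = expm(b * S) @ U
    return out


@dataclasses.dataclass
class AnnealingConfig:
    """Hyperparameters of the simulated-annealing search.

    t_init: initial temperature; None calibrates it to the energy standard
        deviation over ``n_calibration`` random rotation sets.
    tau: temperature decay constant in steps (None -> n_steps / 10).
    mu: adaptive step factor (>1); step sizes multiply by mu on acceptance
        and divide on rejection.
    beta0: initial step size per order (None -> 0.3 / sqrt(2l+1)).
    freeze: hierarchical freeze-out; multiplies the order-l step size by
        exp(-j L / (tau_freeze l)) so low orders settle first.
    flip_prob: probability per step of proposing one per-order reflection.
    """

    n_steps: int = 3000
    t_init: float | None = None
    tau: float | None = None
    mu: float = 1.05
    beta0: dict | float | None = None
    freeze: bool = True
    freeze_tau_factor: float = 3.0
    flip_prob: float = 0.1
    n_calibration: int = 40
    beta_min: float = 1e-5
    beta_max: float = 0.7
    renorm_every: int = 200
    seed: int | None = None

    def __post_init__(self):
        if self.n_steps < 1 or self.mu <= 1.0:
            raise ValueError("need n_steps >= 1 and mu > 1")
        if self.t_init is not None and self.t_init <= 0:
            raise ValueError("t_init must be positive")
        if self.tau is not None and self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclasses.dataclass
class AnnealResult:
    rotations: RotationSet
    energy: float
    trace: np.ndarray           # best-seen energy per step (non-increasing)
    energy_trace: np.ndarray    # current energy per step
    acceptance_rate: float
    model: ShellIntensityModel


def anneal(triplets: TripletHistogram, eigenbasis: EigenBasis,
           config: AnnealingConfig | None = None,
           engine: TripleCorrelationEngine | None = None,
           rng=None) -> AnnealResult:
    """Metropolis simulated annealing for the per-order rotations.

    Accepts downhill steps always and uphill steps with probability
    exp(-dE/T(j)), T(j) = T_init exp(-j/tau); returns the best state seen.
    Deterministic given the rng/seed and inputs.
    """
    config = config or AnnealingConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b = triplets.binning
    if engine is None:
        engine = TripleCorrelationEngine(eigenbasis.grid, eigenbasis.L, b,
                                         b.wavelength or eigenbasis.wavelength)
    L = eigenbasis.L
    orders = [l for l in sphharm.even_orders(L) if l >= 2]

    current = random_rotation_set(L, rng)
    E_cur = energy(triplets, eigenbasis, current, engine)

    if config.t_init is None:
        samples = [energy(triplets, eigenbasis, random_rotation_set(L, rng), engine)
                   for _ in range(config.n_calibration)]
        t_init = max(float(np.std(samples)), 1e-12)
    else:
        t_init = config.t_init
    tau = config.tau if config.tau is not None else config.n_steps / 10.0

    if config.beta0 is None:
        beta = {l: 0.3 / np.sqrt(2 * l + 1) for l in orders}
    elif np.isscalar(config.beta0):
        beta = {l: float(config.beta0) for l in orders}
    else:
        beta = dict(config.beta0)

    best = current.copy()
    E_best = E_cur
    trace = np.empty(config.n_steps)
    etrace = np.empty(config.n_steps)
    n_acc = 0
    tau_freeze = config.freeze_tau_factor * tau
    for j in range(config.n_steps):
        T = t_init * np.exp(-j / tau)
        if config.freeze and L > 2:
            sched = {l: beta[l] * np.exp(-j * L / (tau_freeze * l)) for l in orders}
        else:
            sched = beta
        sched = {l: np.clip(v, config.beta_min, config.beta_max)
                 for l, v in sched.items()}
        proposal = propose_step(current, sched, rng)
        if config.flip_prob > 0 and rng.uniform() < config.flip_prob:
            lf = orders[rng.integers(len(orders))]
            # reflect one eigen-direction of the unaligned basis
            col = rng.integers(2 * lf + 1)
            proposal[lf] = proposal[lf].copy()
            proposal[lf][:, col] = -proposal[lf][:, col]
        E_new = energy(triplets, eigenbasis, proposal, engine)
        dE = E_new - E_cur
        if dE < 0 or (T > 0 and rng.uniform() < np.exp(-dE / max(T, 1e-300))):
            current, E_cur = proposal, E_new
            n_acc += 1
            beta = {l: min(v * config.mu, config.beta_max) for l, v in beta.items()}
        else:
            beta = {l: max(v / config.mu, config.beta_min) for l, v in beta.items()}
        if E_cur < E_best:
            best, E_best = current.copy(), E_cur
        trace[j] = E_best
        etrace[j] = E_cur
        if config.renorm_every and (j + 1) % config.renorm_every == 0:
            current.reorthonormalize()
    best.reorthonormalize()
    E_best = energy(triplets, eigenbasis, best, engine)
    log.info("annealing finished: E=%.6g acc=%.2f", E_best,
             n_acc / config.n_steps)
    return AnnealResult(best, E_best, trace, etrace,
                        n_acc / config.n_steps,
                        apply_rotations(eigenbasis, best))
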