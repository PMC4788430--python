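"""Expanded-ensemble lambda dynamics with adaptive umbrella bias.

An extra dynamic variable lambda scales the tail energy terms
(lambda^2 intra-tail, lambda tail-rest) and diffuses under Langevin
dynamics jointly with the particle coordinates.  An adaptive bias,
RT * ln_p(lambda), is iteratively built from sampled lambda histograms
until the lambda marginal is flat, enabling a random walk across the
lambda range.  Production runs are reweighted downstream to recover the
canonical ensemble at lambda = 1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import logsumexp

from .constants import rt
from .model_builder import CGSystem, initial_conformations
from .energetics import CGEnergetics, EnergyDecomposition, ForceFieldParams


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite energy or force."""

    def __init__(self, message: str, step: int):
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass(frozen=True)
class ALSDConfig:
    """Sampler configuration.

    ``lambda_min``/``lambda_max`` bound the sampled range via half-harmonic
    walls; ``m_lambda`` is the fictitious mass of the lambda coordinate.
    ``freeze_lambda`` pins lambda (plain canonical Langevin dynamics).
    """

    temperature: float = 300.0
    lambda_min: float = 0.6
    lambda_max: float = 1.03
    m_lambda: float = 10.0
    wall_k: float = 500.0
    timestep: float = 0.015
    friction: float = 0.05  # low particle friction: fast conformational diffusion
    lambda_friction: float | None = 1.0  # heavier damping for the lambda walk
    n_steps: int = 10000
    save_interval: int = 100
    equil_steps: int = 0  # un-recorded steps before production frames
    seed: int = 0
    freeze_lambda: bool = False
    wall_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if not (self.lambda_min <= 1.0 <= self.lambda_max):
            raise ValueError("lambda range must satisfy lambda_min <= 1 <= lambda_max")
        if min(self.m_lambda, self.wall_k, self.timestep, self.friction) <= 0:
            raise ValueError("m_lambda, wall_k, timestep and friction must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return rt(self.temperature)

    def content_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ALSDState:
    """Dynamical state of the extended system (coordinates + lambda)."""

    positions: np.ndarray
    velocities: np.ndarray
    lam: float
    lambda_velocity: float
    step: int = 0

    def kinetic_energy(self, masses: np.ndarray, m_lambda: float) -> float:
        ke = 0.5 * float(np.sum(masses[:, None] * self.velocities ** 2))
        return ke + 0.5 * m_lambda * self.lambda_velocity ** 2


class BiasEstimate:
    """Tabulated log-probability estimate ln_p(lambda) on a knot grid.

    Interpolated with a monotone (shape-preserving) cubic, so both the
    value and the first derivative are continuous across knots.
    """

    def __init__(self, lambda_grid: np.ndarray, ln_p: np.ndarray):
        self.lambda_grid = np.asarray(lambda_grid, dtype=float)
        self.ln_p = np.asarray(ln_p, dtype=float)
        if len(self.lambda_grid) < 2 or np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing with >= 2 knots")
        if self.lambda_grid.shape != self.ln_p.shape:
            raise ValueError("lambda_grid and ln_p must have the same shape")
        if not np.all(np.isfinite(self.ln_p)):
            raise ValueError("ln_p must be finite")
        self._spline = PchipInterpolator(self.lambda_grid, self.ln_p, extrapolate=True)
        self._dspline = self._spline.derivative()

    @classmethod
    def zero(cls, lambda_min: float, lambda_max: float, n_knots: int = 30) -> "BiasEstimate":
        grid = np.linspace(lambda_min, lambda_max, n_knots)
        return cls(grid, np.zeros(n_knots))

    def value(self, lam: float) -> float:
        # linear continuation outside the knot range so the bias keeps
        # counteracting the lambda force inside the wall region (a flat
        # continuation would create a spurious potential pocket there).
        lo, hi = self.lambda_grid[0], self.lambda_grid[-1]
        if lam < lo:
            return float(self._spline(lo) + self._dspline(lo) * (lam - lo))
        if lam > hi:
            return float(self._spline(hi) + self._dspline(hi) * (lam - hi))
        return float(self._spline(lam))

    def derivative(self, lam: float) -> float:
        lo, hi = self.lambda_grid[0], self.lambda_grid[-1]
        if lam < lo:
            return float(self._dspline(lo))
        if lam > hi:
            return float(self._dspline(hi))
        return float(self._dspline(lam))

    def shifted(self, constant: float) -> "BiasEstimate":
        return BiasEstimate(self.lambda_grid, self.ln_p + constant)

    def updated(self, delta_ln_p: np.ndarray) -> "BiasEstimate":
        new = self.ln_p + delta_ln_p
        return BiasEstimate(self.lambda_grid, new - new.max())

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.lambda_grid.tobytes())
        h.update(self.ln_p.tobytes())
        return h.hexdigest()[:16]

    def ppoly(self) -> tuple[np.ndarray, np.ndarray]:
        """Breakpoints and piecewise-cubic coefficients of the interpolant."""
        return (np.ascontiguousarray(self._spline.x),
                np.ascontiguousarray(self._spline.c))

    def to_dict(self) -> dict:
        return {"lambda_grid": self.lambda_grid.tolist(), "ln_p": self.ln_p.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "BiasEstimate":
        return cls(np.asarray(d["lambda_grid"]), np.asarray(d["ln_p"]))


def _wall(lam: float, config: ALSDConfig) -> tuple[float, float]:
    """Half-harmonic restraint energy and d/d-lambda outside the range."""
    if lam > config.lambda_max:
        d = lam - config.lambda_max
        return config.wall_k * d * d, 2.0 * config.wall_k * d
    if lam < config.lambda_min:
        d = config.lambda_min - lam
        return config.wall_k * d * d, -2.0 * config.wall_k * d
    return 0.0, 0.0


def _check_lambda(lam: float, config: ALSDConfig, step: int = -1) -> None:
    if lam > config.lambda_max + config.wall_tolerance or \
            lam < config.lambda_min - config.wall_tolerance:
        raise IntegrationError(f"lambda = {lam:.4f} far outside the wall region", step)


def hamiltonian_potential(decomp: EnergyDecomposition, lam: float,
                          bias: BiasEstimate, config: ALSDConfig) -> float:
    """Potential part of the extended Hamiltonian.

    lambda^2 E_tail + lambda E_tail_rest + E_rest + RT ln_p(lambda) + wall.
    """
    _check_lambda(lam, config)
    wall_e, _ = _wall(lam, config)
    return decomp.scaled(lam) + config.rt * bias.value(lam) + wall_e


def lambda_force(decomp: EnergyDecomposition, lam: float,
                 bias: BiasEstimate, config: ALSDConfig) -> float:
    """Negative derivative of the potential with respect to lambda."""
    _check_lambda(lam, config)
    _, wall_d = _wall(lam, config)
    return -(2.0 * lam * decomp.e_tail + decomp.e_tail_rest
             + config.rt * bias.derivative(lam) + wall_d)


def step_langevin(state: ALSDState, system, bias: BiasEstimate,
                  config: ALSDConfig, rng: np.random.Generator) -> ALSDState:
    """One BAOAB Langevin step of the joint (coordinates, lambda) dynamics.

    ``system`` is any object exposing ``masses``, ``mobile`` and
    ``forces_and_decompose(pos, lam)``.  Deterministic given the rng stream.
    """
    new = ALSDState(state.positions.copy(), state.velocities.copy(),
                    state.lam, state.lambda_velocity, state.step)
    _integrate(new, system, bias, config, rng, n_steps=1)
    return new


def _integrate(state: ALSDState, system, bias: BiasEstimate, config: ALSDConfig,
               rng: np.random.Generator, n_steps: int,
               lambda_log: list | None = None,
               frame_hook=None, hook_interval: int | None = None,
               energy_log: list | None = None) -> None:
    """In-place BAOAB integration.

    Optionally logs lambda every step (``lambda_log``), logs
    (lambda, E_tail, E_tail_rest) every step (``energy_log``), and calls
    ``frame_hook(step, positions, lambda, decomposition)`` -- every step,
    or only at multiples of ``hook_interval`` when given.  Dispatches to a
    jit-compiled chunked loop when the system supports it.
    """
    if n_steps <= 0:
        return
    if (getattr(system, "supports_jit_integration", None) is not None
            and system.supports_jit_integration(state.positions)
            and (frame_hook is None or hook_interval is not None)):
        _integrate_fast(state, system, bias, config, rng, n_steps,
                        lambda_log, frame_hook, hook_interval, energy_log)
        return
    dt = config.timestep
    kt = config.rt
    masses = system.masses
    mobile = system.mobile
    inv_m = 1.0 / masses[:, None]
    c1 = np.exp(-config.friction * dt)
    c2v = np.sqrt((1.0 - c1 * c1) * kt / masses)[:, None]
    gamma_l = config.lambda_friction if config.lambda_friction is not None else config.friction
    c1l = np.exp(-gamma_l * dt)
    c2l = np.sqrt((1.0 - c1l * c1l) * kt / config.m_lambda)
    frozen = config.freeze_lambda

    pos, vel = state.positions, state.velocities
    lam, lamv = state.lam, state.lambda_velocity

    f, decomp = system.forces_and_decompose(pos, lam)
    fl = 0.0 if frozen else lambda_force(decomp, lam, bias, config)

    for k in range(n_steps):
        step_idx = state.step + k
        half = 0.5 * dt
        vel += half * f * inv_m
        if not frozen:
            lamv += half * fl / config.m_lambda
        pos[mobile] += half * vel[mobile]
        if not frozen:
            lam += half * lamv
        noise = rng.standard_normal(size=vel.shape)
        vel = c1 * vel + c2v * noise
        vel[~mobile] = 0.0
        if not frozen:
            lamv = c1l * lamv + c2l * rng.standard_normal()
        pos[mobile] += half * vel[mobile]
        if not frozen:
            lam += half * lamv
            _check_lambda(lam, config, step_idx)
        try:
            f, decomp = system.forces_and_decompose(pos, lam)
        except FloatingPointError as exc:
            raise IntegrationError(str(exc), step_idx) from exc
        if not np.all(np.isfinite(f)) or not np.isfinite(decomp.total):
            raise IntegrationError("non-finite force or energy", step_idx)
        fl = 0.0 if frozen else lambda_force(decomp, lam, bias, config)
        vel += half * f * inv_m
        if not frozen:
            lamv += half * fl / config.m_lambda
        if lambda_log is not None:
            lambda_log.append(lam)
        if energy_log is not None:
            energy_log.append((lam, decomp.e_tail, decomp.e_tail_rest))
        if frame_hook is not None and (
                hook_interval is None or (step_idx + 1) % hook_interval == 0):
            frame_hook(step_idx + 1, pos, lam, decomp)

    state.positions = pos
    state.velocities = vel
    state.lam = lam
    state.lambda_velocity = lamv
    state.step += n_steps


def _integrate_fast(state: ALSDState, system, bias: BiasEstimate,
                    config: ALSDConfig, rng: np.random.Generator, n_steps: int,
                    lambda_log, frame_hook, hook_interval, energy_log) -> None:
    """Chunked jit-compiled BAOAB path (CGEnergetics with a rigid scaffold).

    Reproduces the pure-python loop step for step, including the noise
    stream ordering (velocity noise for all beads, then the lambda noise,
    each step).
    """
    from . import _kernels

    dt = config.timestep
    kt = config.rt
    masses = system.masses
    c1 = np.exp(-config.friction * dt)
    c2v = np.sqrt((1.0 - c1 * c1) * kt / masses)
    gamma_l = config.lambda_friction if config.lambda_friction is not None \
        else config.friction
    c1l = np.exp(-gamma_l * dt)
    c2l = np.sqrt((1.0 - c1l * c1l) * kt / config.m_lambda)
    frozen = config.freeze_lambda

    jit = system.jit_integration_args(bias)
    pos = np.ascontiguousarray(state.positions)
    vel = np.ascontiguousarray(state.velocities)
    n_beads = len(pos)
    lam_arr = np.array([state.lam])
    lamv_arr = np.array([state.lambda_velocity])
    forces = np.zeros_like(pos)
    e_by_cat = np.zeros(3)
    inv_m = 1.0 / masses
    mobile = system.mobile

    chunk = hook_interval if (frame_hook is not None and hook_interval) else 4096
    done = 0
    while done < n_steps:
        n = min(chunk, n_steps - done)
        noise_v = np.empty((n, n_beads, 3))
        noise_l = np.zeros(n)
        for s in range(n):
            noise_v[s] = rng.standard_normal(size=(n_beads, 3))
            if not frozen:
                noise_l[s] = rng.standard_normal()
        lam_out = np.empty(n)
        etail_out = np.empty(n)
        etr_out = np.empty(n)
        status, at = _kernels.integrate_chunk(
            pos, vel, lam_arr, lamv_arr, noise_v, noise_l,
            dt, c1, c2v, c1l, c2l, inv_m, mobile,
            *jit["tt"], *jit["tr"], *jit["bonds"],
            jit["kappa_inv"], jit["cutoff"], jit["shift_per_qq"],
            jit["wca_epsilon"], jit["coulomb_over_eps"], jit["bond_k"],
            jit["e_rest"], jit["bias_x"], jit["bias_c"],
            kt, config.m_lambda, config.lambda_min, config.lambda_max,
            config.wall_k, config.wall_tolerance, frozen,
            lam_out, etail_out, etr_out, forces, e_by_cat)
        if status == 1:
            raise IntegrationError("non-finite force or energy",
                                   state.step + done + int(at))
        if status == 3:
            raise IntegrationError(
                f"lambda = {lam_arr[0]:.4f} far outside the wall region",
                state.step + done + int(at))
        if lambda_log is not None:
            lambda_log.extend(lam_out.tolist())
        if energy_log is not None:
            energy_log.extend(zip(lam_out.tolist(), etail_out.tolist(),
                                  etr_out.tolist()))
        done += n
        if frame_hook is not None and hook_interval and \
                (state.step + done) % hook_interval == 0:
            decomp = EnergyDecomposition(float(etail_out[-1]), float(etr_out[-1]),
                                         jit["e_rest"])
            frame_hook(state.step + done, pos, float(lam_out[-1]), decomp)

    state.positions = pos
    state.velocities = vel
    state.lam = float(lam_arr[0])
    state.lambda_velocity = float(lamv_arr[0])
    state.step += n_steps


def initial_state(system, config: ALSDConfig, rng: np.random.Generator,
                  positions: np.ndarray | None = None) -> ALSDState:
    """Fresh state with Maxwell-Boltzmann velocities and lambda = 1."""
    if positions is None:
        if hasattr(system, "initial_positions"):
            positions = system.initial_positions()
        else:
            positions = system.system.positions.copy()
    positions = np.array(positions, dtype=float)
    kt = config.rt
    vel = rng.standard_normal(positions.shape) * np.sqrt(kt / system.masses)[:, None]
    vel[~system.mobile] = 0.0
    lamv = 0.0 if config.freeze_lambda else float(rng.standard_normal()) * np.sqrt(
        kt / config.m_lambda)
    return ALSDState(positions, vel, 1.0, lamv, step=0)


# ---------------------------------------------------------------------------
# Bias adaptation
# ---------------------------------------------------------------------------

class AdaptationError(RuntimeError):
    pass


@dataclass
class AdaptResult:
    """Final bias plus per-iteration flatness diagnostics."""

    bias: BiasEstimate
    flatness: list[float] = field(default_factory=list)
    histograms: list[np.ndarray] = field(default_factory=list)
    converged: bool = False
    final_positions: list[np.ndarray] = field(default_factory=list)


def histogram_flatness(counts: np.ndarray) -> float:
    """min/max ratio of occupied-range bin counts (0 if any bin is empty)."""
    counts = np.asarray(counts, dtype=float)
    if counts.max() <= 0:
        return 0.0
    return float(counts.min() / counts.max())


def estimate_bias_ti(system, config: ALSDConfig, seed: int,
                     n_lambda_points: int = 12, equil_steps: int = 500,
                     sample_steps: int = 1500, n_knots: int = 30,
                     initial_positions: np.ndarray | None = None) -> BiasEstimate:
    """Thermodynamic-integration bootstrap of the bias.

    At fixed lambda, d ln P / d lambda = -beta * <2 lambda E_tail +
    E_tail_rest>.  Short frozen-lambda runs estimate this derivative on a
    coarse grid; integrating it gives a starting ln_p close enough for
    histogram refinement to take over.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x71)))
    lam_points = np.linspace(config.lambda_min, config.lambda_max, n_lambda_points)
    frozen_cfg = replace(config, freeze_lambda=True)
    state = initial_state(system, frozen_cfg, rng, initial_positions)
    beta = 1.0 / config.rt
    derivs = np.empty(n_lambda_points)
    # sweep from lambda = 1 outwards so each point starts near equilibrium
    order = np.argsort(np.abs(lam_points - 1.0))
    for k in order:
        state.lam = float(lam_points[k])
        elog: list[tuple[float, float, float]] = []
        zero = BiasEstimate.zero(config.lambda_min, config.lambda_max, 2)
        _integrate(state, system, zero, frozen_cfg, rng, equil_steps)
        _integrate(state, system, zero, frozen_cfg, rng, sample_steps,
                   energy_log=elog)
        arr = np.asarray(elog)
        derivs[k] = -beta * float(np.mean(2.0 * arr[:, 0] * arr[:, 1] + arr[:, 2]))
    from scipy.integrate import cumulative_trapezoid

    ln_p = cumulative_trapezoid(derivs, lam_points, initial=0.0)
    grid = np.linspace(config.lambda_min, config.lambda_max, n_knots)
    vals = np.interp(grid, lam_points, ln_p)
    return BiasEstimate(grid, vals - vals.max())


def _pooled_ln_p(samples: list[np.ndarray], biases: list[BiasEstimate],
                 grid: np.ndarray, beta: float) -> np.ndarray:
    """Pooled free-energy estimate of ln P(lambda) on the knot grid.

    Samples from iteration i were drawn under bias b_i; the iterations are
    treated as thermodynamic states differing only by their bias and
    combined self-consistently (MBAR-style mixture weights), then each
    pooled sample is reweighted to every grid lambda via the energy
    differences (lambda_g^2 - lambda_s^2) E_tail + (lambda_g - lambda_s)
    E_tail_rest.
    """
    stacked = np.vstack(samples)
    lam_s, et_s, etr_s = stacked[:, 0], stacked[:, 1], stacked[:, 2]
    n_states = len(biases)
    bias_mat = np.array([[b.value(l) for l in lam_s] for b in biases])
    counts = np.array([len(s) for s in samples], dtype=float)
    ln_z = np.zeros(n_states)
    for _ in range(60):
        ln_denom = logsumexp(np.log(counts)[:, None] - ln_z[:, None] - bias_mat, axis=0)
        new_ln_z = np.array([logsumexp(-bias_mat[j] - ln_denom)
                             for j in range(n_states)])
        new_ln_z -= new_ln_z[0]
        if np.max(np.abs(new_ln_z - ln_z)) < 1e-9:
            ln_z = new_ln_z
            break
        ln_z = new_ln_z
    ln_denom = logsumexp(np.log(counts)[:, None] - ln_z[:, None] - bias_mat, axis=0)
    ln_p = np.array([
        logsumexp(-beta * ((g * g - lam_s ** 2) * et_s + (g - lam_s) * etr_s)
                  - ln_denom)
        for g in grid])
    return ln_p - ln_p.max()


def _wham_bins(histograms: list[np.ndarray], biases: list[np.ndarray],
               n_sweeps: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Self-consistent WHAM on binned lambda marginals.

    Each histogram was sampled under the matching bias (ln units,
    evaluated at the bin centers).  Returns ln P per bin up to a constant.
    """
    h = np.asarray(histograms, dtype=float)  # (R, B)
    b = np.asarray(biases, dtype=float)  # (R, B)
    counts = h.sum(axis=1)
    total = h.sum(axis=0)
    f = np.zeros(len(h))  # -ln Z_r
    ln_p = np.zeros(h.shape[1])
    for _ in range(n_sweeps):
        denom = logsumexp(np.log(counts)[:, None] + f[:, None] - b, axis=0)
        new_ln_p = np.where(total > 0, np.log(np.maximum(total, 1e-300)) - denom,
                            ln_p)
        new_f = -logsumexp(new_ln_p[None, :] - b, axis=1)
        new_ln_p -= new_ln_p.max()
        if np.max(np.abs(new_ln_p - ln_p)) < tol:
            ln_p = new_ln_p
            break
        ln_p = new_ln_p
        f = new_f
    return ln_p


def adapt_bias(system, config: ALSDConfig, n_iterations: int,
               steps_per_iteration: int, seed: int,
               flatness_threshold: float = 0.7, n_bins: int = 24,
               n_knots: int = 30, n_walkers: int = 1,
               sample_stride: int = 5, ti_bootstrap: bool = False,
               polish_rounds: int = 0, polish_steps: int = 100000,
               polish_target: float = 0.0,
               initial_positions: np.ndarray | None = None) -> AdaptResult:
    """Iteratively estimate the umbrella bias RT ln_p(lambda).

    Each iteration runs ``n_walkers`` independent samplers under the
    current bias for ``steps_per_iteration`` steps each, recording
    (lambda, E_tail, E_tail_rest) every ``sample_stride`` steps.  All
    samples collected so far are pooled into a new ln P estimate (see
    :func:`_pooled_ln_p`), which becomes the next bias.  Optionally the
    starting bias comes from a thermodynamic-integration bootstrap, which
    shortens the burn-in on strongly coupled systems.  Stops early once
    the per-iteration lambda histogram flatness (min/max over occupied
    bins) reaches the threshold.  Walker states carry over between
    iterations.

    ``polish_rounds`` appends direct marginal corrections: long runs under
    the fixed bias whose smoothed log-histogram is added to ln_p.  This
    removes the residual tilt the pooled estimator can retain when
    conformational relaxation is slow.

    ``initial_positions`` may be a single coordinate set or one per walker.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if ti_bootstrap:
        start0 = None
        if initial_positions is not None:
            arr = np.asarray(initial_positions, dtype=float)
            start0 = arr[0] if arr.ndim == 3 else arr
        bias = estimate_bias_ti(system, config, seed, n_knots=n_knots,
                                initial_positions=start0)
    else:
        bias = BiasEstimate.zero(config.lambda_min, config.lambda_max, n_knots)
    beta = 1.0 / config.rt

    starts: list[np.ndarray | None]
    if initial_positions is None:
        starts = [None] * n_walkers
    else:
        arr = np.asarray(initial_positions, dtype=float)
        starts = [arr[w % len(arr)] for w in range(n_walkers)] if arr.ndim == 3 \
            else [arr] * n_walkers
    rngs = [np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0xADA7, w)))
            for w in range(n_walkers)]
    states = [initial_state(system, config, rngs[w], starts[w])
              for w in range(n_walkers)]

    edges = np.linspace(config.lambda_min, config.lambda_max, n_bins + 1)
    result = AdaptResult(bias=bias)
    all_samples: list[np.ndarray] = []
    iteration_biases: list[BiasEstimate] = []

    for _ in range(n_iterations):
        recs: list[tuple[float, float, float]] = []
        lam_log: list[float] = []
        for w in range(n_walkers):
            elog: list[tuple[float, float, float]] = []
            _integrate(states[w], system, bias, config, rngs[w],
                       steps_per_iteration, lambda_log=lam_log,
                       energy_log=elog)
            recs.extend(elog[sample_stride - 1::sample_stride])
        samples = np.asarray(lam_log)
        samples = samples[(samples >= config.lambda_min) & (samples <= config.lambda_max)]
        hist, _ = np.histogram(samples, bins=edges)
        flat = histogram_flatness(hist)
        result.flatness.append(flat)
        result.histograms.append(hist)
        if np.count_nonzero(hist) <= 1:
            raise AdaptationError(
                "lambda never left a single histogram bin during an iteration; "
                "increase lambda mobility (smaller m_lambda / longer iterations)"
            )
        if flat >= flatness_threshold:
            result.converged = True
            break
        all_samples.append(np.asarray(recs))
        iteration_biases.append(bias)
        ln_p = _pooled_ln_p(all_samples, iteration_biases, bias.lambda_grid, beta)
        bias = BiasEstimate(bias.lambda_grid, ln_p)

    edges_fine = np.linspace(config.lambda_min, config.lambda_max, 21)
    centers_fine = 0.5 * (edges_fine[:-1] + edges_fine[1:])
    polish_hists: list[np.ndarray] = []
    polish_biases: list[np.ndarray] = []
    for _ in range(polish_rounds):
        lam_log = []
        for w in range(n_walkers):
            _integrate(states[w], system, bias, config, rngs[w],
                       polish_steps // max(1, n_walkers), lambda_log=lam_log)
        lam = np.asarray(lam_log)
        lam = lam[(lam >= config.lambda_min) & (lam <= config.lambda_max)]
        hist, _ = np.histogram(lam, bins=edges_fine)
        flat = histogram_flatness(hist)
        result.flatness.append(flat)
        result.histograms.append(hist)
        polish_hists.append(hist.astype(float))
        polish_biases.append(np.interp(centers_fine, bias.lambda_grid, bias.ln_p))
        if polish_target > 0 and flat >= polish_target:
            result.converged = True
            break
        corr = np.log(np.maximum(hist, 0.02 * hist.max()) / hist.mean())
        corr = np.convolve(np.pad(corr, 1, mode="edge"), np.ones(3) / 3,
                           mode="valid")
        delta = np.interp(bias.lambda_grid, centers_fine, corr)
        ln_p = bias.ln_p + delta
        bias = BiasEstimate(bias.lambda_grid, ln_p - ln_p.max())

    if len(polish_hists) >= 2:
        # combine every polish round by bin-wise WHAM (rounds are states
        # differing only by their bias) -- uses all polish data at once
        ln_p_bins = _wham_bins(polish_hists, polish_biases)
        ln_p_bins = np.convolve(np.pad(ln_p_bins, 1, mode="edge"),
                                np.ones(3) / 3, mode="valid")
        ln_p = np.interp(bias.lambda_grid, centers_fine, ln_p_bins)
        bias = BiasEstimate(bias.lambda_grid, ln_p - ln_p.max())

    result.bias = bias
    result.final_positions = [s.positions.copy() for s in states]
    return result


# ---------------------------------------------------------------------------
# Production runs and trivial trajectory parallelization
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Saved frames of a single production run plus reproducibility metadata."""

    positions: np.ndarray  # (F, N, 3)
    lambdas: np.ndarray  # (F,)
    e_tail: np.ndarray
    e_tail_rest: np.ndarray
    e_rest: np.ndarray
    steps: np.ndarray
    metadata: dict

    @property
    def n_frames(self) -> int:
        return len(self.lambdas)

    def decomposition(self, frame: int) -> EnergyDecomposition:
        return EnergyDecomposition(float(self.e_tail[frame]),
                                   float(self.e_tail_rest[frame]),
                                   float(self.e_rest[frame]))

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path, positions=self.positions, lambdas=self.lambdas,
            e_tail=self.e_tail, e_tail_rest=self.e_tail_rest, e_rest=self.e_rest,
            steps=self.steps, metadata=json.dumps(self.metadata))

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["positions"], z["lambdas"], z["e_tail"], z["e_tail_rest"],
                       z["e_rest"], z["steps"], json.loads(str(z["metadata"])))

    def export_text(self, path) -> None:
        """Plain-text export: one row per frame (step, lambda, energy triple)."""
        with open(path, "w") as fh:
            fh.write("# step lambda e_tail e_tail_rest e_rest\n")
            for k in range(self.n_frames):
                fh.write(f"{int(self.steps[k])} {self.lambdas[k]:.8g} "
                         f"{self.e_tail[k]:.10g} {self.e_tail_rest[k]:.10g} "
                         f"{self.e_rest[k]:.10g}\n")


def run_production(system, config: ALSDConfig, bias: BiasEstimate, seed: int,
                   initial_positions: np.ndarray | None = None) -> Trajectory:
    """Fixed-bias production run, saving a frame every ``save_interval`` steps."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x9504)))
    state = initial_state(system, config, rng, initial_positions)
    if config.equil_steps > 0:
        _integrate(state, system, bias, config, rng, config.equil_steps)
        state.step = 0

    frames_pos: list[np.ndarray] = []
    frames_lam: list[float] = []
    frames_e: list[tuple[float, float, float]] = []
    frames_step: list[int] = []

    def record(step: int, pos: np.ndarray, lam: float, decomp: EnergyDecomposition):
        frames_pos.append(pos.copy())
        frames_lam.append(lam)
        frames_e.append((decomp.e_tail, decomp.e_tail_rest, decomp.e_rest))
        frames_step.append(step)

    d0 = system.forces_and_decompose(state.positions, state.lam)[1]
    record(0, state.positions, state.lam, d0)

    def hook(step, pos, lam, decomp):
        if step % config.save_interval == 0:
            record(step, pos, lam, decomp)

    lam_log: list[float] = []
    if config.n_steps > 0:
        _integrate(state, system, bias, config, rng, config.n_steps,
                   lambda_log=lam_log, frame_hook=hook,
                   hook_interval=config.save_interval)

    # decile histogram of the in-range lambda walk
    edges = np.linspace(config.lambda_min, config.lambda_max, 11)
    if lam_log:
        lam_arr = np.asarray(lam_log)
        lam_arr = lam_arr[(lam_arr >= config.lambda_min) & (lam_arr <= config.lambda_max)]
        hist, _ = np.histogram(lam_arr, bins=edges)
    else:
        hist = np.zeros(10, dtype=int)
    meta = {
        "config_hash": config.content_hash(),
        "bias_hash": bias.content_hash(),
        "seed": int(seed),
        "n_steps": int(config.n_steps),
        "lambda_histogram": np.asarray(hist).tolist(),
        "lambda_flatness": histogram_flatness(hist) if lam_log else None,
    }
    e = np.asarray(frames_e)
    return Trajectory(np.asarray(frames_pos), np.asarray(frames_lam),
                      e[:, 0], e[:, 1], e[:, 2],
                      np.asarray(frames_step, dtype=int), meta)


class TTPRunError(RuntimeError):
    """One or more TTP runs failed; partial results are preserved."""

    def __init__(self, failures: list[tuple[int, Exception]], partial: dict):
        msgs = "; ".join(f"run {i}: {e}" for i, e in failures)
        super().__init__(f"TTP run failures: {msgs}")
        self.failures = failures
        self.partial = partial


def run_ttp(system: CGSystem, config: ALSDConfig, bias: BiasEstimate,
            n_runs: int, base_seed: int,
            ff_params: ForceFieldParams | None = None,
            starts: np.ndarray | None = None) -> list[Trajectory]:
    """Independent production runs from distinct initial conformations.

    Run ``i`` uses seed ``(base_seed, i)``; results are independent of
    execution order.  On failure, successfully completed runs are kept on
    the raised :class:`TTPRunError`.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 (TTP needs a between-run variance)")
    eng = CGEnergetics(system, ff_params)
    if starts is None:
        starts = initial_conformations(system, n_runs, base_seed)
    if len(starts) != n_runs:
        raise ValueError("need one starting conformation per run")
    results: dict[int, Trajectory] = {}
    failures: list[tuple[int, Exception]] = []
    for i in range(n_runs):
        run_config = replace(config, seed=base_seed)
        seed_i = int(np.random.SeedSequence(entropy=(base_seed, i)).generate_state(1)[0])
        try:
            traj = run_production(eng, run_config, bias, seed_i,
                                  initial_positions=starts[i])
            traj.metadata["run_index"] = i
            traj.metadata["base_seed"] = int(base_seed)
            results[i] = traj
        except Exception as exc:  # noqa: BLE001 - preserved and re-raised
            failures.append((i, exc))
    if failures:
        raise TTPRunError(failures, results)
    return [results[i] for i in range(n_runs)]
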