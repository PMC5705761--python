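"""Stochastic and deterministic integration of the driven ratchet dynamics.

The equation of motion, in dimensionless form, is

    m ẍ + γ ẋ = −U′(x) + a cos(ω t) + √(2θ) ξ(t),      γ = 1,

integrated with a weak second-order stochastic predictor–corrector (Heun)
scheme for additive noise: the predictor is an explicit Euler–Maruyama drift
step carrying the noise increment √(2θ·dt)/m · Z on the velocity, and the
corrector averages the drift evaluated at the initial and predicted states,
reusing the *same* noise increment.  For additive noise this scheme is weak
order 2; the test suite verifies the order empirically on the exactly solvable
Ornstein–Uhlenbeck configuration.

Randomness policy: one counter-based (Philox) stream per trajectory, derived
from the master seed via ``numpy``'s ``SeedSequence.spawn``.  Each
trajectory's initial condition and its noise history come from its own
stream, so results are bitwise independent of how the ensemble is batched or
split across runs.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NumericalBlowupError
from .model import Potential, SimulationParams

logger = logging.getLogger(__name__)

_CHUNK_STEPS = 512  # noise is drawn and blow-up is checked per chunk


@dataclass
class EnsembleState:
    """Positions/velocities of every trajectory at a common time (unwrapped x)."""

    x: np.ndarray
    v: np.ndarray
    t: float

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if self.x.shape != self.v.shape:
            raise InvalidInputError("positions and velocities must have equal length")


@dataclass
class TrajectoryRecord:
    """Ensemble coordinates sampled on a fixed (stroboscopic) time grid.

    ``positions`` has shape (n_traj, n_samples); ``velocities`` is optional
    with the same shape.  ``params`` and ``seed`` record provenance.
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None
    params: SimulationParams | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.positions.shape[1] != len(self.times):
            raise InvalidInputError("position matrix does not match the time grid")
        if self.velocities is not None and self.velocities.shape != self.positions.shape:
            raise InvalidInputError("velocity matrix does not match the position matrix")

    @property
    def n_traj(self) -> int:
        return self.positions.shape[0]


def spawn_streams(seed: int, n_traj: int) -> list[np.random.Generator]:
    """One independent Philox generator per trajectory, derived from ``seed``."""
    seqs = np.random.SeedSequence(int(seed)).spawn(int(n_traj))
    return [np.random.Generator(np.random.Philox(s)) for s in seqs]


def draw_initial_conditions(
    n: int,
    x_range=(0.0, 2.0 * np.pi),
    v_range=(-2.0, 2.0),
    rng: np.random.Generator | None = None,
) -> EnsembleState:
    """Uniform, mutually independent initial positions and velocities."""
    if n < 1:
        raise InvalidInputError("ensemble size must be at least 1")
    for lo, hi in (x_range, v_range):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise InvalidInputError("initial-condition range must satisfy lo < hi")
    rng = rng if rng is not None else np.random.default_rng()
    x = rng.uniform(x_range[0], x_range[1], size=n)
    v = rng.uniform(v_range[0], v_range[1], size=n)
    return EnsembleState(x=x, v=v, t=0.0)


def _heun_step(x, v, t, dt, pot: Potential, a, omega, m, gamma, noise_v):
    """One predictor–corrector update; ``noise_v`` is the (scaled) increment on v."""
    f1 = (pot.force(x) + a * np.cos(omega * t) - gamma * v) / m
    xp = x + dt * v
    vp = v + dt * f1 + noise_v
    f2 = (pot.force(xp) + a * np.cos(omega * (t + dt)) - gamma * vp) / m
    xn = x + 0.5 * dt * (v + vp)
    vn = v + 0.5 * dt * (f1 + f2) + noise_v
    return xn, vn


def step_weak2(
    state: EnsembleState,
    params: SimulationParams,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
    gamma: float = 1.0,
) -> EnsembleState:
    """Advance the ensemble by one step of the weak order-2 scheme.

    Convenience single-step entry point (one shared ``rng``); ensemble
    simulations use per-trajectory streams internally via
    :func:`simulate_ensemble`.
    """
    dt = params.dt if dt is None else float(dt)
    if not 0 < dt < params.period:
        raise InvalidInputError("dt must satisfy 0 < dt < drive period")
    sigma = np.sqrt(2.0 * params.theta * dt) / params.m
    if sigma > 0:
        rng = rng if rng is not None else np.random.default_rng(params.seed)
        noise = sigma * rng.standard_normal(state.x.shape)
    else:
        noise = 0.0
    x, v = _heun_step(
        state.x, state.v, state.t, dt, params.potential, params.a, params.omega,
        params.m, gamma, noise,
    )
    _raise_on_blowup(x, v)
    return EnsembleState(x=x, v=v, t=state.t + dt)


def _raise_on_blowup(x, v):
    ok = np.isfinite(x) & np.isfinite(v)
    if not ok.all():
        bad = np.flatnonzero(~ok)
        raise NumericalBlowupError(
            f"non-finite state in trajectories {bad[:8].tolist()}"
            + ("..." if bad.size > 8 else ""),
            trajectory_indices=bad.tolist(),
        )


def _integrate(
    x: np.ndarray,
    v: np.ndarray,
    params: SimulationParams,
    n_steps: int,
    sample_stride: int,
    gens: list[np.random.Generator] | None,
    record_velocity: bool,
    gamma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Shared fixed-grid integration loop (stochastic when ``gens`` is given)."""
    dt = params.dt
    n = x.size
    n_samples = n_steps // sample_stride + 1
    times = np.arange(n_samples) * (sample_stride * dt)
    X = np.empty((n_samples, n))
    V = np.empty((n_samples, n)) if record_velocity else None
    X[0] = x
    if V is not None:
        V[0] = v
    sigma = np.sqrt(2.0 * params.theta * dt) / params.m
    pot, a, omega, m = params.potential, params.a, params.omega, params.m
    k_sample = 1
    t0 = _time.perf_counter()
    next_report = n_steps // 10 or n_steps
    with np.errstate(over="ignore", invalid="ignore"):
        for start in range(0, n_steps, _CHUNK_STEPS):
            k = min(_CHUNK_STEPS, n_steps - start)
            if gens is not None and sigma > 0:
                noise = np.empty((k, n))
                for j, g in enumerate(gens):
                    noise[:, j] = g.standard_normal(k)
                noise *= sigma
            else:
                noise = None
            for i in range(k):
                step = start + i
                z = noise[i] if noise is not None else 0.0
                x, v = _heun_step(x, v, step * dt, dt, pot, a, omega, m, gamma, z)
                if (step + 1) % sample_stride == 0:
                    X[k_sample] = x
                    if V is not None:
                        V[k_sample] = v
                    k_sample += 1
            _raise_on_blowup(x, v)
            if start + k >= next_report:
                logger.debug(
                    "integrated %d/%d steps (%.1f s)",
                    start + k, n_steps, _time.perf_counter() - t0,
                )
                next_report += n_steps // 10 or n_steps
    logger.info(
        "integrated %d trajectories × %d steps in %.2f s",
        n, n_steps, _time.perf_counter() - t0,
    )
    Xo = np.ascontiguousarray(X.T)
    Vo = np.ascontiguousarray(V.T) if V is not None else None
    return times, Xo, Vo


def _resolve_steps(params: SimulationParams, sample_stride_periods: int):
    if sample_stride_periods < 1:
        raise InvalidInputError("sample stride must be at least one drive period")
    spp = params.steps_per_period
    n_periods = int(round(params.t_max / params.period))
    if n_periods < sample_stride_periods:
        raise InvalidInputError("horizon shorter than one sampling stride")
    # horizon rounded to a whole number of drive periods (stroboscopic grid)
    n_steps = n_periods * spp
    sample_stride = sample_stride_periods * spp
    return n_steps, sample_stride


def estimate_record_bytes(params: SimulationParams, sample_stride_periods=1,
                          record_velocity=False) -> int:
    n_steps, stride = _resolve_steps(params, sample_stride_periods)
    n_samples = n_steps // stride + 1
    return params.n_traj * n_samples * 8 * (2 if record_velocity else 1)


def simulate_ensemble(
    params: SimulationParams,
    sample_stride_periods: int = 1,
    record_velocity: bool = False,
    traj_slice: slice | None = None,
    max_bytes: int = 2_000_000_000,
) -> TrajectoryRecord:
    """Integrate a thermal ensemble and record it stroboscopically.

    Samples are stored every ``sample_stride_periods`` drive periods (the
    natural grid for period-averaged observables).  ``traj_slice`` restricts
    the run to a subset of the ensemble *without* changing any trajectory's
    stream: simulating trajectories [i:j] reproduces rows [i:j] of the full
    run bitwise.
    """
    est = estimate_record_bytes(params, sample_stride_periods, record_velocity)
    if est > max_bytes:
        raise InvalidInputError(
            f"requested record needs ~{est/1e9:.2f} GB > limit {max_bytes/1e9:.2f} GB; "
            "increase the sampling stride or reduce n_traj/t_max"
        )
    n_steps, stride = _resolve_steps(params, sample_stride_periods)
    gens = spawn_streams(params.seed, params.n_traj)
    if traj_slice is not None:
        gens = gens[traj_slice]
    x0 = np.array([g.uniform(*params.x_range) for g in gens])
    v0 = np.array([g.uniform(*params.v_range) for g in gens])
    times, X, V = _integrate(
        x0, v0, params, n_steps, stride, gens, record_velocity
    )
    return TrajectoryRecord(times=times, positions=X, velocities=V,
                            params=params, seed=params.seed)


def simulate_deterministic(
    params: SimulationParams,
    x0,
    v0,
    sample_stride_periods: int = 1,
    record_velocity: bool = False,
) -> TrajectoryRecord:
    """Noise-free (θ = 0) integration from an explicit list of initial conditions."""
    if params.theta != 0:
        raise InvalidInputError("simulate_deterministic requires theta = 0")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    v0 = np.atleast_1d(np.asarray(v0, dtype=float))
    if x0.shape != v0.shape:
        raise InvalidInputError("x0 and v0 must have the same length")
    n_steps, stride = _resolve_steps(params, sample_stride_periods)
    times, X, V = _integrate(
        x0.copy(), v0.copy(), params, n_steps, stride, None, record_velocity
    )
    return TrajectoryRecord(times=times, positions=X, velocities=V,
                            params=params, seed=None)


# --------------------------------------------------------------------------
# Lyapunov spectrum (deterministic dynamics)
# --------------------------------------------------------------------------


@dataclass
class LyapunovResult:
    """Benettin/QR estimate of both Lyapunov exponents of the (x, v) flow.

    ``exponents`` has shape (n_ic, 2) sorted descending; ``largest`` is the
    first column.  ``trace`` holds the running estimate of the largest
    exponent at each renormalization (for convergence inspection); the
    ``converged`` flag compares the last estimate against the one at half the
    horizon.
    """

    exponents: np.ndarray
    trace_times: np.ndarray
    trace: np.ndarray
    converged: np.ndarray

    @property
    def largest(self) -> np.ndarray:
        return self.exponents[:, 0]


def lyapunov_spectrum(
    params: SimulationParams,
    x0,
    v0,
    t_max: float | None = None,
    gamma: float = 1.0,
    renorm_every: int = 10,
    conv_tol: float = 0.05,
) -> LyapunovResult:
    """Both Lyapunov exponents of the deterministic flow via tangent-space QR.

    The tangent map uses the Jacobian of the drift,
    J = [[0, 1], [−U″(x)/m, −γ/m]], propagated with the same Heun scheme as
    the base trajectory and re-orthonormalized every ``renorm_every`` steps.
    Requires θ = 0.
    """
    if params.theta != 0:
        raise InvalidInputError("Lyapunov estimation requires theta = 0")
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    v = np.atleast_1d(np.asarray(v0, dtype=float)).copy()
    if x.shape != v.shape:
        raise InvalidInputError("x0 and v0 must have the same length")
    n = x.size
    dt = params.dt
    t_max = float(t_max) if t_max is not None else params.t_max
    n_steps = max(int(round(t_max / dt)), 2 * renorm_every)
    pot, a, omega, m = params.potential, params.a, params.omega, params.m

    Q = np.broadcast_to(np.eye(2), (n, 2, 2)).copy()
    logs = np.zeros((n, 2))
    trace, trace_times = [], []

    def jac(xx):
        J = np.zeros((n, 2, 2))
        J[:, 0, 1] = 1.0
        J[:, 1, 0] = pot.force_gradient(xx) / m
        J[:, 1, 1] = -gamma / m
        return J

    with np.errstate(over="ignore", invalid="ignore"):
        for step in range(n_steps):
            t = step * dt
            J1 = jac(x)
            f1 = (pot.force(x) + a * np.cos(omega * t) - gamma * v) / m
            xp = x + dt * v
            vp = v + dt * f1
            J2 = jac(xp)
            Qp = Q + dt * (J1 @ Q)
            Qn = Q + 0.5 * dt * (J1 @ Q + J2 @ Qp)
            f2 = (pot.force(xp) + a * np.cos(omega * (t + dt)) - gamma * vp) / m
            x = x + 0.5 * dt * (v + vp)
            v = v + 0.5 * dt * (f1 + f2)
            Q = Qn
            if (step + 1) % renorm_every == 0:
                Q, R = np.linalg.qr(Q)
                diag = np.einsum("nii->ni", R)
                sign = np.sign(diag)
                sign[sign == 0] = 1.0
                Q *= sign[:, None, :]
                logs += np.log(np.abs(diag))
                t_now = (step + 1) * dt
                trace.append(logs[:, 0] / t_now)
                trace_times.append(t_now)
        _raise_on_blowup(x, v)

    t_total = n_steps - (n_steps % renorm_every)
    exponents = logs / (t_total * dt)
    order = np.argsort(-exponents, axis=1)
    exponents = np.take_along_axis(exponents, order, axis=1)
    trace = np.array(trace).T
    trace_times = np.array(trace_times)
    half = trace.shape[1] // 2
    converged = np.abs(trace[:, -1] - trace[:, half]) <= conv_tol
    if not converged.all():
        logger.warning("Lyapunov estimate not converged for %d initial condition(s)",
                       int((~converged).sum()))
    return LyapunovResult(exponents=exponents, trace_times=trace_times,
                          trace=trace, converged=converged)


def lyapunov_exponent(params, x0, v0, t_max=None, **kwargs) -> LyapunovResult:
    """Largest-exponent convenience wrapper around :func:`lyapunov_spectrum`."""
    return lyapunov_spectrum(params, x0, v0, t_max=t_max, **kwargs)
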