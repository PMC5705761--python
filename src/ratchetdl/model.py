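"""Ratchet potential, external drive, and unit scaling.

The physical system is an inertial Brownian particle of mass ``M`` moving in a
spatially periodic potential with broken reflection symmetry (a *ratchet*),
driven by an unbiased time-periodic force ``A cos(Ωt)`` and coupled to a
thermal bath at temperature ``T``.  After rescaling lengths by the potential
period ``L`` and times by ``τ̃₀ = ΓL²/ΔU`` the dynamics reads, in
dimensionless variables,

    m ẍ + ẋ = −U′(x) + a cos(ω t) + √(2θ) ξ(t),

where ``ξ`` is zero-mean δ-correlated Gaussian white noise and the
2π-periodic double-sine potential with asymmetry phase φ is

    U(x) = −[sin x + c · sin(2x + φ − π/2)],        c = 1/4 by default.

At φ = π/2 this is the canonical ratchet form −sin x − ¼ sin 2x used for all
default parameter values (m = 6, a = 1.899, ω = 0.403).  The dimensionless
temperature θ = k_B T / ΔU measures thermal energy against the barrier.

This module owns the potential/force evaluation, the dimensional ↔
dimensionless maps, the four characteristic time scales, and the
``SimulationParams`` container consumed by the Langevin engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .errors import InvalidInputError

TWO_PI = 2.0 * math.pi

#: Fig.-1-style default physics: dimensionless mass, drive amplitude, frequency.
DEFAULT_MASS = 6.0
DEFAULT_AMPLITUDE = 1.899
DEFAULT_FREQUENCY = 0.403


@dataclass(frozen=True)
class Potential:
    """Double-sine ratchet potential ``−scale·[sin x + asymmetry·sin(2x+φ−π/2)]``.

    ``scale=0`` gives a free particle, ``asymmetry=0`` the reflection-symmetric
    ``−scale·sin x`` (no ratchet effect), and the defaults the canonical ratchet.
    Methods are vectorized and unchecked; use the module-level wrappers for
    validated evaluation.
    """

    scale: float = 1.0
    asymmetry: float = 0.25
    phi: float = math.pi / 2

    def energy(self, x):
        shift = self.phi - math.pi / 2
        return -self.scale * (np.sin(x) + self.asymmetry * np.sin(2.0 * x + shift))

    def force(self, x):
        """−U′(x)."""
        shift = self.phi - math.pi / 2
        return self.scale * (np.cos(x) + 2.0 * self.asymmetry * np.cos(2.0 * x + shift))

    def force_gradient(self, x):
        """d(−U′)/dx = −U″(x); needed by the tangent-space (Lyapunov) dynamics."""
        shift = self.phi - math.pi / 2
        return -self.scale * (np.sin(x) + 4.0 * self.asymmetry * np.sin(2.0 * x + shift))


def _check_finite(x, name="x"):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"non-finite {name} passed to potential evaluation")
    return arr


def potential_energy(x, phi: float = math.pi / 2):
    """Dimensionless ratchet potential U(x) at asymmetry phase ``phi``.

    2π-periodic; reduces to −sin x − ¼ sin 2x at φ = π/2.
    """
    return Potential(phi=phi).energy(_check_finite(x))


def potential_force(x, phi: float = math.pi / 2):
    """−U′(x) = cos x + ½ cos(2x + φ − π/2), the conservative force."""
    return Potential(phi=phi).force(_check_finite(x))


def driving_force(t, a: float = DEFAULT_AMPLITUDE, omega: float = DEFAULT_FREQUENCY):
    """Unbiased time-periodic drive a·cos(ωt); zero mean over one period."""
    return a * np.cos(omega * np.asarray(t, dtype=float))


def wrap_position(x):
    """Map unwrapped coordinates onto one spatial period [0, 2π)."""
    return np.mod(x, TWO_PI)


def barrier_height(phi: float = math.pi / 2, asymmetry: float = 0.25) -> float:
    """max U − min U over one spatial period, by dense grid + local refinement."""
    pot = Potential(asymmetry=asymmetry, phi=phi)
    grid = np.linspace(0.0, TWO_PI, 20001, endpoint=False)
    vals = pot.energy(grid)
    h = grid[1] - grid[0]

    def refine(x0, sign):
        res = optimize.minimize_scalar(
            lambda x: sign * pot.energy(x),
            bounds=(x0 - 2 * h, x0 + 2 * h),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return sign * res.fun

    lo = refine(grid[int(np.argmin(vals))], +1.0)
    hi = refine(grid[int(np.argmax(vals))], -1.0)
    return float(hi - lo)


# --------------------------------------------------------------------------
# Dimensional parameters and scaling
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DimensionalParams:
    """Physical (dimensionful) parameters of the ratchet.

    Units are arbitrary but consistent: ``mass`` [mass], ``friction``
    [mass/time], ``period`` L [length], ``barrier`` ΔU [energy], ``amplitude``
    A [force], ``frequency`` Ω [1/time], ``kT`` = k_B·T [energy], ``phi``
    [rad].
    """

    mass: float
    friction: float
    period: float
    barrier: float
    amplitude: float
    frequency: float
    kT: float
    phi: float = math.pi / 2

    def __post_init__(self):
        for name in ("mass", "friction", "period", "barrier", "frequency"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be strictly positive")
        if self.kT < 0:
            raise InvalidInputError("kT must be non-negative")


@dataclass(frozen=True)
class TimeScales:
    """The four characteristic times of the dimensional model.

    tau0 = ΓL²/ΔU  (overdamped max→min slide, the unit of time),
    tau1 = M/Γ     (velocity relaxation of the free particle),
    tau2 = √(ML²/ΔU) (conservative oscillation scale),
    tau3 = 2π/Ω    (drive period).  Identity: tau2² = tau0·tau1.
    """

    tau0: float
    tau1: float
    tau2: float
    tau3: float


def characteristic_times(p: DimensionalParams) -> TimeScales:
    tau0 = p.friction * p.period**2 / p.barrier
    tau1 = p.mass / p.friction
    tau2 = math.sqrt(p.mass * p.period**2 / p.barrier)
    tau3 = TWO_PI / p.frequency
    return TimeScales(tau0, tau1, tau2, tau3)


def nondimensionalize(p: DimensionalParams) -> "SimulationParams":
    """Map dimensional parameters to the dimensionless groups.

    m = M/(Γ τ̃₀), a = (L/ΔU) A, ω = τ̃₀ Ω, θ = k_B T / ΔU.  Numerical
    fields of the returned ``SimulationParams`` are left at their defaults.
    """
    tau0 = characteristic_times(p).tau0
    return SimulationParams(
        m=p.mass / (p.friction * tau0),
        a=p.period * p.amplitude / p.barrier,
        omega=tau0 * p.frequency,
        theta=p.kT / p.barrier,
        phi=p.phi,
    )


def dimensionalize(
    sp: "SimulationParams", friction: float, period: float, barrier: float
) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` given the three unit scales."""
    if not (friction > 0 and period > 0 and barrier > 0):
        raise InvalidInputError("unit scales must be strictly positive")
    tau0 = friction * period**2 / barrier
    return DimensionalParams(
        mass=sp.m * friction * tau0,
        friction=friction,
        period=period,
        barrier=barrier,
        amplitude=sp.a * barrier / period,
        frequency=sp.omega / tau0,
        kT=sp.theta * barrier,
        phi=sp.phi,
    )


# --------------------------------------------------------------------------
# Dimensionless simulation parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationParams:
    """Full dimensionless parameterization of one ensemble experiment.

    Physics: mass ``m``, drive amplitude ``a`` and frequency ``omega``, thermal
    noise intensity ``theta`` (= k_BT/ΔU), potential asymmetry phase ``phi``.

    Numerics: the integration step is ``dt = T / steps_per_period`` with drive
    period ``T = 2π/ω``, which makes T an exact integer multiple of dt by
    construction.  ``t_max`` is the horizon, ``n_traj`` the ensemble size,
    ``seed`` the master RNG seed, and ``x_range``/``v_range`` the uniform
    initial-condition intervals (defaults [0, 2π] × [−2, 2]).
    """

    m: float = DEFAULT_MASS
    a: float = DEFAULT_AMPLITUDE
    omega: float = DEFAULT_FREQUENCY
    theta: float = 7.0e-4
    phi: float = math.pi / 2
    steps_per_period: int = 1000
    t_max: float = 1.0e4
    n_traj: int = 1024
    seed: int = 12345
    x_range: tuple[float, float] = (0.0, TWO_PI)
    v_range: tuple[float, float] = (-2.0, 2.0)
    potential: Potential | None = None

    def __post_init__(self):
        if not self.m > 0:
            raise InvalidInputError("mass m must be strictly positive")
        if self.theta < 0:
            raise InvalidInputError("noise intensity theta must be non-negative")
        if not self.omega > 0:
            raise InvalidInputError("drive frequency omega must be strictly positive")
        if int(self.steps_per_period) < 1:
            raise InvalidInputError("steps_per_period must be a positive integer")
        if not self.t_max > 0:
            raise InvalidInputError("t_max must be strictly positive")
        if int(self.n_traj) < 1:
            raise InvalidInputError("n_traj must be at least 1")
        for rng_name in ("x_range", "v_range"):
            lo, hi = getattr(self, rng_name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise InvalidInputError(f"{rng_name} must be a finite interval lo < hi")
        if self.potential is None:
            object.__setattr__(self, "potential", Potential(phi=self.phi))

    @property
    def period(self) -> float:
        """Drive period T = 2π/ω."""
        return TWO_PI / self.omega

    @property
    def dt(self) -> float:
        """Integration step T / steps_per_period (always commensurate with T)."""
        return self.period / self.steps_per_period

    def with_(self, **kwargs) -> "SimulationParams":
        """Functional update preserving immutability."""
        return replace(self, **kwargs)
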