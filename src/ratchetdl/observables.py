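"""Diffusion and velocity statistics of trajectory ensembles.

Implements the diagnostics used to classify the ratchet's transport:

* σ²ₓ(t) — ensemble variance of the unwrapped coordinate,
* D(t) = σ²ₓ(t)/(2t) — time-dependent diffusion coefficient (increasing ⇒
  superdiffusion, decreasing ⇒ subdiffusion, flat ⇒ normal diffusion),
* v(t) — period-averaged velocity [x(t+T) − x(t)]/T over consecutive,
  non-overlapping drive periods, with its ensemble mean and variance,
* the scaling index α of σ²ₓ(t) ∼ t^α by log–log least squares,
* the crossover times τ₁, τ₂ that bound the transient sub-/superdiffusive
  regimes, extracted from a smoothed log–log slope of D(t).

All variances use the unbiased (n−1) convention; ensemble standard errors
accompany every series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .engine import TrajectoryRecord
from .errors import InvalidInputError


@dataclass
class ObservableSeries:
    """A time-indexed scalar statistic with ensemble standard errors."""

    times: np.ndarray
    values: np.ndarray
    stderr: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not (len(self.times) == len(self.values) == len(self.stderr)):
            raise InvalidInputError("series components must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(self.stderr < 0):
            raise InvalidInputError("standard errors must be non-negative")


@dataclass
class PeriodVelocityRecord:
    """Per-trajectory period-averaged velocities on consecutive drive periods."""

    window_starts: np.ndarray
    velocities: np.ndarray  # (n_traj, n_windows)
    period: float

    @property
    def n_traj(self) -> int:
        return self.velocities.shape[0]


@dataclass
class AnomalyFit:
    """Diffusion-anomaly diagnostics: scaling index and/or crossover times."""

    alpha: float | None = None
    alpha_stderr: float | None = None
    intercept: float | None = None
    window: tuple[float, float] | None = None
    tau1: float | None = None
    tau1_valid: bool = False
    tau2: float | None = None
    tau2_valid: bool = False
    t_f: float | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "alpha_stderr": self.alpha_stderr,
            "intercept": self.intercept,
            "window": list(self.window) if self.window else None,
            "tau1": self.tau1,
            "tau1_valid": self.tau1_valid,
            "tau2": self.tau2,
            "tau2_valid": self.tau2_valid,
            "t_f": self.t_f,
        }


def _variance_stderr(x: np.ndarray) -> np.ndarray:
    """Standard error of the unbiased variance via the fourth central moment."""
    n = x.shape[0]
    mu = x.mean(axis=0)
    d = x - mu
    s2 = (d**2).sum(axis=0) / (n - 1)
    m4 = (d**4).mean(axis=0)
    var_s2 = (m4 - (n - 3) / (n - 1) * s2**2) / n
    return np.sqrt(np.clip(var_s2, 0.0, None))


def position_variance(rec: TrajectoryRecord) -> ObservableSeries:
    """Unbiased ensemble variance σ²ₓ(t) of the unwrapped coordinate."""
    x = rec.positions
    if x.shape[0] < 2:
        raise InvalidInputError("position variance needs at least two trajectories")
    s2 = x.var(axis=0, ddof=1)
    return ObservableSeries(rec.times, s2, _variance_stderr(x), label="sigma2_x")


def diffusion_coefficient(var: ObservableSeries) -> ObservableSeries:
    """D(t) = σ²ₓ(t)/(2t); the t = 0 sample is dropped, negative times rejected."""
    if np.any(var.times < 0):
        raise InvalidInputError("diffusion coefficient undefined for negative times")
    keep = var.times > 0
    t = var.times[keep]
    return ObservableSeries(t, var.values[keep] / (2 * t),
                            var.stderr[keep] / (2 * t), label="D")


def period_averaged_velocity(rec: TrajectoryRecord,
                             period: float | None = None) -> PeriodVelocityRecord:
    """v(t) = [x(t+T) − x(t)]/T on consecutive non-overlapping drive periods.

    The displacement form evaluates the defining integral (1/T)∫ẋ ds exactly.
    Requires the record's sample grid to contain every multiple of T.
    """
    if period is None:
        if rec.params is None:
            raise InvalidInputError("period not given and record has no parameters")
        period = rec.params.period
    t = rec.times
    if len(t) < 2:
        raise InvalidInputError("record too short for period averaging")
    dt_grid = np.diff(t)
    if not np.allclose(dt_grid, dt_grid[0], rtol=1e-9, atol=1e-12):
        raise InvalidInputError("sample grid must be uniform")
    ratio = period / dt_grid[0]
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise InvalidInputError("sample grid is not commensurate with the drive period")
    idx = np.arange(0, len(t), k)
    xs = rec.positions[:, idx]
    v = np.diff(xs, axis=1) / period
    return PeriodVelocityRecord(window_starts=t[idx[:-1]], velocities=v, period=period)


def velocity_mean_and_variance(
    pv: PeriodVelocityRecord,
) -> tuple[ObservableSeries, ObservableSeries]:
    """Ensemble mean ⟨v(t)⟩ and unbiased variance σ²_v(t) per window."""
    v = pv.velocities
    n = v.shape[0]
    if n < 2:
        raise InvalidInputError("velocity statistics need at least two trajectories")
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    mean_series = ObservableSeries(pv.window_starts, mean, sd / np.sqrt(n),
                                   label="v_mean")
    var_series = ObservableSeries(pv.window_starts, sd**2, _variance_stderr(v),
                                  label="sigma2_v")
    return mean_series, var_series


def directed_velocity(pv: PeriodVelocityRecord, t_min: float = 0.0
                      ) -> tuple[float, float]:
    """Long-time directed velocity ⟨v⟩ = mean of ⟨v(t)⟩ over windows with t ≥ t_min.

    Returns (estimate, standard error); the error is computed across
    trajectories (per-trajectory long-time means are independent), which is
    robust to the strong temporal correlation of v(t) within a trajectory.
    """
    keep = pv.window_starts >= t_min
    if not keep.any():
        raise InvalidInputError("no windows at or after t_min")
    per_traj = pv.velocities[:, keep].mean(axis=1)
    n = per_traj.size
    se = per_traj.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    return float(per_traj.mean()), float(se)


def fit_scaling_index(
    var: ObservableSeries,
    window: tuple[float, float] | None = None,
    min_points: int = 10,
) -> AnomalyFit:
    """α from the least-squares slope of log σ²ₓ vs log t inside ``window``.

    The default window is the last decade of available data (the asymptotic
    part of the series).
    """
    t, y = var.times, var.values
    if window is None:
        window = (t[-1] / 10.0, t[-1])
    lo, hi = window
    if not lo < hi:
        raise InvalidInputError("fit window must satisfy t_lo < t_hi")
    keep = (t >= lo) & (t <= hi) & (t > 0)
    if keep.sum() < min_points:
        raise InvalidInputError(
            f"fit window contains {int(keep.sum())} samples; need >= {min_points}"
        )
    if np.any(y[keep] <= 0):
        raise InvalidInputError("nonpositive variance values inside the fit window")
    res = stats.linregress(np.log(t[keep]), np.log(y[keep]))
    return AnomalyFit(
        alpha=float(res.slope),
        alpha_stderr=float(res.stderr),
        intercept=float(res.intercept),
        window=(float(lo), float(hi)),
        t_f=float(t[-1]),
    )


def loglog_slope(
    series: ObservableSeries,
    bandwidth_decades: float = 0.25,
    polyorder: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed value and d log₁₀ y / d log₁₀ t on a uniform log-time grid.

    A Savitzky–Golay local polynomial of width ``bandwidth_decades`` is
    applied to log₁₀ y interpolated onto a uniform grid in log₁₀ t.  Returns
    (log10_t_grid, smoothed_log10_y, slope).
    """
    keep = series.times > 0
    t, y = series.times[keep], series.values[keep]
    if np.any(y <= 0):
        raise InvalidInputError("log-log smoothing requires positive values")
    lt, ly = np.log10(t), np.log10(y)
    span = lt[-1] - lt[0]
    delta = bandwidth_decades / 10.0
    n_grid = int(np.floor(span / delta)) + 1
    if n_grid < 25:
        raise InvalidInputError("series too short for the requested bandwidth")
    grid = lt[0] + np.arange(n_grid) * delta
    ly_u = np.interp(grid, lt, ly)
    window = 11  # = bandwidth_decades / delta + 1, always odd
    smooth = signal.savgol_filter(ly_u, window, polyorder)
    slope = signal.savgol_filter(ly_u, window, polyorder, deriv=1, delta=delta)
    return grid, smooth, slope


def detect_crossovers(
    D: ObservableSeries,
    bandwidth_decades: float = 0.25,
    slope_eps: float = 0.05,
) -> AnomalyFit:
    """Crossover times τ₁, τ₂ from the smoothed log–log slope s(t) of D(t).

    τ₁ is the first downward zero crossing of s (the maximum of D, end of the
    superdiffusive stage); τ₂ is the first later time at which |s| stays
    below ``slope_eps`` for a full smoothing window (onset of normal
    diffusion).  A missing crossing within the horizon leaves the
    corresponding validity flag False.  Requires at least two decades of data.
    """
    keep = D.times > 0
    t = D.times[keep]
    if len(t) < 4 or np.log10(t[-1] / t[0]) < 2.0:
        raise InvalidInputError("crossover detection needs >= 2 decades of data")
    grid, _, s = loglog_slope(D, bandwidth_decades)
    fit = AnomalyFit(t_f=float(t[-1]))

    pos = np.flatnonzero(s > 0)
    if pos.size:
        i0 = pos[0]
        down = np.flatnonzero((s[i0:-1] > 0) & (s[i0 + 1:] <= 0))
        if down.size:
            j = i0 + down[0]
            frac = s[j] / (s[j] - s[j + 1])
            lt_cross = grid[j] + frac * (grid[j + 1] - grid[j])
            fit.tau1 = float(10.0 ** lt_cross)
            fit.tau1_valid = True
    if fit.tau1_valid:
        w = 11
        start = int(np.searchsorted(grid, np.log10(fit.tau1)))
        for j in range(start, len(s) - w + 1):
            if np.all(np.abs(s[j:j + w]) < slope_eps):
                fit.tau2 = float(10.0 ** grid[j])
                fit.tau2_valid = True
                break
    return fit
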