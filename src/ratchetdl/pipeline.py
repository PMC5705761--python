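"""Experiment orchestration, configuration, and serialization.

An experiment is a θ-sweep: for each thermal noise intensity the Langevin
ensemble is simulated and the full set of diagnostics is computed — σ²ₓ(t),
D(t), ⟨v(t)⟩, σ²_v(t), the anomaly fit (α, τ₁, τ₂), the three-state
transition matrix and the occupation series.  Every run writes a manifest
with the resolved configuration, derived seeds, package versions and
runtimes, and reruns with the same configuration reproduce all numbers
byte-identically.

Configuration lives in a YAML document validated by a pydantic schema; see
``configs/`` in the repository for annotated examples.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .engine import TrajectoryRecord, simulate_ensemble
from .errors import InvalidInputError
from .model import Potential, SimulationParams
from .observables import (
    ObservableSeries,
    detect_crossovers,
    diffusion_coefficient,
    directed_velocity,
    fit_scaling_index,
    period_averaged_velocity,
    position_variance,
    velocity_mean_and_variance,
)
from .states import (
    State,
    StateModel,
    coarse_grain,
    occupation_series,
    transition_probabilities,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


# --------------------------------------------------------------------------
# Configuration schema
# --------------------------------------------------------------------------


class PhysicsConfig(BaseModel):
    """Dimensionless physics; defaults are the reference parameter set."""

    m: float = 6.0
    a: float = 1.899
    omega: float = 0.403
    theta: float = 7.0e-4
    phi: float = float(np.pi / 2)
    potential_scale: float = 1.0
    asymmetry: float = 0.25

    @field_validator("m", "omega")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be strictly positive")
        return v

    @field_validator("theta")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("theta must be non-negative")
        return v


class NumericsConfig(BaseModel):
    steps_per_period: int = Field(1000, ge=1)
    t_max: float = Field(1.0e4, gt=0)
    n_traj: int = Field(1024, ge=1)
    seed: int = 12345
    sample_stride_periods: int = Field(1, ge=1)
    record_velocity: bool = False
    store_trajectories: bool = False
    x_range: tuple[float, float] = (0.0, float(2 * np.pi))
    v_range: tuple[float, float] = (-2.0, 2.0)


class AnalysisConfig(BaseModel):
    alpha_window_decades: float = Field(1.0, gt=0)
    smoothing_bandwidth_decades: float = Field(0.25, gt=0)
    slope_epsilon: float = Field(0.05, gt=0)
    threshold_nu: float = Field(0.2, gt=0)
    state_centers: tuple[float, float, float] = (-0.4, 0.0, 0.4)
    lag_periods: int = Field(1, ge=1)
    transient_periods: int = Field(1000, ge=0)
    attractor_merge_tol: float = Field(0.05, gt=0)


class ExperimentConfig(BaseModel):
    physics: PhysicsConfig = PhysicsConfig()
    numerics: NumericsConfig = NumericsConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    thetas: list[float] = []
    output_dir: str = "results"

    def sim_params(self, theta: float | None = None,
                   seed: int | None = None) -> SimulationParams:
        ph, nu = self.physics, self.numerics
        return SimulationParams(
            m=ph.m, a=ph.a, omega=ph.omega,
            theta=ph.theta if theta is None else theta,
            phi=ph.phi,
            steps_per_period=nu.steps_per_period,
            t_max=nu.t_max, n_traj=nu.n_traj,
            seed=nu.seed if seed is None else seed,
            x_range=tuple(nu.x_range), v_range=tuple(nu.v_range),
            potential=Potential(scale=ph.potential_scale,
                                asymmetry=ph.asymmetry, phi=ph.phi),
        )

    def state_model(self) -> StateModel:
        an = self.analysis
        return StateModel(centers=tuple(an.state_centers), nu=an.threshold_nu,
                          lag=an.lag_periods)


def load_config(path) -> ExperimentConfig:
    """Read and schema-validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError
        raise InvalidInputError(f"invalid experiment configuration: {exc}") from exc


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def series_to_csv(series: ObservableSeries, path) -> None:
    data = np.column_stack([series.times, series.values, series.stderr])
    np.savetxt(path, data, fmt=_FLOAT_FMT, delimiter=",",
               header=f"time,{series.label or 'value'},stderr", comments="")


def series_from_csv(path, label: str = "") -> ObservableSeries:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return ObservableSeries(data[:, 0], data[:, 1], data[:, 2], label=label)


def save_record(rec: TrajectoryRecord, path) -> None:
    """Binary array container (.npz) plus a JSON metadata sidecar."""
    path = Path(path)
    arrays = {"times": rec.times, "positions": rec.positions}
    if rec.velocities is not None:
        arrays["velocities"] = rec.velocities
    np.savez_compressed(path, **arrays)
    meta = {"seed": rec.seed, "package_version": __version__}
    if rec.params is not None:
        p = rec.params
        meta["params"] = {
            "m": p.m, "a": p.a, "omega": p.omega, "theta": p.theta, "phi": p.phi,
            "steps_per_period": p.steps_per_period, "t_max": p.t_max,
            "n_traj": p.n_traj, "seed": p.seed,
            "x_range": list(p.x_range), "v_range": list(p.v_range),
            "potential": {"scale": p.potential.scale,
                          "asymmetry": p.potential.asymmetry,
                          "phi": p.potential.phi},
        }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_record(path) -> TrajectoryRecord:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        times = npz["times"]
        positions = npz["positions"]
        velocities = npz["velocities"] if "velocities" in npz else None
    params = None
    seed = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        seed = meta.get("seed")
        if "params" in meta:
            pd = dict(meta["params"])
            pot = pd.pop("potential")
            params = SimulationParams(
                **{k: (tuple(v) if k.endswith("_range") else v)
                   for k, v in pd.items()},
                potential=Potential(**pot),
            )
    return TrajectoryRecord(times=times, positions=positions,
                            velocities=velocities, params=params, seed=seed)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------


def analyze_record(rec: TrajectoryRecord, analysis: AnalysisConfig,
                   state_model: StateModel) -> dict:
    """All diagnostics for one trajectory record, as in-memory objects."""
    var = position_variance(rec)
    D = diffusion_coefficient(var)
    pv = period_averaged_velocity(rec)
    v_mean, v_var = velocity_mean_and_variance(pv)
    t_f = var.times[-1]
    window = (t_f / 10 ** analysis.alpha_window_decades, t_f)
    fit = fit_scaling_index(var, window=window)
    try:
        cross = detect_crossovers(D, analysis.smoothing_bandwidth_decades,
                                  analysis.slope_epsilon)
        fit.tau1, fit.tau1_valid = cross.tau1, cross.tau1_valid
        fit.tau2, fit.tau2_valid = cross.tau2, cross.tau2_valid
    except InvalidInputError:
        logger.warning("series too short for crossover detection; taus skipped")
    seqs = coarse_grain(pv, state_model)
    period = pv.period
    pool_start = analysis.transient_periods * period
    t_hi = pv.window_starts[-1]
    if pool_start >= t_hi:
        pool_start = 0.0  # short runs: pool everything rather than nothing
    tm = transition_probabilities(seqs, t_range=(pool_start, t_hi))
    occ = occupation_series(seqs)
    v_directed, v_directed_se = directed_velocity(pv, t_min=pool_start)
    return {
        "variance": var, "diffusion": D, "pv": pv,
        "v_mean": v_mean, "v_var": v_var,
        "anomaly": fit, "transitions": tm, "occupations": occ,
        "directed_velocity": (v_directed, v_directed_se),
        "pool_start": pool_start,
    }


def _run_single(cfg: ExperimentConfig, theta: float, seed: int, outdir: Path) -> dict:
    t0 = time.perf_counter()
    params = cfg.sim_params(theta=theta, seed=seed)
    rec = simulate_ensemble(
        params,
        sample_stride_periods=cfg.numerics.sample_stride_periods,
        record_velocity=cfg.numerics.record_velocity,
    )
    res = analyze_record(rec, cfg.analysis, cfg.state_model())
    outdir.mkdir(parents=True, exist_ok=True)
    series_to_csv(res["variance"], outdir / "sigma2_x.csv")
    series_to_csv(res["diffusion"], outdir / "diffusion.csv")
    series_to_csv(res["v_mean"], outdir / "v_mean.csv")
    series_to_csv(res["v_var"], outdir / "sigma2_v.csv")
    occ = res["occupations"]
    occ_data = np.column_stack([res["pv"].window_starts]
                               + [occ[s] for s in State])
    np.savetxt(outdir / "occupations.csv", occ_data, fmt=_FLOAT_FMT, delimiter=",",
               header="time,p_minus,p_zero,p_plus,p_other", comments="")
    _write_json(res["anomaly"].to_dict(), outdir / "anomaly.json")
    summary = res["transitions"].to_dict()
    summary["directed_velocity"] = res["directed_velocity"][0]
    summary["directed_velocity_stderr"] = res["directed_velocity"][1]
    summary["pool_start_time"] = res["pool_start"]
    _write_json(summary, outdir / "transitions.json")
    if cfg.numerics.store_trajectories:
        save_record(rec, outdir / "record.npz")
    return {
        "theta": theta,
        "seed": seed,
        "runtime_s": time.perf_counter() - t0,
        "alpha": res["anomaly"].alpha,
        "tau1": res["anomaly"].tau1,
        "directed_velocity": res["directed_velocity"][0],
        "status": "ok",
    }


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, well-separated per-θ seeds below 2**31."""
    state = np.random.SeedSequence(int(master_seed)).generate_state(n, np.uint64)
    return [int(s % (2**31)) for s in state]


def run_experiment(cfg: ExperimentConfig, output_dir=None,
                   master_seed: int | None = None) -> dict:
    """Run the θ-sweep and write the full result bundle to disk.

    A failure for one θ is recorded in the manifest and does not abort the
    remaining runs.  Returns the manifest (also written as manifest.json).
    """
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = cfg.numerics.seed if master_seed is None else master_seed
    thetas = list(cfg.thetas)  # an empty sweep is valid and produces zero runs
    seeds = derive_seeds(master, max(len(thetas), 1))
    runs = []
    for theta, seed in zip(thetas, seeds):
        sub = outdir / f"theta_{theta:g}"
        try:
            runs.append(_run_single(cfg, theta, seed, sub))
        except Exception as exc:  # isolate the failing theta, keep sweeping
            logger.exception("run failed for theta=%g", theta)
            runs.append({"theta": theta, "seed": seed, "status": "error",
                         "error": f"{type(exc).__name__}: {exc}"})
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "master_seed": master,
        "config": cfg.model_dump(),
        "runs": runs,
    }
    _write_json(manifest, outdir / "manifest.json")
    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(cfg.model_dump(), sort_keys=True))
    return manifest
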