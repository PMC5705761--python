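"""Reference processes, experiment orchestration, serialization, CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from ratchetdl import (
    InvalidInputError,
    ObservableSeries,
    ReferenceProcessSpec,
    diffusion_coefficient,
    fit_scaling_index,
    generate_reference,
    ou_exact_step,
    position_variance,
)
from ratchetdl.cli import main as cli_main
from ratchetdl.pipeline import (
    ExperimentConfig,
    load_config,
    load_record,
    run_experiment,
    save_record,
    series_from_csv,
    series_to_csv,
)


# --------------------------------------------------------------------------
# Reference processes
# --------------------------------------------------------------------------


def test_ballistic_identical_speed_has_zero_variance():
    spec = ReferenceProcessSpec("ballistic", n_traj=32, t_max=100, dt=1.0,
                                params={"v0": 0.4})
    rec = generate_reference(spec)
    var = position_variance(rec)
    np.testing.assert_allclose(var.values, 0.0, atol=1e-20)


def test_ballistic_uniform_speeds_are_exactly_quadratic():
    """v₀ ~ U(−2, 2): σ²ₓ(t) = Var(v₀)·t², Var → 4/3, and α = 2 exactly."""
    spec = ReferenceProcessSpec("ballistic", n_traj=4096, t_max=1000, dt=10.0,
                                seed=3, params={"v0_range": (-2.0, 2.0)})
    rec = generate_reference(spec)
    var = position_variance(rec)
    fit = fit_scaling_index(var, window=(var.times[1], var.times[-1]))
    assert fit.alpha == pytest.approx(2.0, abs=1e-10)
    sample_var = var.values[-1] / var.times[-1] ** 2
    se = (4 / 3) * np.sqrt(2 / spec.n_traj)
    assert abs(sample_var - 4 / 3) < 3 * se


def test_free_brownian_is_normally_diffusive():
    theta = 7e-4
    spec = ReferenceProcessSpec("free-brownian", n_traj=2048, t_max=1e4, dt=10.0,
                                seed=5, params={"theta": theta})
    rec = generate_reference(spec)
    var = position_variance(rec)
    fit = fit_scaling_index(var, window=(var.times[1], var.times[-1]))
    assert fit.alpha == pytest.approx(1.0, abs=0.05)
    D = diffusion_coefficient(var)
    se = theta * np.sqrt(2 / spec.n_traj)
    assert abs(D.values[-1] - theta) < 3 * se


def test_ou_exact_transition_reaches_stationarity():
    """Exact discrete OU sampling: ⟨v²⟩ = θ/m with no integrator bias."""
    theta, m = 0.5, 2.0
    spec = ReferenceProcessSpec("ornstein-uhlenbeck", n_traj=8192, t_max=30,
                                dt=0.5, seed=6, params={"theta": theta, "m": m})
    rec = generate_reference(spec)
    v = rec.positions[:, -1]
    se = (theta / m) * np.sqrt(2 / spec.n_traj)
    assert abs((v**2).mean() - theta / m) < 3 * se


def test_ou_exact_step_deterministic_part():
    assert ou_exact_step(1.0, 0.5, 2.0, 0.3, 0.0) == pytest.approx(np.exp(-0.25))


def test_piecewise_msd_recovers_exponents_segmentwise():
    spec = ReferenceProcessSpec("piecewise-power-msd", t_max=1e5, dt=10.0,
                                params={"exponents": [2.0, 0.5],
                                        "break_times": [1e3]})
    series = generate_reference(spec)
    early = fit_scaling_index(series, window=(10.0, 900.0))
    late = fit_scaling_index(series, window=(2e3, 1e5))
    assert early.alpha == pytest.approx(2.0, abs=1e-9)
    assert late.alpha == pytest.approx(0.5, abs=1e-9)
    # continuity at the break
    i = np.searchsorted(series.times, 1e3)
    assert series.values[i] == pytest.approx(series.values[i - 1], rel=0.05)


def test_unknown_reference_kind_rejected():
    with pytest.raises(InvalidInputError):
        ReferenceProcessSpec("levy-flight")


# --------------------------------------------------------------------------
# Serialization round trips
# --------------------------------------------------------------------------


def test_series_csv_round_trip(tmp_path):
    s = ObservableSeries(np.arange(1.0, 9.0), np.linspace(0.1, 0.8, 8),
                         np.full(8, 0.01), label="sigma2_x")
    path = tmp_path / "series.csv"
    series_to_csv(s, path)
    back = series_from_csv(path, label="sigma2_x")
    np.testing.assert_array_equal(back.times, s.times)
    np.testing.assert_array_equal(back.values, s.values)


def test_record_round_trip_preserves_params(tmp_path, free_params):
    from ratchetdl import simulate_ensemble

    rec = simulate_ensemble(free_params(t_max=40.0, n_traj=6), record_velocity=True)
    save_record(rec, tmp_path / "rec.npz")
    back = load_record(tmp_path / "rec.npz")
    np.testing.assert_array_equal(back.positions, rec.positions)
    np.testing.assert_array_equal(back.velocities, rec.velocities)
    assert back.params.theta == rec.params.theta
    assert back.params.potential.scale == rec.params.potential.scale


# --------------------------------------------------------------------------
# Experiment orchestration
# --------------------------------------------------------------------------


def _tiny_cfg(tmp_path, thetas):
    return ExperimentConfig.model_validate({
        "numerics": {"steps_per_period": 200, "t_max": 1600.0, "n_traj": 48,
                     "seed": 99},
        "analysis": {"transient_periods": 20},
        "thetas": thetas,
        "output_dir": str(tmp_path / "out"),
    })


def test_run_experiment_writes_complete_bundle(tmp_path):
    cfg = _tiny_cfg(tmp_path, [0.0007])
    manifest = run_experiment(cfg)
    assert manifest["runs"][0]["status"] == "ok"
    sub = tmp_path / "out" / "theta_0.0007"
    for name in ("sigma2_x.csv", "diffusion.csv", "v_mean.csv", "sigma2_v.csv",
                 "occupations.csv", "anomaly.json", "transitions.json"):
        assert (sub / name).exists()
    assert (tmp_path / "out" / "manifest.json").exists()
    probs = json.loads((sub / "transitions.json").read_text())["probabilities"]
    assert set(probs) == {f"p_{i}{j}" for i in "-0+" for j in "-0+"}


def test_rerun_is_byte_identical(tmp_path):
    cfg = _tiny_cfg(tmp_path, [0.0007])
    run_experiment(cfg, output_dir=tmp_path / "a")
    run_experiment(cfg, output_dir=tmp_path / "b")
    for name in ("sigma2_x.csv", "v_mean.csv"):
        fa = (tmp_path / "a" / "theta_0.0007" / name).read_bytes()
        fb = (tmp_path / "b" / "theta_0.0007" / name).read_bytes()
        assert fa == fb


def test_empty_sweep_succeeds_with_zero_runs(tmp_path):
    manifest = run_experiment(_tiny_cfg(tmp_path, []))
    assert manifest["runs"] == []
    assert (tmp_path / "out" / "manifest.json").exists()


def test_config_schema_rejects_invalid(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump({"physics": {"m": -1.0}}))
    with pytest.raises(InvalidInputError):
        load_config(bad)


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------


@pytest.fixture
def cli_cfg(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text(yaml.safe_dump({
        "numerics": {"steps_per_period": 200, "t_max": 800.0, "n_traj": 24,
                     "seed": 7},
        "analysis": {"transient_periods": 10},
    }))
    return path


def test_cli_deterministic_scan_finds_attractors(tmp_path, cli_cfg):
    out = tmp_path / "attractors.json"
    result = CliRunner().invoke(cli_main, [
        "deterministic-scan", "--config", str(cli_cfg), "--n-ic", "40",
        "--transient-periods", "300", "--window-periods", "50",
        "--seed", "1", "--out", str(out),
    ])
    assert result.exit_code == 0, result.output
    att = json.loads(out.read_text())
    assert any(abs(c - 0.4) < 0.05 for c in att["centers"])


def test_cli_reference_writes_series(tmp_path):
    out = tmp_path / "msd.csv"
    result = CliRunner().invoke(cli_main, [
        "reference", "--kind", "piecewise-power-msd", "--t-max", "1000",
        "--dt", "1", "--param", 'exponents=[1.0]', "--out", str(out),
    ])
    assert result.exit_code == 0, result.output
    series = series_from_csv(out)
    assert fit_scaling_index(series, window=(10, 1000)).alpha == pytest.approx(1.0)


def test_cli_simulate_then_states(tmp_path, cli_cfg):
    rec_path = tmp_path / "rec.npz"
    r1 = CliRunner().invoke(cli_main, [
        "simulate", "--config", str(cli_cfg), "--out", str(rec_path)])
    assert r1.exit_code == 0, r1.output
    out = tmp_path / "tm.json"
    r2 = CliRunner().invoke(cli_main, [
        "states", "--record", str(rec_path), "--config", str(cli_cfg),
        "--out", str(out)])
    assert r2.exit_code == 0, r2.output
    assert "p_++" in json.loads(out.read_text())["probabilities"]
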