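"""Fixture self-checks, experiment configs, manifests and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from atrialaf import cli, fixtures
from atrialaf.experiments import (
    EXPERIMENTS,
    ExperimentConfig,
    run_experiment,
)


# ---------------------------------------------------------------------------
# Fixture validity
# ---------------------------------------------------------------------------

def test_ap_fixture_rejects_inconsistent_shapes():
    with pytest.raises(ValueError, match="APD must be shorter"):
        fixtures.make_ap_fixture(apd=1200.0, bcl=1000.0)
    with pytest.raises(ValueError, match="threshold"):
        fixtures.make_ap_fixture(rmp=-60.0, peak=20.0, threshold=-70.8)
    with pytest.raises(ValueError, match="multiple of dt"):
        fixtures.make_ap_fixture(rise=0.7, dt=0.5)


def test_ap_fixture_reproducible():
    a = fixtures.make_ap_fixture()
    b = fixtures.make_ap_fixture()
    np.testing.assert_array_equal(a.trace.data, b.trace.data)


def test_ap_fixture_surrogate_currents_constant():
    fx = fixtures.make_ap_fixture(currents={"I_Kur": 1.5})
    assert np.all(fx.trace.current("I_Kur") == 1.5)
    with pytest.raises(KeyError):
        fixtures.make_ap_fixture(currents={"I_XYZ": 1.0})


def test_phase_fixture_rejects_bad_vortices():
    with pytest.raises(ValueError, match="coincident"):
        fixtures.make_phase_fixture([(10.5, 10.5, 1), (10.5, 10.5, -1)])
    with pytest.raises(ValueError, match="outside"):
        fixtures.make_phase_fixture([(100.0, 10.0, 1)], (64, 64))


def test_phase_fixture_empty_is_vortex_free():
    pm = fixtures.make_phase_fixture([])
    assert np.all(pm == 0.0)


def test_restitution_fixture_noise_reproducible():
    a = fixtures.make_restitution_points(noise_sd=2.0, seed=4)
    b = fixtures.make_restitution_points(noise_sd=2.0, seed=4)
    np.testing.assert_array_equal(a[1], b[1])


# ---------------------------------------------------------------------------
# Experiment config
# ---------------------------------------------------------------------------

def test_config_yaml_round_trip_lossless():
    cfg = ExperimentConfig("fig5-2d", variant="PeAF2", seed=7, scale="desk",
                           settings={"grid": 100, "t_end_2d": 500.0})
    assert ExperimentConfig.from_yaml(cfg.to_yaml()) == cfg


def test_config_rejects_unknown_fields():
    with pytest.raises(ValueError, match="unknown experiment"):
        ExperimentConfig("fig9-nope")
    with pytest.raises(ValueError, match="unknown variant"):
        ExperimentConfig("fig1-sensitivity", variant="AF")
    with pytest.raises(ValueError, match="scale"):
        ExperimentConfig("fig1-sensitivity", scale="huge")
    with pytest.raises(ValueError, match="seed"):
        ExperimentConfig("fig1-sensitivity", seed=-1)


def test_config_hash_tracks_settings():
    a = ExperimentConfig("fig3-adaptation")
    b = ExperimentConfig("fig3-adaptation", settings={"pace_duration": 1.0})
    assert a.hash != b.hash


def test_resolved_settings_apply_scale_then_overrides():
    cfg = ExperimentConfig("fig1-sensitivity", scale="desk",
                           settings={"trials": 13})
    s = cfg.resolved()
    assert s["trials"] == 13
    assert s["pace_duration"] == 60_000.0


def test_every_experiment_has_a_runner():
    from atrialaf.experiments import _RUNNERS

    assert set(_RUNNERS) == set(EXPERIMENTS)


def test_run_experiment_writes_manifest_and_checksums(tmp_path):
    cfg = ExperimentConfig(
        "fig4-dq", variant="control", scale="desk",
        settings={"pace_duration": 20_000.0}, outdir=str(tmp_path),
    )
    manifest = run_experiment(cfg)
    assert manifest["status"] == "ok"
    outdir = tmp_path / "fig4-dq_control_desk"
    stored = json.loads((outdir / "manifest.json").read_text())
    assert stored["config_hash"] == cfg.hash
    assert "dq_control.csv" in stored["outputs"]
    assert set(manifest["results"]) == {"dQ_ICaL", "dQ_IKur", "dQ_INaCa"}
    # determinism: a second run reproduces the output checksums
    manifest2 = run_experiment(cfg)
    assert manifest2["outputs"] == manifest["outputs"]


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_pace_emits_csv():
    runner = CliRunner()
    res = runner.invoke(cli.main, ["pace", "--variant", "control",
                                   "--bcl", "1000", "--duration", "5000"])
    assert res.exit_code == 0, res.output
    assert "BCL_ms" in res.output and "APD_ms" in res.output


def test_cli_ps_reads_framestack(tmp_path):
    from atrialaf import tissue

    frames = fixtures.make_rotating_frames(shape=(24, 24), n_frames=8)
    path = tmp_path / "fs.h5"
    tissue.FrameStack(frames.astype(np.float32), dx=0.025,
                      frame_interval=10.0).to_hdf5(path)
    runner = CliRunner()
    res = runner.invoke(cli.main, ["ps", str(path)])
    assert res.exit_code == 0, res.output
    assert "s^-1 cm^-2" in res.output


def test_cli_run_executes_config(tmp_path):
    cfg = ExperimentConfig("fig4-dq", scale="desk",
                           settings={"pace_duration": 20_000.0},
                           outdir=str(tmp_path / "out"))
    cfg_path = tmp_path / "cfg.yaml"
    cfg_path.write_text(cfg.to_yaml())
    runner = CliRunner()
    res = runner.invoke(cli.main, ["run", str(cfg_path)])
    assert res.exit_code == 0, res.output
    assert "dQ_ICaL" in res.output
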