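"""Figure-level experiment runners with manifests.

Each runner reproduces one analysis of the study end-to-end — parameter
sensitivity, NCX mode integrals, rate adaptation, charge decomposition,
2D reentry, cable restitution — at either ``desk`` scale (reduced trial
counts, pacing times and grids that run in minutes on one core) or
``full`` scale (the headline problem sizes).  Every run writes its
outputs plus a JSON manifest recording the configuration, its hash, the
seed, package versions and a checksum of every file, so each reported
number is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import charge, pacing, phase, sensitivity, tissue
from .params import VARIANTS, ParameterSet, apply_remodeling

log = logging.getLogger("atrialaf")

EXPERIMENTS = (
    "fig1-sensitivity", "fig2-ncx", "fig3-adaptation",
    "fig4-dq", "fig5-2d", "fig6-restitution",
)

#: problem sizes per scale
SCALES = {
    "desk": dict(
        trials=200, pace_duration=60_000.0, grid=200,
        t_end_2d=1400.0, dt_levels_2d=(0.05, 0.1),
        dt_levels_cable=(0.05, 0.1),
    ),
    "full": dict(
        trials=1000, pace_duration=250_000.0, grid=600,
        t_end_2d=4760.0, dt_levels_2d=(0.01, 0.02, 0.05, 0.1),
        dt_levels_cable=(0.01, 0.02, 0.05, 0.1),
    ),
}

#: cross-field S2 coupling intervals (ms) found to induce reentry on the
#: desk 5 cm sheet; None -> automatic (first-beat APD + 55 ms)
DESK_S2 = {"PeAF2": 200.0, "PeAF1": 225.0, "ICaL50": 300.0}


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment run."""

    experiment: str
    variant: str = "control"
    seed: int = 1
    scale: str = "desk"
    settings: dict = field(default_factory=dict)
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected {EXPERIMENTS}"
            )
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {tuple(SCALES)}")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def resolved(self) -> dict:
        """Scale defaults overridden by explicit settings."""
        out = dict(SCALES[self.scale])
        out.update(self.settings)
        return out

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError("config YAML must be a mapping")
        return cls(**raw)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_yaml(Path(path).read_text())

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _variant_params(variant: str) -> ParameterSet:
    return apply_remodeling(ParameterSet(), variant)


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------

def _run_fig1(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    base = _variant_params(cfg.variant)
    sample = sensitivity.sample_scales(n_trials=s["trials"], seed=cfg.seed)
    pop = sensitivity.run_population(sample, base,
                                     pace_duration=s["pace_duration"])
    res = sensitivity.regress_population(pop)
    ranking = sensitivity.rank_sensitivities(res)

    pd.DataFrame(sample.scales, columns=sample.names).to_csv(
        outdir / "X_scales.csv", index=False, float_format="%.8g")
    pd.DataFrame({"APD_ms": pop.apds}).to_csv(
        outdir / "Y_apd.csv", index=False, float_format="%.6g")
    pd.DataFrame({"parameter": res.names, "B": res.B}).to_csv(
        outdir / "B_coefficients.csv", index=False, float_format="%.6g")
    with open(outdir / "ranking.txt", "w") as fh:
        fh.write(f"R^2 = {res.r2:.4f} ({res.preprocessing} scale), "
                 f"{pop.n_failed} failed trials\n")
        for name, b in ranking:
            fh.write(f"{name:14s} {b:+.4f}\n")
    return {"r2": res.r2, "n_failed": pop.n_failed,
            "top4": [n for n, _ in ranking[:4]]}


def _run_fig2(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    rows = []
    for label, variant in (("control", "control"), ("PeAF", "PeAF1")):
        for boost, tag in ((1.0, "base"), (2.0, "NCX+100%")):
            p = _variant_params(variant).scaled({"I_NaCa_max": boost})
            res = pacing.pace_to_steady_state(p, 1000.0,
                                              duration=s["pace_duration"])
            split = charge.split_ncx_modes(res.trace)
            rows.append(dict(condition=label, ncx=tag,
                             reverse=split.reverse, forward=split.forward,
                             apd=res.apd))
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "ncx_modes.csv", index=False, float_format="%.6g")
    return {"rows": len(df)}


def _run_fig3(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    variants = s.get("variants", list(VARIANTS))
    slopes = {}
    frames = []
    for var in variants:
        curve = pacing.adaptation_curve(
            _variant_params(var), duration_per_rate=s["pace_duration"])
        slopes[var] = curve.slope
        frames.append(pd.DataFrame(
            {"variant": var, "BCL_ms": curve.bcls, "APD_ms": curve.apds}))
    pd.concat(frames).to_csv(outdir / "adaptation.csv", index=False,
                             float_format="%.6g")
    pd.Series(slopes, name="slope").to_csv(outdir / "slopes.csv")
    return {"slopes": slopes}


def _run_fig4(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    p = _variant_params(cfg.variant)
    slow = pacing.pace_to_steady_state(p, 2000.0, duration=s["pace_duration"])
    fast = pacing.pace_to_steady_state(p, 500.0, duration=s["pace_duration"])
    table = charge.delta_q(slow.trace, fast.trace)
    table.to_csv(outdir / f"dq_{cfg.variant}.csv")
    return {"dQ_ICaL": table.dq("I_CaL"), "dQ_IKur": table.dq("I_Kur"),
            "dQ_INaCa": table.dq("I_NaCa")}


def _run_fig5(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    p = _variant_params(cfg.variant)
    grid = int(s["grid"])
    config = tissue.TissueConfig(nx=grid, ny=grid,
                                 dt_levels=tuple(s["dt_levels_2d"]))
    s2 = s.get("s2_time")
    if s2 is None:
        s2 = DESK_S2.get(cfg.variant) if cfg.scale == "desk" else 300.0
    if s2 is None:
        run = tissue.simulate_cable(p, [0.0], 500.0)
        apds = run.apds()
        s2 = 5.0 * round((float(apds[0]) + 55.0) / 5.0)
    proto = tissue.CrossFieldProtocol(s2_time=float(s2))
    fs = tissue.simulate_2d(p, config, proto, t_end=s["t_end_2d"])
    fs.to_hdf5(outdir / f"frames_{cfg.variant}.h5")
    ph = phase.compute_phase(fs.frames, fs.frame_interval)
    counts = phase.count_ps_per_frame(ph)
    tt = fs.times[:len(counts)]
    w = tt >= float(s2) + 100.0
    dens = phase.ps_density(int(counts[w].sum()), int(w.sum()),
                            fs.frame_interval, fs.area_cm2)
    pd.DataFrame({"t_ms": tt, "n_ps": counts}).to_csv(
        outdir / f"ps_counts_{cfg.variant}.csv", index=False)
    return {"s2_time": float(s2), "ps_density": dens,
            "frames_with_ps": float((counts[w] > 0).mean())}


def _run_fig6(cfg: ExperimentConfig, s: dict, outdir: Path) -> dict:
    variants = s.get("variants", ["ICaL50", "ICaL70"])
    config = tissue.TissueConfig(nx=128, ny=1,
                                 dt_levels=tuple(s["dt_levels_cable"]))
    out = {}
    frames = []
    for var in variants:
        curve = tissue.restitution_protocol(_variant_params(var), config)
        smax, di_at = tissue.max_restitution_slope(curve)
        out[var] = {"smax": smax, "di_at_smax": di_at,
                    "terminated_by": curve.terminated_by}
        frames.append(pd.DataFrame(
            {"variant": var, "DI_ms": curve.di, "APD_ms": curve.apd,
             "BCL_ms": curve.bcls}))
    pd.concat(frames).to_csv(outdir / "restitution.csv", index=False,
                             float_format="%.6g")
    with open(outdir / "smax.json", "w") as fh:
        json.dump(out, fh, indent=1)
    return out


_RUNNERS = {
    "fig1-sensitivity": _run_fig1,
    "fig2-ncx": _run_fig2,
    "fig3-adaptation": _run_fig3,
    "fig4-dq": _run_fig4,
    "fig5-2d": _run_fig5,
    "fig6-restitution": _run_fig6,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment and write outputs plus a manifest.

    Returns the manifest dictionary.  A stage failure is recorded in the
    manifest (with the stage name) and re-raised.
    """
    outdir = Path(config.outdir) / f"{config.experiment}_{config.variant}_{config.scale}"
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.hash,
        "versions": _versions(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    t0 = time.time()
    try:
        log.info("running %s (%s, %s scale)", config.experiment,
                 config.variant, config.scale)
        manifest["results"] = _RUNNERS[config.experiment](
            config, config.resolved(), outdir)
        manifest["status"] = "ok"
    except Exception as exc:  # recorded, then re-raised
        manifest["status"] = "failed"
        manifest["failure"] = {"stage": config.experiment, "error": repr(exc)}
        _write_manifest(outdir, manifest, t0)
        raise
    _write_manifest(outdir, manifest, t0)
    return manifest


def _write_manifest(outdir: Path, manifest: dict, t0: float) -> None:
    manifest["wall_seconds"] = round(time.time() - t0, 2)
    manifest["outputs"] = {
        f.name: _sha256(f)
        for f in sorted(outdir.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def _versions() -> dict:
    import numba

    from . import __version__

    return {"atrialaf": __version__, "numpy": np.__version__,
            "numba": numba.__version__, "pandas": pd.__version__}
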