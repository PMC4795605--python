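"""Monodomain tissue: 1D cable and 2D sheet simulations.

The monodomain reaction–diffusion equation

    dV/dt = -(I_ion + I_stim)/C_m + D * laplacian(V)

is solved by operator splitting: a reaction step (Rush–Larsen gates,
forward-Euler V and concentrations, via :mod:`atrialaf.engine`) followed
by an explicit diffusion step at the same adaptive dt.  Default grid
constants follow the tissue model this package reproduces:
D = 0.001 cm^2/ms, dx = 0.025 cm, C_m = 1 uF/cm^2, zero-flux boundaries,
adaptive step within [0.01, 0.1] ms.  The full-size sheet is
15 cm x 15 cm (600 x 600 nodes); reduced grids for routine testing are a
construction parameter, not a change of the numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import engine, model_core
from .cell import integrate_cell
from .pacing import APD_THRESHOLD, _interp_crossings
from .params import ParameterSet

ALTERNANS_TOL = 2.0   # ms, beat-to-beat APD difference flagged as alternans

#: Fixed BCL schedule head of the dynamic restitution protocol (ms);
#: continues downward in 5 ms steps from its last entry.
RESTITUTION_BCLS_HEAD = (600.0, 500.0, 400.0, 350.0, 320.0, 310.0, 300.0)


@dataclass(frozen=True)
class TissueConfig:
    """Grid and numerics for cable/sheet runs."""

    nx: int = 600
    ny: int = 600                     # ny = 1 -> cable
    dx: float = 0.025                 # cm
    D: float = 0.001                  # cm^2/ms
    dt_levels: tuple = (0.01, 0.02, 0.05, 0.1)   # ms, adaptive bounds
    stim_duration: float = 2.0        # ms
    n_stim_nodes: int = 5             # cable stimulus width (nodes)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 1:
            raise ValueError("grid too small")
        if self.dx <= 0 or self.D < 0:
            raise ValueError("dx must be positive and D non-negative")
        ndim = 1 if self.ny == 1 else 2
        cfl = self.dx**2 / (2.0 * ndim * self.D) if self.D > 0 else np.inf
        if max(self.dt_levels) > cfl + 1e-12:
            raise ValueError(
                f"explicit diffusion unstable: max dt {max(self.dt_levels)} ms "
                f"exceeds the CFL bound {cfl:.4f} ms"
            )

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def area_cm2(self) -> float:
        return (self.nx * self.dx) * (self.ny * self.dx)

    def cable(self, n: int = 128) -> "TissueConfig":
        return replace(self, nx=n, ny=1)


DEFAULT_CABLE = TissueConfig(nx=128, ny=1)


# ---------------------------------------------------------------------------
# Initial states
# ---------------------------------------------------------------------------

_equilibrated_cache: dict[bytes, np.ndarray] = {}


def equilibrated_state(params: ParameterSet, t_rest: float = 10_000.0) -> np.ndarray:
    """Single-cell state after ``t_rest`` ms of quiescence (per parameter set)."""
    key = params.to_vector().tobytes()
    if key not in _equilibrated_cache:
        tr = integrate_cell(model_core.initial_state(), params, None,
                            t_end=t_rest, dt_out=t_rest)
        _equilibrated_cache[key] = tr.final_state
    return _equilibrated_cache[key].copy()


def _tiled(state: np.ndarray, n: int) -> np.ndarray:
    return np.repeat(state[:, None], n, axis=1)


def _ticks(t_ms: float, what: str) -> np.int64:
    ticks = int(round(t_ms / engine.TICK_MS))
    if abs(ticks * engine.TICK_MS - t_ms) > 1e-9:
        raise ValueError(f"{what} = {t_ms} ms is not a multiple of {engine.TICK_MS} ms")
    return np.int64(ticks)


def _aligned_ticks(t_ms: float, base_ticks: np.int64, what: str) -> np.int64:
    """Ticks for an event instant/interval; must sit on the base-dt grid
    so the adaptive stepper can land on it exactly."""
    ticks = _ticks(t_ms, what)
    if ticks % base_ticks != 0:
        raise ValueError(
            f"{what} = {t_ms} ms is not a multiple of the smallest dt level"
        )
    return ticks


# ---------------------------------------------------------------------------
# Cable
# ---------------------------------------------------------------------------

@dataclass
class CableRun:
    """Result of a cable simulation."""

    t_probe: np.ndarray        # ms
    v_probe: np.ndarray        # mV at the probe node
    probe_idx: int
    t_full: np.ndarray | None  # ms, frames of all-node V (optional)
    v_full: np.ndarray | None  # (n_frames, n_nodes)
    config: TissueConfig
    final_state: np.ndarray    # (21, n_nodes)
    nernst_cache: np.ndarray

    def apds(self, threshold: float = APD_THRESHOLD) -> np.ndarray:
        """APDs of every complete AP at the probe node."""
        ups, downs = _interp_crossings(self.t_probe, self.v_probe, threshold)
        out = []
        for tu in ups:
            later = downs[downs > tu]
            if later.size == 0:
                break
            out.append(later[0] - tu)
        return np.asarray(out)


def simulate_cable(
    params: ParameterSet,
    stim_onsets,
    t_end: float,
    config: TissueConfig = DEFAULT_CABLE,
    amplitude: float | None = None,
    state0: np.ndarray | None = None,
    nernst_cache: np.ndarray | None = None,
    probe_idx: int = 63,
    dt_probe: float = 0.5,
    full_dt: float | None = None,
    tables: engine.Tables | None = None,
) -> CableRun:
    """Run a 1D cable paced at one end.

    ``stim_onsets`` are stimulus times (ms); the pulse is applied to the
    first ``config.n_stim_nodes`` nodes.  ``state0`` (21, n) continues a
    previous run; default is the quiescent-equilibrated state tiled over
    the cable.  ``full_dt`` additionally records all-node V at that
    interval (for conduction-velocity measurement).
    """
    if config.ny != 1:
        raise ValueError("cable config requires ny = 1")
    n = config.nx
    if amplitude is None:
        amplitude = twice_cable_threshold(params, config)
    if state0 is None:
        state0 = _tiled(equilibrated_state(params), n)
    S = np.ascontiguousarray(state0, dtype=float).copy()
    if S.shape != (model_core.N_STATE, n):
        raise ValueError(f"state0 must have shape (21, {n})")
    EC = engine.fresh_nernst_cache(n) if nernst_cache is None else nernst_cache.copy()
    if tables is None:
        tables = engine.build_tables(params, dt_levels=config.dt_levels)

    base = tables.dt_ticks[0]
    onsets = np.asarray(sorted(float(x) for x in np.atleast_1d(stim_onsets)))
    onset_ticks = np.array(
        [_aligned_ticks(x, base, "stimulus onset") for x in onsets],
        dtype=np.int64)
    end_ticks = _aligned_ticks(t_end, base, "t_end")
    probe_every = _aligned_ticks(dt_probe, base, "dt_probe")
    n_probe_max = int(end_ticks // probe_every) + 2
    probe_out = np.empty(n_probe_max)
    if full_dt is not None:
        full_every = _aligned_ticks(full_dt, base, "full_dt")
        full_out = np.empty((int(end_ticks // full_every) + 2, n))
    else:
        full_every = np.int64(0)
        full_out = np.empty((1, n))

    status, fail_t, n_probe, n_full = engine._run_cable(
        S, EC, tables.tab, tables.dt_levels, tables.dt_ticks,
        tables.rl_fca, tables.rl_u, tables.rl_v0, tables.rl_v1, tables.pvec,
        config.D / config.dx**2,
        onset_ticks, _aligned_ticks(config.stim_duration, base, "stim duration"),
        -abs(amplitude), config.n_stim_nodes,
        end_ticks, probe_idx, probe_every, probe_out,
        full_every, full_out,
    )
    if status != 0:
        raise RuntimeError(f"cable integration failed at t = {fail_t:.2f} ms")
    return CableRun(
        t_probe=dt_probe * np.arange(n_probe), v_probe=probe_out[:n_probe].copy(),
        probe_idx=probe_idx,
        t_full=(full_dt * np.arange(n_full)) if full_dt is not None else None,
        v_full=full_out[:n_full].copy() if full_dt is not None else None,
        config=config, final_state=S, nernst_cache=EC,
    )


_cable_threshold_cache: dict[tuple, float] = {}


def cable_threshold(params: ParameterSet, config: TissueConfig = DEFAULT_CABLE,
                    amp_max: float = 200.0, rel_tol: float = 0.01) -> float:
    """Minimal end-stimulus amplitude that propagates an AP to the probe
    node (bisection to 1% relative precision)."""
    key = (params.to_vector().tobytes(), config.nx, config.dx, config.D)
    if key in _cable_threshold_cache:
        return _cable_threshold_cache[key]

    tables = engine.build_tables(params, dt_levels=config.dt_levels)
    state0 = _tiled(equilibrated_state(params), config.nx)
    t_run = 300.0 + config.nx * config.dx / 0.02  # generous transit margin

    def captures(amp: float) -> bool:
        run = simulate_cable(params, [0.0], t_run, config, amplitude=amp,
                             state0=state0, tables=tables,
                             probe_idx=3 * config.nx // 4)
        return run.v_probe.max() > 0.0

    lo, hi = 0.0, amp_max
    if not captures(hi):
        raise RuntimeError(f"no cable capture at amplitude {amp_max} pA/pF")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    _cable_threshold_cache[key] = hi
    return hi


def twice_cable_threshold(params: ParameterSet,
                          config: TissueConfig = DEFAULT_CABLE) -> float:
    return 2.0 * cable_threshold(params, config)


def measure_cv(run: CableRun, threshold: float = APD_THRESHOLD) -> float:
    """Planar conduction velocity (cm/s) between the nodes at 25% and 75%
    of the cable, from interpolated activation (upward-crossing) times."""
    if run.v_full is None:
        raise ValueError("run must record full-cable V (full_dt=...)")
    n = run.config.nx
    i1, i2 = n // 4, 3 * n // 4

    def activation(idx: int) -> float:
        ups, _ = _interp_crossings(run.t_full, run.v_full[:, idx], threshold)
        if ups.size == 0:
            raise RuntimeError(f"no activation at node {idx} (no propagation?)")
        return float(ups[0])

    t1, t2 = activation(i1), activation(i2)
    if t2 <= t1:
        raise RuntimeError("non-monotone activation order along the cable")
    dist_cm = (i2 - i1) * run.config.dx
    return dist_cm / (t2 - t1) * 1000.0


# ---------------------------------------------------------------------------
# Dynamic restitution in the cable
# ---------------------------------------------------------------------------

@dataclass
class RestitutionCurve:
    """Steady-state APD90 vs diastolic interval at the cable midpoint."""

    di: np.ndarray             # ms, sorted ascending
    apd: np.ndarray            # ms
    bcls: np.ndarray           # ms, aligned with (di, apd)
    terminated_by: str         # "alternans", "block" or "schedule"
    terminal_bcl: float | None

    def n_points(self) -> int:
        return len(self.di)


def restitution_protocol(
    params: ParameterSet,
    config: TissueConfig = DEFAULT_CABLE,
    n_stim: int = 40,
    amplitude: float | None = None,
    bcl_min: float = 120.0,
    alternans_tol: float = ALTERNANS_TOL,
) -> RestitutionCurve:
    """Dynamic APD-restitution protocol in the cable.

    BCL decreases through 600, 500, 400, 350, 320, 310, 300 ms and then
    in 5 ms steps; at each BCL, ``n_stim`` stimuli are applied at one end
    (continuing the tissue state) and APD90 and DI are measured at node
    64.  The schedule stops at APD alternans (beat-to-beat change above
    ``alternans_tol``) or 2:1 block.
    """
    if config.ny != 1:
        raise ValueError("restitution runs on a cable config")
    if amplitude is None:
        amplitude = twice_cable_threshold(params, config)
    tables = engine.build_tables(params, dt_levels=config.dt_levels)
    state = _tiled(equilibrated_state(params), config.nx)
    ec = engine.fresh_nernst_cache(config.nx)

    bcls: list[float] = list(RESTITUTION_BCLS_HEAD)
    b = bcls[-1]
    while b - 5.0 >= bcl_min:
        b -= 5.0
        bcls.append(b)

    out_di, out_apd, out_bcl = [], [], []
    terminated_by, terminal_bcl = "schedule", None
    for bcl in bcls:
        onsets = bcl * np.arange(n_stim)
        run = simulate_cable(
            params, onsets, t_end=n_stim * bcl, config=config,
            amplitude=amplitude, state0=state, nernst_cache=ec, tables=tables,
        )
        state, ec = run.final_state, run.nernst_cache
        apds = run.apds()
        # 2:1 block: the last 10 stimuli should elicit 10 APs
        ups, _ = _interp_crossings(run.t_probe, run.v_probe, APD_THRESHOLD)
        n_last = np.sum(ups >= (n_stim - 10) * bcl)
        if len(apds) < 2 or n_last <= 8:
            terminated_by, terminal_bcl = "block", bcl
            break
        delta = abs(apds[-1] - apds[-2])
        if delta > alternans_tol:
            terminated_by, terminal_bcl = "alternans", bcl
            break
        apd_ss = float(apds[-1])
        di = bcl - float(apds[-2])
        if di <= 0:
            terminated_by, terminal_bcl = "block", bcl
            break
        out_bcl.append(bcl)
        out_apd.append(apd_ss)
        out_di.append(di)
    if terminated_by == "schedule":
        warnings.warn("restitution schedule exhausted without alternans or block")
    if not out_di:
        raise RuntimeError("2:1 block at the first BCL; protocol cannot start")
    order = np.argsort(out_di)
    return RestitutionCurve(
        di=np.asarray(out_di)[order], apd=np.asarray(out_apd)[order],
        bcls=np.asarray(out_bcl)[order],
        terminated_by=terminated_by, terminal_bcl=terminal_bcl,
    )


def max_restitution_slope(curve: RestitutionCurve | tuple) -> tuple[float, float]:
    """Maximal slope of the restitution curve and the DI at which it occurs.

    Fits least-squares lines to every three consecutive points in DI and
    returns the largest slope (Smax, DI_centre).
    """
    if isinstance(curve, RestitutionCurve):
        di, apd = curve.di, curve.apd
    else:
        di, apd = (np.asarray(x, dtype=float) for x in curve)
    if len(di) < 3:
        raise ValueError("at least three restitution points are required")
    best, best_di = -np.inf, np.nan
    for k in range(len(di) - 2):
        x, y = di[k:k + 3], apd[k:k + 3]
        slope = np.polyfit(x, y, 1)[0]
        if slope > best:
            best, best_di = float(slope), float(np.mean(x))
    return best, best_di


# ---------------------------------------------------------------------------
# 2D sheet with cross-field induction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossFieldProtocol:
    """S1 planar stimulus along one edge, S2 orthogonal half-field."""

    s1_time: float = 0.0
    s2_time: float = 300.0        # coupling interval (ms after S1)
    amplitude: float | None = None  # pA/pF; None -> twice cable threshold
    s1_cols: int = 5              # width of the S1 edge strip (nodes)
    s2_fraction: float = 0.5      # fraction of rows covered by S2

    def __post_init__(self) -> None:
        if self.s2_time <= self.s1_time:
            raise ValueError("S2 must follow S1")
        if not 0.0 < self.s2_fraction < 1.0:
            raise ValueError("s2_fraction must be in (0, 1)")


@dataclass
class FrameStack:
    """2D membrane-potential snapshots at a fixed frame interval."""

    frames: np.ndarray            # (n_frames, ny, nx), float32, mV
    dx: float                     # cm
    frame_interval: float         # ms
    t0: float = 0.0               # ms, time of the first frame

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.frame_interval * np.arange(self.frames.shape[0])

    @property
    def area_cm2(self) -> float:
        ny, nx = self.frames.shape[1:]
        return nx * self.dx * ny * self.dx

    def window(self, t_lo: float, t_hi: float) -> "FrameStack":
        tt = self.times
        mask = (tt >= t_lo - 1e-9) & (tt <= t_hi + 1e-9)
        if not mask.any():
            raise ValueError("window outside the recorded frames")
        lo = int(np.argmax(mask))
        return FrameStack(self.frames[mask], self.dx, self.frame_interval,
                          t0=float(tt[lo]))

    def to_hdf5(self, path, name: str = "frames") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            ds = fh.create_dataset(name, data=self.frames,
                                   compression="gzip", compression_opts=4)
            ds.attrs["dx_cm"] = self.dx
            ds.attrs["frame_interval_ms"] = self.frame_interval
            ds.attrs["t0_ms"] = self.t0

    @classmethod
    def from_hdf5(cls, path, name: str = "frames") -> "FrameStack":
        import h5py

        with h5py.File(path, "r") as fh:
            ds = fh[name]
            return cls(ds[...], float(ds.attrs["dx_cm"]),
                       float(ds.attrs["frame_interval_ms"]),
                       float(ds.attrs["t0_ms"]))


def simulate_2d(
    params: ParameterSet,
    config: TissueConfig,
    protocol: CrossFieldProtocol,
    t_end: float,
    frame_interval: float = 10.0,
    state0: np.ndarray | None = None,
) -> FrameStack:
    """Cross-field S1-S2 run on the 2D sheet, returning V frames.

    Deterministic for fixed configuration.  Aborts with an error if the
    solution blows up (|V| > 200 mV).
    """
    if config.ny < 3:
        raise ValueError("2D simulation requires ny >= 3")
    n = config.n_nodes
    amplitude = protocol.amplitude
    if amplitude is None:
        amplitude = twice_cable_threshold(params, config.cable(128))
    if state0 is None:
        state0 = _tiled(equilibrated_state(params), n)
    S = np.ascontiguousarray(state0, dtype=float).copy()
    if S.shape != (model_core.N_STATE, n):
        raise ValueError(f"state0 must have shape (21, {n})")
    EC = engine.fresh_nernst_cache(n)
    tables = engine.build_tables(params, dt_levels=config.dt_levels)

    base = tables.dt_ticks[0]
    end_ticks = _aligned_ticks(t_end, base, "t_end")
    frame_every = _aligned_ticks(frame_interval, base, "frame_interval")
    n_frames_max = int(end_ticks // frame_every) + 2
    frames = np.empty((n_frames_max, n), dtype=np.float32)
    s2_rows = int(round(config.ny * protocol.s2_fraction))

    status, fail_t, n_frames = engine._run_sheet(
        S, EC, tables.tab, tables.dt_levels, tables.dt_ticks,
        tables.rl_fca, tables.rl_u, tables.rl_v0, tables.rl_v1, tables.pvec,
        config.nx, config.ny, config.D / config.dx**2,
        _aligned_ticks(protocol.s1_time, base, "s1_time"),
        _aligned_ticks(protocol.s2_time, base, "s2_time"),
        _aligned_ticks(config.stim_duration, base, "stim duration"),
        -abs(amplitude),
        protocol.s1_cols, s2_rows,
        end_ticks, frame_every, frames,
    )
    if status != 0:
        frame_idx = int(fail_t // frame_interval)
        raise RuntimeError(
            f"2D simulation blew up at t = {fail_t:.2f} ms (frame {frame_idx})"
        )
    return FrameStack(
        frames=frames[:n_frames].reshape(n_frames, config.ny, config.nx).copy(),
        dx=config.dx, frame_interval=frame_interval,
    )
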