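"""Pacing protocols, APD / resting-potential measurement, rate adaptation.

APD is measured at the fixed threshold V = -70.8 mV — the voltage of 90%
repolarization of the control action potential at 1 Hz — with linear
interpolation between samples.  Steady-state pacing runs 250 s per rate;
the rate-adaptation curve applies the rates as a descending-BCL staircase
(each rate continues from the previous rate's final state), the standard
dynamic protocol for steady-state adaptation, so the slow intracellular
Na+ loading carries across rates as it does in a paced cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import model_core
from .cell import DEFAULT_DT, StimulusProtocol, integrate_cell
from .params import ParameterSet
from .trace import APTrace

APD_THRESHOLD = -70.8     # mV, fixed across all conditions
STEADY_APD_TOL = 1.0      # ms, beat-to-beat APD change regarded as steady
RMP_WINDOW = 50.0         # ms of diastole before stimulus onset
BCL_MIN, BCL_MAX = 330.0, 2000.0

#: Default BCL staircase for adaptation curves, 0.5 Hz -> 3 Hz.
ADAPTATION_BCLS = (2000.0, 1500.0, 1000.0, 750.0, 667.0, 600.0,
                   500.0, 450.0, 400.0, 350.0, 330.0)


class NoActionPotential(Exception):
    """Raised when a measurement requires an AP the trace does not contain."""


@dataclass(frozen=True)
class APDMeasurement:
    apd: float                # ms
    threshold: float          # mV
    beat_index: int
    t_up: float               # ms, upward threshold crossing
    t_down: float             # ms, downward threshold crossing

    def __post_init__(self) -> None:
        if self.apd <= 0:
            raise ValueError("APD must be positive")


def _interp_crossings(t: np.ndarray, V: np.ndarray, threshold: float):
    """Linearly interpolated upward and downward crossing times."""
    below = V < threshold
    up_idx = np.flatnonzero(below[:-1] & ~below[1:])
    dn_idx = np.flatnonzero(~below[:-1] & below[1:])

    def interp(idx):
        frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return interp(up_idx), interp(dn_idx)


def measure_all_apds(trace: APTrace, threshold: float = APD_THRESHOLD) -> list[APDMeasurement]:
    """APD of every complete AP in the trace (upward-to-downward crossing)."""
    ups, downs = _interp_crossings(trace.t, trace.V, threshold)
    out: list[APDMeasurement] = []
    for k, tu in enumerate(ups):
        later = downs[downs > tu]
        if later.size == 0:
            break
        td = later[0]
        out.append(APDMeasurement(apd=float(td - tu), threshold=threshold,
                                  beat_index=k, t_up=float(tu), t_down=float(td)))
    return out


def measure_apd(trace: APTrace, threshold: float = APD_THRESHOLD,
                beat: int = -1) -> APDMeasurement:
    """APD of one AP (default: the last complete one).

    Raises :class:`NoActionPotential` if the trace never crosses the
    threshold — deliberately not returned as a zero duration.
    """
    apds = measure_all_apds(trace, threshold)
    if not apds:
        raise NoActionPotential(
            f"trace has no complete AP at threshold {threshold} mV"
        )
    return apds[beat]


def measure_rmp(trace: APTrace, bcl: float | None = None) -> float:
    """Resting membrane potential: the most negative V over the final
    diastolic window (RMP_WINDOW ms) before the last stimulus onset.

    A trace without any stimulus marks falls back to the global minimum
    (appropriate for quiescent or synthetic traces).  If ``bcl`` is given
    the trace must span at least one cycle.
    """
    if bcl is not None and trace.t[-1] - trace.t[0] < bcl:
        raise ValueError("trace is shorter than one BCL")
    stim = trace.I_stim
    active = np.flatnonzero(stim != 0.0)
    if active.size == 0:
        return float(trace.V.min())
    onsets = active[np.flatnonzero(np.diff(active, prepend=-10) > 1)]
    t_on = trace.t[onsets[-1]]
    win = trace.window(max(trace.t[0], t_on - RMP_WINDOW), t_on)
    return float(win.V.min())


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def _captures(params, bcl, amplitude, n_beats, state0, dt, tables) -> bool:
    """True if every one of ``n_beats`` stimuli elicits an AP (peak V > 0)."""
    proto = StimulusProtocol(BCL=bcl, amplitude=amplitude, n_beats=n_beats)
    tr = integrate_cell(state0, params, proto, t_end=n_beats * bcl + proto.offset,
                        dt_out=0.5, dt=dt, tables=tables)
    for k in range(n_beats):
        t0 = proto.offset + k * bcl
        beat = tr.window(t0, t0 + bcl)
        if beat.V.max() <= 0.0:
            return False
    return True


def find_threshold(params: ParameterSet, bcl: float, n_beats: int = 10,
                   amp_max: float = 80.0, rel_tol: float = 0.01,
                   state0: np.ndarray | None = None,
                   dt: float = DEFAULT_DT) -> float:
    """Minimal stimulus amplitude (pA/pF, magnitude) capturing every beat
    of a short pacing run, by bisection to 1% relative precision."""
    if not (BCL_MIN <= bcl <= BCL_MAX):
        raise ValueError(f"BCL {bcl} ms outside the single-cell range "
                         f"[{BCL_MIN}, {BCL_MAX}] ms")
    if state0 is None:
        state0 = model_core.initial_state()
    from . import engine
    tables = engine.build_tables(params, dt_levels=(dt,))
    lo, hi = 0.0, float(amp_max)
    if not _captures(params, bcl, hi, n_beats, state0, dt, tables):
        raise RuntimeError(f"no capture at the maximal test amplitude {amp_max} pA/pF")
    # grow lo to a non-capturing bound quickly
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _captures(params, bcl, mid, n_beats, state0, dt, tables):
            hi = mid
        else:
            lo = mid
    return hi


_threshold_cache: dict[tuple, float] = {}


def twice_threshold(params: ParameterSet, bcl: float, **kw) -> float:
    """Stimulus amplitude used throughout: twice the per-BCL capture threshold."""
    key = (params.to_vector().tobytes(), round(bcl, 3))
    if key not in _threshold_cache:
        _threshold_cache[key] = find_threshold(params, bcl, **kw)
    return 2.0 * _threshold_cache[key]


# ---------------------------------------------------------------------------
# Steady-state pacing
# ---------------------------------------------------------------------------

@dataclass
class SteadyPacingResult:
    """Final beats of a steady-pacing run plus steadiness diagnostics."""

    trace: APTrace
    bcl: float
    amplitude: float
    apds: list[APDMeasurement]
    rmp: float
    steady: bool              # final beat-to-beat APD change < 1 ms
    delta_apd: float          # |APD_n - APD_(n-1)| of the final pair, ms
    captured: bool            # 1:1 capture over the recorded beats

    @property
    def apd(self) -> float:
        return self.apds[-1].apd


def pace_to_steady_state(
    params: ParameterSet,
    bcl: float,
    duration: float = 250_000.0,
    amplitude: float | None = None,
    state0: np.ndarray | None = None,
    record_beats: int = 4,
    dt: float = DEFAULT_DT,
    dt_out: float = 0.5,
) -> SteadyPacingResult:
    """Pace for ``duration`` ms (default 250 s) and return the final beats.

    ``amplitude=None`` auto-calibrates to twice the per-BCL threshold.
    Alternans (beat-to-beat APD change above tolerance) or loss of capture
    is flagged in the result, and additionally raised as a warning.
    """
    if amplitude is None:
        amplitude = twice_threshold(params, bcl)
    if state0 is None:
        state0 = model_core.initial_state()
    proto = StimulusProtocol(BCL=bcl, amplitude=amplitude)
    n_cycles = int((duration - proto.offset) // bcl)
    record_start = proto.offset + (n_cycles - record_beats) * bcl - 50.0
    record_start = max(0.0, round(record_start, 1))
    tr = integrate_cell(state0, params, proto, t_end=duration,
                        dt_out=dt_out, record_start=record_start, dt=dt)
    apds = measure_all_apds(tr)
    captured = len(apds) >= record_beats
    if len(apds) >= 2:
        delta = abs(apds[-1].apd - apds[-2].apd)
    else:
        delta = np.inf
    steady = delta < STEADY_APD_TOL
    if not captured:
        warnings.warn(f"loss of 1:1 capture at BCL {bcl} ms "
                      f"({len(apds)} APs in {record_beats} cycles)")
    elif not steady:
        warnings.warn(f"beat-to-beat APD change {delta:.2f} ms at BCL {bcl} ms "
                      "exceeds the 1 ms steadiness tolerance (alternans?)")
    return SteadyPacingResult(
        trace=tr, bcl=bcl, amplitude=amplitude, apds=apds,
        rmp=measure_rmp(tr), steady=steady, delta_apd=float(delta),
        captured=captured,
    )


# ---------------------------------------------------------------------------
# Rate adaptation
# ---------------------------------------------------------------------------

@dataclass
class AdaptationCurve:
    """Steady-state APD as a function of BCL, with the 0.5-2 Hz slope."""

    bcls: np.ndarray            # ms, sorted ascending
    apds: np.ndarray            # ms
    slope: float                # dimensionless, between BCL 2000 and 500 ms
    slope_bcls: tuple[float, float] = (2000.0, 500.0)
    excluded: list[float] = field(default_factory=list)

    def as_pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.bcls.tolist(), self.apds.tolist()))


def slope_between(bcls, apds, b_slow: float = 2000.0, b_fast: float = 500.0) -> float:
    """Chord slope dAPD/dBCL between two named cycle lengths."""
    bcls = np.asarray(bcls, dtype=float)
    apds = np.asarray(apds, dtype=float)
    try:
        i_slow = np.flatnonzero(np.isclose(bcls, b_slow))[0]
        i_fast = np.flatnonzero(np.isclose(bcls, b_fast))[0]
    except IndexError:
        raise ValueError(f"curve lacks the BCL {b_slow} or {b_fast} ms point")
    return float((apds[i_slow] - apds[i_fast]) / (b_slow - b_fast))


def adaptation_curve(
    params: ParameterSet,
    bcls=ADAPTATION_BCLS,
    duration_per_rate: float = 250_000.0,
    amplitude: float | None = None,
    staircase: bool = True,
    dt: float = DEFAULT_DT,
) -> AdaptationCurve:
    """Steady-state APD-vs-BCL curve.

    Rates are applied in the given (descending-BCL) order; with
    ``staircase=True`` each rate continues from the previous rate's final
    state.  Rates that lose 1:1 capture are excluded with a warning.
    """
    bcls = [float(b) for b in bcls]
    state = model_core.initial_state()
    kept_b, kept_a, excluded = [], [], []
    for bcl in bcls:
        res = pace_to_steady_state(
            params, bcl, duration=duration_per_rate, amplitude=amplitude,
            state0=state, dt=dt,
        )
        if staircase:
            state = res.trace.final_state
        if not res.captured:
            warnings.warn(f"excluding BCL {bcl} ms: loss of 1:1 capture")
            excluded.append(bcl)
            continue
        kept_b.append(bcl)
        kept_a.append(res.apd)
    order = np.argsort(kept_b)
    bcl_arr = np.asarray(kept_b)[order]
    apd_arr = np.asarray(kept_a)[order]
    return AdaptationCurve(
        bcls=bcl_arr, apds=apd_arr,
        slope=slope_between(bcl_arr, apd_arr), excluded=excluded,
    )
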