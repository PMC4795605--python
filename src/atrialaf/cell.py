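"""Single-cell integration: periodic pacing of the CRN model.

The production scheme (Rush–Larsen gates, forward-Euler V and
concentrations, fixed 0.02 ms step) is driven through the table kernel in
:mod:`atrialaf.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine, model_core
from .params import ParameterSet
from .trace import APTrace

DEFAULT_DT = 0.02  # ms, validated against the 1 us Euler oracle


@dataclass(frozen=True)
class StimulusProtocol:
    """Periodic rectangular-pulse pacing.

    ``amplitude`` is a current density in pA/pF applied with the membrane
    sign convention: the stored value is positive by convention and is
    applied as an inward (negative) stimulus current.
    """

    BCL: float = 1000.0        # ms; 0 disables pacing
    amplitude: float = 4.0     # pA/pF, depolarizing magnitude
    duration: float = 2.0      # ms
    n_beats: int = 10**9       # effectively unlimited
    offset: float = 20.0       # ms from trace start to first pulse

    def __post_init__(self) -> None:
        if self.BCL < 0 or self.duration <= 0 or self.offset < 0:
            raise ValueError("BCL/duration/offset out of range")
        if self.BCL and self.duration >= self.BCL:
            raise ValueError("pulse duration must be shorter than the BCL")

    def replace(self, **kw) -> "StimulusProtocol":
        import dataclasses

        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "BCL": self.BCL, "amplitude": self.amplitude,
            "duration": self.duration, "n_beats": self.n_beats,
            "offset": self.offset,
        }


def _ticks(t_ms: float, what: str) -> np.int64:
    ticks = int(round(t_ms / engine.TICK_MS))
    if abs(ticks * engine.TICK_MS - t_ms) > 1e-9:
        raise ValueError(f"{what} = {t_ms} ms is not a multiple of 0.01 ms")
    return np.int64(ticks)


def integrate_cell(
    state0: np.ndarray,
    params: ParameterSet,
    protocol: StimulusProtocol | None,
    t_end: float,
    dt_out: float = 0.1,
    record_start: float = 0.0,
    dt: float = DEFAULT_DT,
    tables: engine.Tables | None = None,
) -> APTrace:
    """Integrate one cell for ``t_end`` ms and return a sampled trace.

    Samples (V, all 12 membrane currents, Cai, I_stim) every ``dt_out`` ms
    from ``record_start`` on.  Deterministic for fixed inputs.  The
    returned trace carries the final state vector in ``final_state``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if dt_out < dt:
        raise ValueError("dt_out must be at least the internal step")
    state0 = model_core.validate_state(state0)
    if protocol is None:
        protocol = StimulusProtocol(BCL=0.0)

    if tables is None:
        tables = engine.build_tables(params, dt_levels=(dt,))
        level = 0
    else:
        matches = np.flatnonzero(np.isclose(tables.dt_levels, dt))
        if matches.size == 0:
            raise ValueError(f"dt={dt} ms is not one of the table levels")
        level = int(matches[0])

    end_ticks = _ticks(t_end, "t_end")
    rec_start_ticks = _ticks(record_start, "record_start")
    rec_every = _ticks(dt_out, "dt_out")
    bcl_ticks = _ticks(protocol.BCL, "BCL") if protocol.BCL else np.int64(0)
    n_samples = int((end_ticks - rec_start_ticks) // rec_every) + 1

    S = state0.reshape(-1, 1).copy()
    rec = np.empty((n_samples, engine.N_REC))
    status, fail_t, n_rec = engine._run_cell(
        S, tables.tab, tables.dt_levels, tables.dt_ticks,
        tables.rl_fca, tables.rl_u, tables.rl_v0, tables.rl_v1, tables.pvec,
        level,
        bcl_ticks, protocol.n_beats, _ticks(protocol.offset, "offset"),
        _ticks(protocol.duration, "duration"), -abs(protocol.amplitude),
        end_ticks, rec_start_ticks, rec_every, rec,
    )
    if status != 0:
        raise RuntimeError(
            f"cell integration failed (non-finite state) at t = {fail_t:.2f} ms"
        )
    t = record_start + dt_out * np.arange(n_rec)
    return APTrace(t, rec[:n_rec], final_state=S[:, 0].copy())
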