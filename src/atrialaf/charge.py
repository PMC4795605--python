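"""Charge integrals of individual currents and their rate dependence.

For each membrane current i, Q_i is the trapezoidal integral of its
density over a fixed beat window — stimulus at t = 20 ms, return to rest
at t = 500 ms — so Q_i is the total charge (pA*ms/pF) that current moves
during one action potential.  The rate-adaptation decomposition compares
steady beats at 0.5 Hz and 2 Hz:

    dQ_i = Q_i(0.5 Hz) - Q_i(2 Hz).

Sign convention: the membrane convention is kept throughout — inward
currents are negative, so Q_CaL < 0 — and consequently a current with
negative dQ carries more depolarizing (or less repolarizing) charge at
the slow rate and therefore promotes APD prolongation at 0.5 Hz, i.e. it
*drives* rate adaptation; a positive dQ opposes it.  (Stating the rule
once: dQ < 0 -> prolongation at the slow rate; dQ > 0 -> shortening.)

The Na+/Ca2+ exchanger is additionally split by mode: the reverse
(outward, Ca2+-entry) phase from stimulus onset to the current's first
zero crossing, and the forward (inward) phase from that crossing to the
time of the current's minimum during repolarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import CURRENT_NAMES
from .trace import APTrace

T_STIM = 20.0      # ms, stimulus time in the aligned beat
T_REPOL = 500.0    # ms, end of the integration window (back at rest)


def align_final_beat(trace: APTrace, t_stim: float = T_STIM,
                     t_need: float = T_REPOL) -> APTrace:
    """Re-time the latest beat so its stimulus onset sits at ``t_stim``.

    Chooses the latest stimulus onset that still leaves ``t_need - t_stim``
    ms of trace after it.  Raises if no stimulus pulse is recorded or no
    onset has enough tail.
    """
    stim = trace.I_stim
    active = np.flatnonzero(stim != 0.0)
    if active.size == 0:
        raise ValueError("trace has no recorded stimulus; cannot align a beat")
    onsets = active[np.flatnonzero(np.diff(active, prepend=-10) > 1)]
    t_onsets = trace.t[onsets]
    usable = t_onsets[t_onsets + (t_need - t_stim) <= trace.t[-1] + 1e-9]
    if usable.size == 0:
        raise ValueError(
            f"no beat has {t_need - t_stim} ms of trace after its stimulus"
        )
    return trace.shifted(usable[-1] - t_stim)


def integrate_charge(trace: APTrace, current: str,
                     window: tuple[float, float] = (T_STIM, T_REPOL)) -> float:
    """Trapezoidal integral (pA*ms/pF) of one current over the window.

    The trace must already be beat-aligned (stimulus at t = 20 ms).
    Inward charge is negative.
    """
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("empty integration window")
    if t0 < trace.t[0] - 1e-9 or t1 > trace.t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] ms outside trace span "
            f"[{trace.t[0]:.6g}, {trace.t[-1]:.6g}] ms"
        )
    sub = trace.window(t0, t1)
    return float(np.trapezoid(sub.current(current), sub.t))


@dataclass
class ChargeTable:
    """Per-current charge at two rates and their difference."""

    table: pd.DataFrame          # index: current name; columns Q_slow, Q_fast, dQ
    rate_slow_hz: float = 0.5
    rate_fast_hz: float = 2.0
    window: tuple[float, float] = (T_STIM, T_REPOL)

    def dq(self, current: str) -> float:
        return float(self.table.loc[current, "dQ"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.6g")


def delta_q(trace_slow: APTrace, trace_fast: APTrace,
            currents=CURRENT_NAMES,
            window: tuple[float, float] = (T_STIM, T_REPOL),
            align: bool = True) -> ChargeTable:
    """dQ_i = Q_i(slow) - Q_i(fast) for every requested current.

    Both traces must be steady-state recordings containing at least one
    full beat plus the window tail; they are re-timed so the stimulus
    fires at t = 20 ms (``align=False`` if already aligned).
    """
    if align:
        trace_slow = align_final_beat(trace_slow, window[0], window[1])
        trace_fast = align_final_beat(trace_fast, window[0], window[1])
    rows = {}
    for name in currents:
        qs = integrate_charge(trace_slow, name, window)
        qf = integrate_charge(trace_fast, name, window)
        rows[name] = (qs, qf, qs - qf)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["Q_slow", "Q_fast", "dQ"]
    )
    return ChargeTable(table=table, window=window)


# ---------------------------------------------------------------------------
# NCX mode split
# ---------------------------------------------------------------------------

@dataclass
class NCXModeSplit:
    """Reverse- and forward-mode NCX charge during one beat.

    In the membrane convention the reverse (outward) integral is >= 0 and
    the forward (inward) integral is <= 0.  ``t_cross`` is the first
    zero crossing after the stimulus, ``t_min`` the time of the current's
    minimum (deep forward mode during late repolarization).
    """

    reverse: float
    forward: float
    t_cross: float | None       # ms, None when the mode is absent
    t_min: float | None
    flag: str | None = None     # set when one mode is empty


def split_ncx_modes(trace: APTrace, t_stim: float = T_STIM,
                    align: bool = True) -> NCXModeSplit:
    """Split the I_NaCa integral of one beat into reverse and forward modes.

    Reverse mode: stimulus onset -> first zero crossing (linear
    interpolation).  Forward mode: zero crossing -> time of the I_NaCa
    minimum.  A beat in which the current never changes sign returns the
    missing mode as 0 with a flag.
    """
    if align:
        trace = align_final_beat(trace, t_stim)
    beat = trace.window(t_stim, trace.t[-1])
    t = beat.t
    i_ncx = beat.current("I_NaCa")

    positive = np.flatnonzero(i_ncx > 0)
    if positive.size == 0:
        # inward throughout: no reverse mode
        k_min = int(np.argmin(i_ncx))
        fwd = float(np.trapezoid(i_ncx[: k_min + 1], t[: k_min + 1]))
        return NCXModeSplit(reverse=0.0, forward=fwd, t_cross=None,
                            t_min=float(t[k_min]), flag="no reverse mode")
    k0 = positive[0]
    negative = np.flatnonzero(i_ncx < 0)
    negative = negative[negative > k0]
    if negative.size == 0:
        # never goes inward: all charge is reverse mode
        rev = float(np.trapezoid(i_ncx, t))
        return NCXModeSplit(reverse=rev, forward=0.0, t_cross=None,
                            t_min=None, flag="no forward mode")
    # last positive sample before the first strictly negative one
    k = negative[0] - 1
    while i_ncx[k] <= 0 and k > k0:
        k -= 1
    frac = i_ncx[k] / (i_ncx[k] - i_ncx[k + 1])
    t_cross = float(t[k] + frac * (t[k + 1] - t[k]))

    # reverse: [t_stim, t_cross], with the interpolated end point
    rev_t = np.append(t[: k + 1], t_cross)
    rev_i = np.append(i_ncx[: k + 1], 0.0)
    reverse = float(np.trapezoid(rev_i, rev_t))

    after = slice(k + 1, None)
    k_min = k + 1 + int(np.argmin(i_ncx[after]))
    fwd_t = np.concatenate([[t_cross], t[k + 1 : k_min + 1]])
    fwd_i = np.concatenate([[0.0], i_ncx[k + 1 : k_min + 1]])
    forward = float(np.trapezoid(fwd_i, fwd_t))

    return NCXModeSplit(reverse=reverse, forward=forward,
                        t_cross=t_cross, t_min=float(t[k_min]))
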