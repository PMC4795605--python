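"""Synthetic fixtures with analytically known answers.

Every measurement stage of the pipeline (APD/RMP reading, charge
integration, NCX mode splitting, phase mapping, PS detection, restitution
slopes) can be exercised on constructed inputs whose correct results are
known in closed form, without running any cell or tissue simulation.
Each maker returns the synthetic object together with its expected
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CURRENT_NAMES, N_REC, REC_NAMES
from .trace import APTrace


# ---------------------------------------------------------------------------
# AP-shaped traces
# ---------------------------------------------------------------------------

@dataclass
class APFixture:
    """Piecewise-linear AP surrogate with exact expected measurements."""

    trace: APTrace
    apd: float                  # expected APD at `threshold`
    rmp: float
    peak: float
    bcl: float
    threshold: float
    t_up: np.ndarray            # exact upward crossing times, per beat
    t_down: np.ndarray
    currents: dict = field(default_factory=dict)


def make_ap_fixture(
    apd: float = 300.0,
    rmp: float = -80.0,
    peak: float = 20.0,
    bcl: float = 1000.0,
    n_beats: int = 2,
    threshold: float = -70.8,
    dt: float = 0.5,
    rise: float = 1.0,
    offset: float = 20.0,
    stim_amplitude: float = 20.0,
    stim_duration: float = 2.0,
    currents: dict | None = None,
) -> APFixture:
    """Build an AP-shaped trace with exactly known threshold crossings.

    Each beat rises linearly from ``rmp`` to ``peak`` over ``rise`` ms at
    its stimulus onset, then declines linearly so the downward crossing
    of ``threshold`` falls exactly ``apd`` ms after the upward crossing;
    after reaching ``rmp`` the trace stays flat.  ``currents`` maps
    current names to constant surrogate densities (pA/pF).  The corner
    times are kept on the sample grid so interpolated crossings are exact.
    """
    if apd >= bcl:
        raise ValueError("APD must be shorter than the BCL")
    if not rmp < threshold < peak:
        raise ValueError("threshold must lie between RMP and peak")
    if rise <= 0 or abs(round(rise / dt) * dt - rise) > 1e-9:
        raise ValueError("rise must be a positive multiple of dt")
    t_end = offset + n_beats * bcl
    t = np.arange(0.0, t_end + dt / 2, dt)
    V = np.full_like(t, rmp)
    stim = np.zeros_like(t)

    frac_up = (threshold - rmp) / (peak - rmp)
    t_ups, t_downs = [], []
    for k in range(n_beats):
        t0 = offset + k * bcl
        t_up = t0 + rise * frac_up
        t_down = t_up + apd
        decline = (peak - threshold) / (t_down - (t0 + rise))
        if decline <= 0:
            raise ValueError("inconsistent shape: APD too short for the rise")
        t_rest = t0 + rise + (peak - rmp) / decline
        if t_rest >= t0 + bcl:
            raise ValueError("inconsistent shape: beat does not return to rest")
        seg = (t >= t0) & (t <= t0 + rise)
        V[seg] = rmp + (peak - rmp) * (t[seg] - t0) / rise
        seg = (t > t0 + rise) & (t < t_rest)
        V[seg] = peak - decline * (t[seg] - (t0 + rise))
        stim[(t >= t0) & (t < t0 + stim_duration)] = -abs(stim_amplitude)
        t_ups.append(t_up)
        t_downs.append(t_down)

    data = np.zeros((t.size, N_REC))
    data[:, 0] = V
    currents = dict(currents or {})
    for name, value in currents.items():
        if name not in CURRENT_NAMES:
            raise KeyError(f"unknown current {name!r}")
        data[:, 1 + CURRENT_NAMES.index(name)] = value
    data[:, REC_NAMES.index("I_stim")] = stim
    return APFixture(
        trace=APTrace(t, data), apd=apd, rmp=rmp, peak=peak, bcl=bcl,
        threshold=threshold, t_up=np.asarray(t_ups), t_down=np.asarray(t_downs),
        currents=currents,
    )


@dataclass
class NCXFixture:
    """Half-sine NCX beat with analytic mode integrals.

    ``expected_reverse`` is the full positive half-sine area;
    ``expected_forward`` is the area from the zero crossing to the
    current's minimum — half of the negative half-sine's total, which is
    exactly what the mode split integrates.
    """

    trace: APTrace
    expected_reverse: float
    expected_forward: float
    t_cross: float
    t_min: float


def make_ncx_fixture(
    reverse_area: float = 30.0,
    forward_area: float = -80.0,
    t_stim: float = 20.0,
    width_rev: float = 60.0,
    width_fwd: float = 200.0,
    t_end: float = 520.0,
    dt: float = 0.1,
) -> NCXFixture:
    """I_NaCa as a positive half-sine (reverse mode) followed by a negative
    half-sine (forward mode) with the given analytic areas.

    A half-sine of width W and amplitude a has area 2*a*W/pi.
    """
    if reverse_area <= 0 or forward_area >= 0:
        raise ValueError("reverse area must be positive, forward negative")
    t = np.arange(0.0, t_end + dt / 2, dt)
    i_ncx = np.zeros_like(t)
    a_rev = reverse_area * np.pi / (2.0 * width_rev)
    a_fwd = forward_area * np.pi / (2.0 * width_fwd)
    t_cross = t_stim + width_rev
    seg = (t >= t_stim) & (t <= t_cross)
    i_ncx[seg] = a_rev * np.sin(np.pi * (t[seg] - t_stim) / width_rev)
    seg = (t > t_cross) & (t <= t_cross + width_fwd)
    i_ncx[seg] = a_fwd * np.sin(np.pi * (t[seg] - t_cross) / width_fwd)

    data = np.zeros((t.size, N_REC))
    data[:, 0] = -80.0
    data[:, 1 + CURRENT_NAMES.index("I_NaCa")] = i_ncx
    stim_col = REC_NAMES.index("I_stim")
    data[(t >= t_stim) & (t < t_stim + 2.0), stim_col] = -20.0
    return NCXFixture(
        trace=APTrace(t, data),
        expected_reverse=reverse_area, expected_forward=forward_area / 2.0,
        t_cross=t_cross, t_min=t_cross + width_fwd / 2.0,
    )


# ---------------------------------------------------------------------------
# Phase fields
# ---------------------------------------------------------------------------

def make_phase_fixture(vortices, shape=(64, 64)) -> np.ndarray:
    """Phase map that superposes analytic vortices.

    ``vortices`` is a list of (y0, x0, charge); the returned (ny, nx)
    field is sum_i charge_i * atan2(y - y0, x - x0), wrapped to
    (-pi, pi].  Coincident vortices are rejected.
    """
    ny, nx = shape
    pts = [(float(y), float(x), int(q)) for y, x, q in vortices]
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            if (pts[a][0], pts[a][1]) == (pts[b][0], pts[b][1]):
                raise ValueError("coincident vortices are not allowed")
        if not (0 <= pts[a][0] < ny and 0 <= pts[a][1] < nx):
            raise ValueError("vortex outside the grid")
    yy, xx = np.mgrid[0:ny, 0:nx]
    phase = np.zeros(shape, dtype=float)
    for y0, x0, q in pts:
        phase += q * np.arctan2(yy - y0, xx - x0)
    return (phase + np.pi) % (2.0 * np.pi) - np.pi


def make_rotating_frames(
    shape=(40, 40),
    period: float = 100.0,
    n_frames: int = 12,
    frame_interval: float = 10.0,
    amplitude: float = 30.0,
    v_offset: float = -50.0,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Voltage frames V(x, t) = v_offset + A*cos(w*t - theta(x)).

    With embedding origin v_offset and delay tau = period/4, the
    delay-embedded phase equals theta(x) - w*t (mod 2pi) — a closed-form
    target for the phase computation.
    """
    ny, nx = shape
    if theta is None:
        yy, xx = np.mgrid[0:ny, 0:nx]
        theta = 2.0 * np.pi * xx / nx
    w = 2.0 * np.pi / period
    tt = frame_interval * np.arange(n_frames)
    return v_offset + amplitude * np.cos(
        w * tt[:, None, None] - theta[None, :, :]
    )


# ---------------------------------------------------------------------------
# Restitution points
# ---------------------------------------------------------------------------

def make_restitution_points(
    slope: float = 1.2,
    intercept: float = 120.0,
    di: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(DI, APD) points on an exactly linear restitution curve, with
    optional Gaussian noise."""
    if di is None:
        di = np.linspace(20.0, 300.0, 15)
    di = np.asarray(di, dtype=float)
    apd = intercept + slope * di
    if noise_sd > 0:
        apd = apd + np.random.default_rng(seed).normal(0.0, noise_sd, di.size)
    return di, apd
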