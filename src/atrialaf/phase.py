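"""Phase maps and phase-singularity (PS) detection for 2D voltage frames.

The phase of each node is obtained by time-delay embedding of the
membrane potential (Iyer & Gray, Ann Biomed Eng 2001): with delay tau and
origin V*, phase(x, t) is the angle of the point
``(V(x, t) - V*, V(x, t + tau) - V*)`` in the embedded plane.  A phase
singularity is a point around which the phase winds by +-2pi; it marks a
spiral-wave (rotor) core.  Detection sums wrapped phase differences
around every 2x2 plaquette of the grid; a loop sum of +-2pi flags a PS of
that topological charge at the plaquette centre.

PS activity is summarized as a density in time and space:
``1000 * N / N_frames / frame_interval_ms / area_cm2`` (units s^-1 cm^-2),
i.e. the number of PS detections per second and per cm^2 of tissue.  A
rotor present in every frame of a 225 cm^2 domain sampled at 10 ms
contributes 1000 * 1/10/225 ~ 0.444 in these units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_TAU = 10.0       # ms, embedding delay (one frame at 10 ms)
DEFAULT_V_STAR = -50.0   # mV, embedding origin (mid-range of the AP)


@dataclass(frozen=True)
class PSEvent:
    """One phase-singularity detection."""

    frame: int
    y: float
    x: float          # grid coordinates of the plaquette centre
    charge: int       # +1 or -1 (winding of +-2pi)

    def __post_init__(self) -> None:
        if self.charge not in (-1, 1):
            raise ValueError("topological charge must be +-1")


@dataclass(frozen=True)
class PSDensity:
    n_events: int
    n_frames: int
    frame_interval_ms: float
    area_cm2: float

    @property
    def density(self) -> float:
        """PS detections per second per cm^2."""
        return ps_density(self.n_events, self.n_frames,
                          self.frame_interval_ms, self.area_cm2)


def compute_phase(
    frames: np.ndarray,
    frame_interval_ms: float,
    tau: float = DEFAULT_TAU,
    v_star: float = DEFAULT_V_STAR,
) -> np.ndarray:
    """Delay-embedded phase of a (n_frames, ny, nx) voltage stack.

    Returns an (n_frames - k, ny, nx) stack of angles in (-pi, pi], where
    k = tau / frame_interval (the trailing tau of frames has no partner
    and is dropped).  Raises if tau is not a positive multiple of the
    frame interval.  Nodes pinned exactly at V* in both embedding
    coordinates have undefined phase; they are returned as NaN.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be (n_frames, ny, nx)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    k = tau / frame_interval_ms
    if abs(k - round(k)) > 1e-9:
        raise ValueError("tau must be a multiple of the frame interval")
    k = int(round(k))
    if k >= frames.shape[0]:
        raise ValueError("tau exceeds the trace length")
    a = frames[:-k] - v_star          # V(t) - V*
    b = frames[k:] - v_star           # V(t + tau) - V*
    phase = np.arctan2(b, a)
    phase[(a == 0.0) & (b == 0.0)] = np.nan
    return phase


def _wrap(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    return (dphi + np.pi) % (2.0 * np.pi) - np.pi


def detect_ps(phase: np.ndarray, frame: int = 0) -> list[PSEvent]:
    """Phase singularities of one phase map (ny, nx).

    Sums the wrapped phase differences counterclockwise around every 2x2
    plaquette; a loop sum of +-2pi yields a PS of charge +-1 at the
    plaquette centre.  Returns an empty list when no PS is present.
    """
    counts, charges, ys, xs = _ps_plaquettes(phase)
    return [
        PSEvent(frame=frame, y=float(y), x=float(x), charge=int(c))
        for y, x, c in zip(ys, xs, charges)
    ]


def _ps_plaquettes(phase: np.ndarray):
    phase = np.asarray(phase, dtype=float)
    if phase.ndim != 2:
        raise ValueError("phase map must be 2D")
    p00 = phase[:-1, :-1]
    p01 = phase[:-1, 1:]
    p11 = phase[1:, 1:]
    p10 = phase[1:, :-1]
    loop = (
        _wrap(p01 - p00) + _wrap(p11 - p01) + _wrap(p10 - p11) + _wrap(p00 - p10)
    )
    hit = np.abs(loop) > np.pi  # loop sums are ~0 or ~+-2pi
    ys, xs = np.nonzero(hit)
    charges = np.sign(loop[ys, xs]).astype(int)
    return int(hit.sum()), charges, ys + 0.5, xs + 0.5


def count_ps_per_frame(phase_stack: np.ndarray) -> np.ndarray:
    """Number of PS detections in each frame of a phase stack."""
    return np.array([_ps_plaquettes(ph)[0] for ph in phase_stack], dtype=int)


def ps_density(n_events: int, n_frames: int, frame_interval_ms: float,
               area_cm2: float) -> float:
    """PS count normalized per second and per cm^2.

    density = 1000 * N / N_frames / frame_interval_ms / area_cm2.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if frame_interval_ms <= 0 or area_cm2 <= 0:
        raise ValueError("frame interval and area must be positive")
    return 1000.0 * n_events / n_frames / frame_interval_ms / area_cm2
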