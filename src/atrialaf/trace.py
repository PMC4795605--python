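"""Uniformly sampled action-potential traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import CURRENT_NAMES, REC_NAMES


@dataclass
class APTrace:
    """Membrane potential, per-current densities and Ca2+ transient over time.

    ``t`` is in ms; ``data`` has one row per sample and columns ordered as
    :data:`atrialaf.engine.REC_NAMES` (V in mV, currents in pA/pF with
    inward negative, Cai in mM, I_stim in pA/pF).
    """

    t: np.ndarray
    data: np.ndarray
    final_state: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.t.size, len(REC_NAMES)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({self.t.size}, {len(REC_NAMES)})"
            )

    # -- column access -----------------------------------------------------

    @property
    def V(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def Cai(self) -> np.ndarray:
        return self.data[:, len(REC_NAMES) - 2]

    @property
    def I_stim(self) -> np.ndarray:
        return self.data[:, len(REC_NAMES) - 1]

    def current(self, name: str) -> np.ndarray:
        if name not in CURRENT_NAMES:
            raise KeyError(f"unknown current {name!r}; expected one of {CURRENT_NAMES}")
        return self.data[:, 1 + CURRENT_NAMES.index(name)]

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValueError("trace has fewer than two samples")
        return float(self.t[1] - self.t[0])

    # -- manipulation ------------------------------------------------------

    def window(self, t0: float, t1: float) -> "APTrace":
        """Sub-trace with t0 <= t <= t1 (small tolerance on the edges)."""
        eps = 1e-9
        mask = (self.t >= t0 - eps) & (self.t <= t1 + eps)
        if not mask.any():
            raise ValueError(f"window [{t0}, {t1}] ms is outside the trace")
        return APTrace(self.t[mask], self.data[mask], self.final_state)

    def shifted(self, t_new_origin_at: float) -> "APTrace":
        """Re-time so the sample currently at ``t_new_origin_at`` is t = 0."""
        return APTrace(self.t - t_new_origin_at, self.data, self.final_state)

    # -- serialization -----------------------------------------------------

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.t, self.data]), columns=("t",) + REC_NAMES
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def to_hdf5(self, path, name: str = "trace") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("t", data=self.t)
            g.create_dataset("data", data=self.data)
            g.attrs["columns"] = list(REC_NAMES)
            if self.final_state is not None:
                g.create_dataset("final_state", data=self.final_state)

    @classmethod
    def from_hdf5(cls, path, name: str = "trace") -> "APTrace":
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[name]
            fs = g["final_state"][...] if "final_state" in g else None
            return cls(g["t"][...], g["data"][...], fs)
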