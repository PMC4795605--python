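# atrialaf

Rate-dependent action-potential duration and reentry patterns in a
mathematical model of the persistently fibrillating human atrium.

Persistent atrial fibrillation (PeAF) remodels atrial ion channels —
chiefly L-type Ca²⁺ current down 50–70% and inward-rectifier K⁺ current
up 100% — which shortens the action potential (APD) and blunts its
rate adaptation. This package implements the full computational chain
for studying that remodeling quantitatively:

* the Courtemanche–Ramirez–Nattel (CRN) human atrial cell model with the
  PeAF remodeling recipe applied as multiplicative parameter changes;
* regression-based parameter sensitivity: APD of lognormally perturbed
  parameter populations (median 1, log-SD 0.1) regressed on the scale
  factors, `X·B ≈ Y`, giving signed dimensionless sensitivities and R²;
* per-current charge integrals `Q_i = ∫ I_i dt` over a fixed beat window
  and their rate difference `ΔQ_i = Q_i(0.5 Hz) − Q_i(2 Hz)`, which
  attributes APD rate adaptation to individual currents (inward
  negative: ΔQ < 0 promotes adaptation), plus the forward/reverse-mode
  split of the Na⁺/Ca²⁺-exchange current;
* monodomain tissue (`∂V/∂t = −(I_ion+I_stim)/C_m + D∇²V`,
  D = 0.001 cm²/ms, Δx = 0.025 cm): cable conduction velocity, the
  dynamic APD-restitution protocol with maximal slope S_max, and
  cross-field S1–S2 spiral-wave induction on a 2D sheet;
* Iyer–Gray phase-singularity detection (time-delay embedding, ±2π
  plaquette winding) with the PS-density normalization
  `1000·N/N_frames/Δt_frame/area` in s⁻¹·cm⁻².

`docs/methods.md` documents the model, conventions and numerics.

## Worked example

```python
from atrialaf import pacing
from atrialaf.params import ParameterSet, apply_remodeling

control = ParameterSet()                       # CRN defaults
peaf = apply_remodeling(control, "PeAF1")      # the 7-parameter recipe

for name, p in [("control", control), ("PeAF1", peaf)]:
    res = pacing.pace_to_steady_state(p, bcl=1000.0)   # 250 s at 1 Hz
    print(f"{name}: RMP {res.rmp:.2f} mV, APD {res.apd:.1f} ms")
```

prints

```
control: RMP -81.41 mV, APD 272.8 ms
PeAF1: RMP -83.90 mV, APD 143.6 ms
```

— the remodeled cell rests ~2.5 mV *more* negative (doubled I_K1) and
its action potential is roughly halved. The numbered drivers under
`analysis/` run each full analysis and narrate what they find:

```
01_single_cell_ap.py        RMP/APD per remodeling variant
02_sensitivity_regression.py  R² and ranked APD sensitivities
03_ncx_modes.py             forward/reverse NCX charge, control vs PeAF
04_rate_adaptation.py       APD-vs-BCL curves and 0.5–2 Hz slopes
05_charge_decomposition.py  ΔQ per current, control vs PeAF1
06_restitution.py           cable restitution and S_max
07_spiral_waves.py          2D reentry and phase-singularity counts
```

Outputs (CSV/HDF5 plus a manifest with config hash and checksums) land
under `results/`. Full-size experiment configurations (1000-trial
sensitivity, the 15 cm × 15 cm sheet) are provided as YAML files under
`configs/` and run through `atrialaf run <config.yaml>`; they take hours
on one core. A `atrialaf` command-line tool exposes the same operations
(`pace`, `sensitivity`, `charge`, `tissue`, `ps`, `run`).

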