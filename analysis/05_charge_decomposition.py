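#!/usr/bin/env python
"""Which currents carry the rate dependence of APD: dQ decomposition.

Integrates every membrane current over the fixed beat window (stimulus
at 20 ms, rest by 500 ms) at steady 0.5 Hz and 2 Hz pacing and forms
dQ = Q(0.5 Hz) - Q(2 Hz) per current, for control and PeAF1.  In the
membrane sign convention a negative dQ means the current carries more
depolarizing charge at the slow rate, i.e. it drives APD prolongation
there — it promotes rate adaptation; positive dQ opposes it.  Expected
structure: I_CaL dominates adaptation in control with I_Kur opposing;
in PeAF the up-regulated exchanger joins I_CaL.
"""

from pathlib import Path

import pandas as pd

from atrialaf.experiments import ExperimentConfig, run_experiment

outdir = Path(__file__).resolve().parents[1] / "results"
for variant in ("control", "PeAF1"):
    cfg = ExperimentConfig("fig4-dq", variant=variant, scale="desk",
                           settings={"pace_duration": 250_000.0},
                           outdir=str(outdir))
    run_experiment(cfg)
    df = pd.read_csv(outdir / f"fig4-dq_{variant}_desk" / f"dq_{variant}.csv",
                     index_col=0)
    promoting = df[df.dQ < 0].dQ.sort_values()
    print(f"\n{variant}: dQ per current (pA*ms/pF)")
    print(df.round(1).to_string())
    print(f"  adaptation-promoting (most negative first): "
          f"{', '.join(f'{n} {v:.0f}' for n, v in promoting.head(3).items())}")
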