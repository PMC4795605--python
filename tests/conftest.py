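"""Shared fixtures.

The expensive simulations (desk-scale sensitivity population, 2D rotor
run, steady 1 Hz pacing) are session-scoped so every test that needs
them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from atrialaf import pacing, sensitivity, tissue
from atrialaf.params import ParameterSet, apply_remodeling

#: desk-scale tissue numerics used throughout the tests: 5 cm sheet,
#: 0.05 ms reaction-step floor (convergence-checked against 0.025 ms)
DESK_SHEET = dict(nx=200, ny=200, dt_levels=(0.05, 0.1))
DESK_CABLE = dict(nx=128, ny=1, dt_levels=(0.05, 0.1))

#: cross-field S2 coupling intervals that induce reentry on the 5 cm sheet
DESK_S2 = {"PeAF2": 200.0, "PeAF1": 225.0, "ICaL50": 300.0}


@pytest.fixture(scope="session")
def control_params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def peaf1_params() -> ParameterSet:
    return apply_remodeling(ParameterSet(), "PeAF1")


@pytest.fixture(scope="session")
def control_population_desk():
    """Desk-scale sensitivity population: 200 trials, 60 s of 1 Hz pacing,
    seed 1 (shared by the fit-quality and robustness checks)."""
    sample = sensitivity.sample_scales(200, seed=1)
    pop = sensitivity.run_population(sample, ParameterSet(),
                                     pace_duration=60_000.0)
    result = sensitivity.regress_population(pop)
    return sample, pop, result


@pytest.fixture(scope="session")
def control_1hz_steady(control_params):
    """Control cell paced at 1 Hz for 250 s (twice-threshold stimulus)."""
    return pacing.pace_to_steady_state(control_params, 1000.0)


@pytest.fixture(scope="session")
def peaf1_1hz_steady(peaf1_params):
    return pacing.pace_to_steady_state(peaf1_params, 1000.0)


@pytest.fixture(scope="session")
def peaf2_desk_frames():
    """Cross-field PeAF2 run on the 5 cm desk sheet (stable-rotor case)."""
    params = apply_remodeling(ParameterSet(), "PeAF2")
    config = tissue.TissueConfig(**DESK_SHEET)
    proto = tissue.CrossFieldProtocol(s2_time=DESK_S2["PeAF2"])
    return tissue.simulate_2d(params, config, proto, t_end=1100.0)


def soft_assert(failures: list[str], condition: bool, message: str) -> None:
    """Collect assertion failures so every clause of a check reports."""
    if not condition:
        failures.append(message)


def finish_soft(failures: list[str]) -> None:
    assert not failures, "failed clauses:\n" + "\n".join(f"  - {m}" for m in failures)
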