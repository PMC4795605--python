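"""APD/RMP measurement, threshold calibration, adaptation-slope helpers."""

import numpy as np
import pytest

from atrialaf import fixtures, pacing
from atrialaf.params import ParameterSet


# ---------------------------------------------------------------------------
# Measurement on synthetic traces
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("apd, bcl", [(300.0, 1000.0), (120.0, 400.0), (55.0, 330.0)])
def test_measure_apd_exact_on_fixture(apd, bcl):
    fx = fixtures.make_ap_fixture(apd=apd, bcl=bcl)
    m = pacing.measure_apd(fx.trace)
    assert m.apd == pytest.approx(apd, abs=0.1)
    assert m.t_up == pytest.approx(fx.t_up[-1], abs=0.1)
    assert m.t_down == pytest.approx(fx.t_down[-1], abs=0.1)


def test_measure_apd_interpolation_insensitive_to_sampling():
    a = fixtures.make_ap_fixture(dt=0.5)
    b = fixtures.make_ap_fixture(dt=0.25)
    assert abs(pacing.measure_apd(a.trace).apd
               - pacing.measure_apd(b.trace).apd) < 0.1


def test_constant_trace_reports_no_ap():
    fx = fixtures.make_ap_fixture()
    flat = fx.trace
    flat.data[:, 0] = -80.0
    with pytest.raises(pacing.NoActionPotential):
        pacing.measure_apd(flat)


def test_measure_all_apds_counts_beats():
    fx = fixtures.make_ap_fixture(n_beats=3)
    apds = pacing.measure_all_apds(fx.trace)
    assert len(apds) == 3
    assert [m.beat_index for m in apds] == [0, 1, 2]


def test_measure_rmp_constant_trace():
    fx = fixtures.make_ap_fixture()
    fx.trace.data[:, 0] = -80.0
    fx.trace.data[:, -1] = 0.0  # no stimulus marks
    assert pacing.measure_rmp(fx.trace) == -80.0


def test_measure_rmp_uses_diastolic_window_before_stimulus():
    fx = fixtures.make_ap_fixture(rmp=-79.0, n_beats=2)
    assert pacing.measure_rmp(fx.trace) == pytest.approx(-79.0, abs=1e-9)


def test_measure_rmp_requires_full_cycle():
    fx = fixtures.make_ap_fixture(bcl=1000.0, n_beats=1)
    with pytest.raises(ValueError, match="shorter than one BCL"):
        pacing.measure_rmp(fx.trace.window(0.0, 500.0), bcl=1000.0)


def test_slope_between_endpoints():
    bcls = np.array([330.0, 500.0, 1000.0, 2000.0])
    flat = np.full(4, 250.0)
    assert pacing.slope_between(bcls, flat) == 0.0
    linear = 100.0 + 0.05 * bcls
    assert pacing.slope_between(bcls, linear) == pytest.approx(0.05)
    with pytest.raises(ValueError, match="lacks the BCL"):
        pacing.slope_between(bcls[:2], flat[:2])


# ---------------------------------------------------------------------------
# Threshold calibration (real model, short runs)
# ---------------------------------------------------------------------------

def test_threshold_brackets_capture(control_params):
    thr = pacing.find_threshold(control_params, 1000.0, n_beats=5)
    from atrialaf.pacing import _captures
    from atrialaf import engine

    tables = engine.build_tables(control_params, dt_levels=(0.02,))
    from atrialaf import model_core as mc
    s0 = mc.initial_state()
    assert _captures(control_params, 1000.0, 2.0 * thr, 5, s0, 0.02, tables)
    assert not _captures(control_params, 1000.0, 0.5 * thr, 5, s0, 0.02, tables)


def test_threshold_matches_linear_sweep_oracle(control_params):
    """Bisection threshold agrees with an exhaustive amplitude sweep."""
    thr = pacing.find_threshold(control_params, 1000.0, n_beats=5)
    from atrialaf.pacing import _captures
    from atrialaf import engine, model_core as mc

    tables = engine.build_tables(control_params, dt_levels=(0.02,))
    s0 = mc.initial_state()
    grid = thr * np.arange(0.95, 1.06, 0.01)
    captured = [_captures(control_params, 1000.0, a, 5, s0, 0.02, tables)
                for a in grid]
    first = grid[int(np.argmax(captured))]
    assert abs(first - thr) <= 0.011 * thr


def test_threshold_rejects_out_of_range_bcl(control_params):
    with pytest.raises(ValueError, match="outside the single-cell range"):
        pacing.find_threshold(control_params, 5000.0)


def test_no_capture_at_max_amplitude_raises(control_params):
    with pytest.raises(RuntimeError, match="no capture"):
        pacing.find_threshold(control_params, 1000.0, amp_max=0.5)


def test_all_variants_capture_at_1hz():
    """Every remodeling variant supports 1:1 capture at 1 Hz (the
    threshold search itself verifies an AP on every beat)."""
    from atrialaf.params import VARIANTS, apply_remodeling

    for variant in VARIANTS:
        params = apply_remodeling(ParameterSet(), variant)
        thr = pacing.find_threshold(params, 1000.0, n_beats=5)
        assert 0.0 < thr < 80.0
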