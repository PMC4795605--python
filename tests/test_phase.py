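"""Phase maps, PS detection, density normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrialaf import fixtures, phase


# ---------------------------------------------------------------------------
# compute_phase
# ---------------------------------------------------------------------------

def test_uniform_periodic_voltage_gives_uniform_phase():
    t = np.arange(20)
    frames = -50.0 + 30.0 * np.cos(0.3 * t)[:, None, None] * np.ones((1, 8, 8))
    ph = phase.compute_phase(frames, 10.0, tau=10.0)
    for k in range(ph.shape[0]):
        assert np.ptp(ph[k]) == pytest.approx(0.0, abs=1e-12)


def test_quarter_period_embedding_recovers_spatial_phase():
    period = 120.0
    frames = fixtures.make_rotating_frames(period=period, n_frames=10,
                                           frame_interval=10.0)
    ph = phase.compute_phase(frames, 10.0, tau=period / 4.0, v_star=-50.0)
    ny, nx = frames.shape[1:]
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = 2.0 * np.pi * xx / nx
    w = 2.0 * np.pi / period
    # embedded phase = theta - w*t (mod 2pi)
    for k in range(ph.shape[0]):
        expect = np.angle(np.exp(1j * (theta - w * (10.0 * k))))
        diff = np.angle(np.exp(1j * (ph[k] - expect)))
        assert np.abs(diff).max() < 1e-9


def test_degenerate_origin_flagged_as_nan():
    frames = np.full((5, 4, 4), -50.0)
    ph = phase.compute_phase(frames, 10.0, tau=10.0, v_star=-50.0)
    assert np.isnan(ph).all()


@pytest.mark.parametrize("tau", [0.0, -10.0, 7.0])
def test_invalid_tau_rejected(tau):
    frames = np.zeros((6, 4, 4))
    with pytest.raises(ValueError):
        phase.compute_phase(frames, 10.0, tau=tau)


# ---------------------------------------------------------------------------
# detect_ps
# ---------------------------------------------------------------------------

def test_single_vortex_detected_at_core():
    pm = fixtures.make_phase_fixture([(20.0 + 0.3, 30.0 + 0.7, +1)])
    events = phase.detect_ps(pm)
    assert len(events) == 1
    ev = events[0]
    assert ev.charge == +1
    assert abs(ev.y - 20.3) < 1.0 and abs(ev.x - 30.7) < 1.0


def test_uniform_phase_has_no_ps():
    assert phase.detect_ps(np.full((32, 32), 1.234)) == []


def test_vortex_antivortex_pair_net_charge_zero():
    pm = fixtures.make_phase_fixture([(10.2, 10.4, +1), (40.6, 50.1, -1)])
    events = phase.detect_ps(pm)
    assert len(events) == 2
    assert sum(ev.charge for ev in events) == 0


def test_three_vortices_counts_and_net_charge():
    pm = fixtures.make_phase_fixture(
        [(10.5, 12.5, +1), (30.5, 40.5, +1), (50.5, 20.5, -1)])
    events = phase.detect_ps(pm)
    assert len(events) == 3
    assert sum(ev.charge for ev in events) == +1


@given(dy=st.floats(-3.0, 3.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_detection_invariant_under_global_phase_shift(dy):
    pm = fixtures.make_phase_fixture([(25.4, 33.6, +1)], (56, 56))
    shifted = (pm + dy + np.pi) % (2 * np.pi) - np.pi
    a = phase.detect_ps(pm)
    b = phase.detect_ps(shifted)
    assert [(ev.y, ev.x, ev.charge) for ev in a] == \
           [(ev.y, ev.x, ev.charge) for ev in b]


def test_charge_conservation_on_pair_annihilation_fixture():
    """Total topological charge is the same whether the pair is present
    or the field is uniform (creation/annihilation in +- pairs)."""
    with_pair = fixtures.make_phase_fixture([(20.5, 20.5, +1), (20.5, 40.5, -1)])
    without = np.zeros((64, 64))
    q1 = sum(ev.charge for ev in phase.detect_ps(with_pair))
    q2 = sum(ev.charge for ev in phase.detect_ps(without))
    assert q1 == q2 == 0


def test_count_ps_per_frame():
    stack = np.stack([
        fixtures.make_phase_fixture([]),
        fixtures.make_phase_fixture([(20.5, 20.5, +1)]),
        fixtures.make_phase_fixture([(20.5, 20.5, +1), (40.5, 40.5, -1)]),
    ])
    np.testing.assert_array_equal(phase.count_ps_per_frame(stack), [0, 1, 2])


# ---------------------------------------------------------------------------
# density normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n, nf, dt, area, expected", [
    (354, 364, 10.0, 225.0, 0.4322),     # the worked normalization
    (0, 364, 10.0, 225.0, 0.0),
    (364, 364, 10.0, 225.0, 0.4444),     # persistent single rotor
])
def test_ps_density_normalization(n, nf, dt, area, expected):
    assert phase.ps_density(n, nf, dt, area) == pytest.approx(expected, abs=5e-5)


def test_ps_density_invalid_inputs():
    with pytest.raises(ValueError):
        phase.ps_density(1, 0, 10.0, 225.0)
    with pytest.raises(ValueError):
        phase.ps_density(1, 10, -1.0, 225.0)


def test_ps_event_validation():
    with pytest.raises(ValueError):
        phase.PSEvent(frame=0, y=1.5, x=1.5, charge=2)
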