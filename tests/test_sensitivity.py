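"""Lognormal sampling and the APD regression machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from atrialaf import sensitivity as S
from atrialaf.params import PARAM_NAMES, ParameterSet


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def test_zero_sigma_gives_exact_ones():
    sample = S.sample_scales(5, sigma=0.0, seed=3)
    np.testing.assert_array_equal(sample.scales, np.ones((5, len(PARAM_NAMES))))


def test_lognormal_median_and_log_sd():
    sample = S.sample_scales(10_000, seed=7)
    med = np.median(sample.scales, axis=0)
    assert np.all(med > 0.99) and np.all(med < 1.01)
    log_sd = np.log(sample.scales).std(axis=0, ddof=1)
    assert np.all(log_sd > 0.095) and np.all(log_sd < 0.105)


def test_sampler_reproducible_and_extensible():
    a = S.sample_scales(10, seed=5).scales
    b = S.sample_scales(25, seed=5).scales
    np.testing.assert_array_equal(a, b[:10])
    c = S.sample_scales(10, seed=6).scales
    assert not np.array_equal(a, c)


@given(n=st.integers(1, 50), sigma=st.floats(0.0, 0.5), seed=st.integers(0, 10**6))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_sampler_properties(n, sigma, seed):
    sample = S.sample_scales(n, sigma=sigma, seed=seed)
    assert sample.scales.shape == (n, len(PARAM_NAMES))
    assert np.all(sample.scales > 0)


def test_negative_sigma_rejected():
    with pytest.raises(ValueError):
        S.sample_scales(5, sigma=-0.1)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

def test_exact_loglinear_system_recovered():
    rng = np.random.default_rng(0)
    X = np.exp(0.1 * rng.standard_normal((200, 6)))
    b_true = np.array([2.0, -1.0, 0.5, 0.0, 1.5, -0.25])
    Y = np.exp(np.log(X) @ b_true)
    res = S.regress(X, Y, names=tuple("abcdef"))
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    # z-scored coefficients are proportional to b_true * sd(log x_j)
    expected = b_true * np.log(X).std(axis=0) / np.log(Y).std()
    np.testing.assert_allclose(res.B, expected, rtol=1e-8, atol=1e-12)


def test_raw_mode_matches_normal_equations_oracle():
    rng = np.random.default_rng(42)
    X = rng.uniform(0.5, 2.0, (50, 5))
    Y = rng.uniform(100.0, 300.0, 50)
    res = S.regress(X, Y, zscore_log=False, names=tuple("abcde"))
    Xi = np.column_stack([X, np.ones(50)])
    b_oracle = np.linalg.solve(Xi.T @ Xi, Xi.T @ Y)
    np.testing.assert_allclose(res.B, b_oracle[:-1], atol=1e-10)


def test_zscore_mode_matches_normal_equations_oracle():
    rng = np.random.default_rng(1)
    X = np.exp(0.1 * rng.standard_normal((50, 5)))
    Y = np.exp(np.log(X) @ np.array([1.0, -2.0, 0.3, 0.7, -0.1])
               + 0.01 * rng.standard_normal(50))
    res = S.regress(X, Y, names=tuple("abcde"))
    lx = np.log(X)
    Xf = (lx - lx.mean(0)) / lx.std(0)
    ly = np.log(Y)
    Yf = (ly - ly.mean()) / ly.std()
    b_oracle = np.linalg.solve(Xf.T @ Xf, Xf.T @ Yf)
    np.testing.assert_allclose(res.B, b_oracle, atol=1e-10)


def test_rank_deficient_design_rejected():
    X = np.exp(0.1 * np.random.default_rng(2).standard_normal((30, 3)))
    X = np.column_stack([X, X[:, 0]])  # duplicated column
    Y = np.exp(np.log(X).sum(axis=1))
    with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
        S.regress(X, Y, names=tuple("abcd"))


def test_nonfinite_inputs_rejected():
    X = np.ones((10, 2))
    Y = np.ones(10)
    Y[3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        S.regress(X, Y, names=("a", "b"))


def test_parameter_recovery_under_noise():
    """Recovered coefficients correlate r > 0.99 with the generating ones
    when the noise SD is 5% of the response SD."""
    rng = np.random.default_rng(11)
    X = np.exp(0.1 * rng.standard_normal((1000, len(PARAM_NAMES))))
    b_true = rng.standard_normal(len(PARAM_NAMES))
    lin = np.log(X) @ b_true
    noisy = lin + 0.05 * lin.std() * rng.standard_normal(1000)
    res = S.regress(X, np.exp(noisy))
    r = np.corrcoef(res.B, b_true)[0, 1]
    assert r > 0.99


def test_rank_sensitivities_orders_by_magnitude():
    res = S.SensitivityResult(
        X=np.zeros((4, 3)), Y=np.zeros(4),
        B=np.array([0.2, -0.9, 0.5]), r2=0.9, names=("a", "b", "c"))
    assert S.rank_sensitivities(res) == [("b", -0.9), ("c", 0.5), ("a", 0.2)]


# ---------------------------------------------------------------------------
# Population runs (short pacing; structure comes from the acceptance suite)
# ---------------------------------------------------------------------------

def test_identity_scaling_reproduces_baseline_apd():
    sample = S.sample_scales(3, sigma=0.0, seed=0)
    pop = S.run_population(sample, ParameterSet(), pace_duration=20_000.0,
                           dt=0.1)
    assert pop.n_failed == 0
    assert np.ptp(pop.apds) == 0.0  # identical trials, identical APDs


def test_population_reproducible_bit_for_bit():
    sample = S.sample_scales(2, seed=9)
    runs = [S.run_population(sample, ParameterSet(), pace_duration=10_000.0,
                             dt=0.1, amplitude=27.0).apds for _ in range(2)]
    np.testing.assert_array_equal(runs[0], runs[1])


def test_ik1_upscaling_shortens_apd():
    base = ParameterSet()
    ones = S.ScaleSample(np.ones((1, 20)), sigma=0.0, seed=0)
    k1_up = S.ScaleSample(np.ones((1, 20)), sigma=0.0, seed=0)
    k1_up.scales[0, PARAM_NAMES.index("G_K1")] = 1.2
    apd_base = S.run_population(ones, base, pace_duration=20_000.0,
                                dt=0.1, amplitude=27.0).apds[0]
    apd_k1 = S.run_population(k1_up, base, pace_duration=20_000.0,
                              dt=0.1, amplitude=27.0).apds[0]
    assert apd_k1 < apd_base


def test_no_single_trial_leverage(control_population_desk):
    """Dropping any one trial moves R^2 by less than 0.01."""
    sample, pop, res = control_population_desk
    ok = pop.ok
    X, Y = sample.scales[ok], pop.apds[ok]
    r2_full = res.r2
    worst = 0.0
    for k in range(X.shape[0]):
        keep = np.ones(X.shape[0], dtype=bool)
        keep[k] = False
        r2_k = S.regress(X[keep], Y[keep]).r2
        worst = max(worst, abs(r2_k - r2_full))
    assert worst < 0.01
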