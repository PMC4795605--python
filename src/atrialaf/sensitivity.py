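"""Multivariable-regression parameter sensitivity of APD.

The population protocol: each of the 20 perturbable model parameters is
multiplied by an i.i.d. lognormal scale factor with median 1 and log-SD
sigma = 0.1; each parameter-set variant is paced to steady state at 1 Hz
and its APD measured at the fixed -70.8 mV threshold.  Regressing the
(log, z-scored) APDs on the (log, z-scored) scale-factor matrix X gives a
coefficient vector B of dimensionless sensitivities — X @ B ~ Y — whose
entries say how strongly (and in which direction) each conductance or
rate controls APD.  The fit quality R^2 doubles as a check that APD
responds near-linearly to log-parameter perturbations of this size.

The scale-factor sampler is also the pipeline's synthetic-population
generator: one master seed spawns one child stream per trial, so a
population can be extended without re-drawing earlier trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import engine, model_core
from .cell import StimulusProtocol, integrate_cell
from .pacing import APD_THRESHOLD, NoActionPotential, measure_apd, twice_threshold
from .params import PARAM_NAMES, ParameterSet

DEFAULT_SIGMA = 0.1
DEFAULT_TRIALS = 1000
MAX_FAILED_FRACTION = 0.05


@dataclass
class ScaleSample:
    """Lognormal parameter scale factors, trials x parameters."""

    scales: np.ndarray
    sigma: float
    seed: int
    names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        if self.scales.ndim != 2:
            raise ValueError("scales must be 2D (trials x parameters)")
        if np.any(self.scales <= 0):
            raise ValueError("scale factors must be strictly positive")

    @property
    def n_trials(self) -> int:
        return self.scales.shape[0]

    @property
    def n_params(self) -> int:
        return self.scales.shape[1]


def sample_scales(n_trials: int = DEFAULT_TRIALS, n_params: int = len(PARAM_NAMES),
                  sigma: float = DEFAULT_SIGMA, seed: int = 0) -> ScaleSample:
    """Draw the lognormal scale-factor matrix (median 1, log-SD sigma).

    Reproducible for a fixed seed; trial k always gets the same row
    regardless of n_trials (per-trial child streams).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    children = np.random.SeedSequence(seed).spawn(n_trials)
    scales = np.empty((n_trials, n_params))
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        scales[k] = np.exp(sigma * rng.standard_normal(n_params))
    return ScaleSample(scales=scales, sigma=sigma, seed=seed)


@dataclass
class PopulationResult:
    """APDs of a perturbed-parameter population."""

    sample: ScaleSample
    apds: np.ndarray            # ms; NaN where the trial failed to capture
    base: ParameterSet
    bcl: float
    pace_duration: float
    n_failed: int

    @property
    def ok(self) -> np.ndarray:
        return np.isfinite(self.apds)


def run_population(
    sample: ScaleSample,
    base: ParameterSet | None = None,
    bcl: float = 1000.0,
    pace_duration: float = 250_000.0,
    amplitude: float | None = None,
    dt: float = 0.02,
) -> PopulationResult:
    """Pace every trial's parameter set to steady state and measure APD.

    Trials that lose capture (no AP on the final beats) are recorded as
    NaN and excluded downstream; more than 5% failures aborts, since a
    regression over qualitatively different outputs is meaningless.
    The stimulus is twice the *base* model's threshold at this BCL,
    matching a fixed-amplitude experimental protocol across the
    population.
    """
    if base is None:
        base = ParameterSet()
    if amplitude is None:
        amplitude = twice_threshold(base, bcl)
    proto = StimulusProtocol(BCL=bcl, amplitude=amplitude)
    record_start = max(0.0, pace_duration - 2 * bcl - 100.0)
    state0 = model_core.initial_state()
    apds = np.full(sample.n_trials, np.nan)
    for k in range(sample.n_trials):
        params_k = base.scaled(sample.scales[k])
        tables = engine.build_tables(params_k, dt_levels=(dt,))
        trace = integrate_cell(state0, params_k, proto, t_end=pace_duration,
                               dt_out=0.5, record_start=record_start,
                               dt=dt, tables=tables)
        try:
            apds[k] = measure_apd(trace, APD_THRESHOLD).apd
        except NoActionPotential:
            pass
    n_failed = int(np.sum(~np.isfinite(apds)))
    if n_failed > MAX_FAILED_FRACTION * sample.n_trials:
        raise RuntimeError(
            f"{n_failed}/{sample.n_trials} trials failed to capture "
            f"(> {MAX_FAILED_FRACTION:.0%}); the population is not regressable"
        )
    if n_failed:
        warnings.warn(f"excluded {n_failed} failed-capture trials")
    return PopulationResult(sample=sample, apds=apds, base=base, bcl=bcl,
                            pace_duration=pace_duration, n_failed=n_failed)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Least-squares sensitivity coefficients B with X @ B ~ Y."""

    X: np.ndarray               # (n, p) regressors on the fitted scale
    Y: np.ndarray               # (n,)  response on the fitted scale
    B: np.ndarray               # (p,)
    r2: float
    names: tuple[str, ...] = PARAM_NAMES
    preprocessing: str = "zscore-log"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")

    def predicted(self) -> np.ndarray:
        return self.X @ self.B


def regress(X: np.ndarray, Y: np.ndarray, zscore_log: bool = True,
            names: tuple[str, ...] = PARAM_NAMES) -> SensitivityResult:
    """Least-squares fit of Y on X.

    With ``zscore_log`` (the convention for this method family) both the
    scale factors and the outputs are log-transformed and z-scored
    column-wise first, making B dimensionless and comparable across
    parameters; R^2 is computed on that same scale.  ``zscore_log=False``
    fits the raw matrices (an intercept column is appended).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != Y.size:
        raise ValueError("X rows must align with Y")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in X or Y")

    if zscore_log:
        lx = np.log(X)
        ly = np.log(Y)
        sx = lx.std(axis=0, ddof=0)
        sy = ly.std(ddof=0)
        if np.any(sx == 0) or sy == 0:
            raise ValueError("degenerate (zero-variance) column; cannot z-score")
        Xf = (lx - lx.mean(axis=0)) / sx
        Yf = (ly - ly.mean()) / sy
    else:
        Xf = np.column_stack([X, np.ones(X.shape[0])])
        Yf = Y

    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design matrix (rank {rank} < {Xf.shape[1]})"
        )
    B, *_ = np.linalg.lstsq(Xf, Yf, rcond=None)
    resid = Yf - Xf @ B
    ss_res = float(resid @ resid)
    ss_tot = float(((Yf - Yf.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if not zscore_log:
        B = B[:-1]  # drop the intercept from the reported coefficients
    return SensitivityResult(X=Xf[:, :len(B)], Y=Yf, B=B, r2=float(r2),
                             names=tuple(names)[:len(B)],
                             preprocessing="zscore-log" if zscore_log else "raw")


def regress_population(pop: PopulationResult, zscore_log: bool = True) -> SensitivityResult:
    """Convenience: regression over the non-failed trials of a population."""
    ok = pop.ok
    return regress(pop.sample.scales[ok], pop.apds[ok], zscore_log=zscore_log)


def rank_sensitivities(result: SensitivityResult) -> list[tuple[str, float]]:
    """Parameters ordered by |coefficient|, signs retained."""
    order = np.argsort(-np.abs(result.B))
    return [(result.names[i], float(result.B[i])) for i in order]
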