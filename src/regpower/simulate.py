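"""Synthetic data generation, the joint F test on data, and Monte Carlo power.

This module is the empirical counterpart of the analytic engine: it draws
predictors from their population distribution (predictors are random — the
premise of the whole exercise), draws responses from the regression model,
runs the joint intercept-slope F test on each replicate, and reports the
rejection proportion.  Agreement of that proportion with the analytic
power functions, within binomial noise, is the end-to-end validation of
the theory.

Non-normal predictor families are standardized affinely so every family
shares the requested mean and variance; only shape (skewness/kurtosis)
differs.  With E ~ Exponential(1), G ~ Gamma(2,1), L ~ Laplace(0,1),
U ~ Uniform(0,1), Z ~ N(0,1):

    exponential: X = mu + sigma (E - 1)
    gamma:       X = mu + sigma (G - 2) / sqrt(2)
    laplace:     X = mu + sigma L / sqrt(2)
    uniform:     X = mu + sigma sqrt(12) (U - 1/2)
    normal:      X = mu + sigma Z

Reproducibility: every routine takes a seed (or Generator).  Monte Carlo
power derives one independent child stream per replicate from the master
seed via ``numpy.random.SeedSequence.spawn``, so replicate k is
reproducible in isolation as ``SeedSequence(seed).spawn(k + 1)[k]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, SingularDesignError
from .power import QuadratureSpec, critical_value, power_approx, power_exact
from .samplesize import min_sample_size
from .specs import DesignSummary, EffectSpec, PredictorSpec

__all__ = [
    "TestResult",
    "SimulationResult",
    "StudyCell",
    "generate_predictors",
    "generate_responses",
    "joint_f_test",
    "simulate_power",
    "coefficient_shift_grid",
    "run_validation_study",
    "write_study_csv",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_predictors(
    predictor: PredictorSpec, n: int, seed=None
) -> np.ndarray:
    """Draw an n x p predictor matrix from the specified population.

    Multivariate draws (p > 1) are supported for the normal family only;
    the non-normal families are univariate by construction.
    """
    n = int(n)
    if n < 1:
        raise InputError(f"need n >= 1, got {n}")
    rng = _rng(seed)
    p = predictor.p
    if predictor.family == "normal":
        chol = np.linalg.cholesky(predictor.covariance)
        return predictor.mean + rng.standard_normal((n, p)) @ chol.T
    if p != 1:
        raise InputError(
            f"family {predictor.family!r} supports a single predictor only"
        )
    mu = float(predictor.mean[0])
    sigma = float(np.sqrt(predictor.covariance[0, 0]))
    if predictor.family == "exponential":
        x = mu + sigma * (rng.standard_exponential(n) - 1.0)
    elif predictor.family == "gamma":
        x = mu + sigma * (rng.gamma(2.0, 1.0, n) - 2.0) / np.sqrt(2.0)
    elif predictor.family == "laplace":
        x = mu + sigma * rng.laplace(0.0, 1.0, n) / np.sqrt(2.0)
    else:  # uniform
        x = mu + sigma * np.sqrt(12.0) * (rng.uniform(size=n) - 0.5)
    return x[:, None]


def generate_responses(
    true_effect: EffectSpec,
    predictors: np.ndarray,
    seed=None,
    error_variance: Optional[float] = None,
) -> np.ndarray:
    """Draw responses Y = beta_I + X beta_S + eps with iid N(0, sigma^2) errors.

    ``error_variance`` overrides the effect's sigma^2 and may be 0 — for
    testing only, where an exactly noiseless response is convenient.
    """
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[1] != true_effect.p:
        raise InputError(
            f"predictors have {x.shape[1]} columns but effect has p = {true_effect.p}"
        )
    rng = _rng(seed)
    s2 = true_effect.error_variance if error_variance is None else float(error_variance)
    if s2 < 0:
        raise InputError("error_variance must be >= 0")
    beta = true_effect.true_coefficients
    linear = beta[0] + x @ beta[1:]
    if s2 == 0.0:
        return linear
    return linear + rng.normal(0.0, np.sqrt(s2), x.shape[0])


@dataclass(frozen=True)
class TestResult:
    """Outcome of the joint intercept-slope F test on one data set."""

    coefficient_estimates: np.ndarray
    error_variance_estimate: float
    f_statistic: float
    numerator_df: int
    denominator_df: int
    p_value: float
    reject: bool
    alpha: float
    design_summary: DesignSummary
    covariance_factor: np.ndarray  # (X'X)^{-1}; sigma^2 times it is Cov(beta_hat)


def joint_f_test(
    predictors: np.ndarray,
    responses: np.ndarray,
    null_coefficients,
    alpha: float = 0.05,
) -> TestResult:
    """Likelihood-ratio F test that the full coefficient vector equals theta.

    Fits ordinary least squares and forms

        F = { (beta_hat - theta)' (X'X) (beta_hat - theta) / (p + 1) }
            / sigma_hat^2,

    rejected at level alpha when F exceeds the upper-alpha central F
    quantile with (p + 1, n - p - 1) degrees of freedom (strict
    inequality; ties have probability zero for continuous data).
    """
    x = np.atleast_2d(np.asarray(predictors, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    y = np.asarray(responses, dtype=float).ravel()
    n, p = x.shape
    if y.size != n:
        raise InputError(f"{n} predictor rows but {y.size} responses")
    theta = np.asarray(null_coefficients, dtype=float).ravel()
    if theta.size != p + 1:
        raise InputError(
            f"null_coefficients must have length p + 1 = {p + 1}, got {theta.size}"
        )
    if n <= p + 1:
        raise InputError(
            f"need n >= p + 2 = {p + 2} for a positive-df error estimate, got {n}"
        )
    xf = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(xf) < p + 1:
        raise SingularDesignError(
            "design matrix is rank deficient (constant or collinear predictors)"
        )
    gram = xf.T @ xf
    beta_hat = np.linalg.solve(gram, xf.T @ y)
    resid = y - xf @ beta_hat
    nu = n - p - 1
    sse = float(resid @ resid)
    sigma2_hat = sse / nu
    if sigma2_hat <= 0.0:
        raise InputError("zero residual variance: responses fit exactly")
    diff = beta_hat - theta
    f_stat = float(diff @ gram @ diff) / (p + 1) / sigma2_hat
    crit = critical_value(p + 1, nu, alpha)
    return TestResult(
        coefficient_estimates=beta_hat,
        error_variance_estimate=sigma2_hat,
        f_statistic=f_stat,
        numerator_df=p + 1,
        denominator_df=nu,
        p_value=float(stats.f.sf(f_stat, p + 1, nu)),
        reject=bool(f_stat > crit),
        alpha=float(alpha),
        design_summary=DesignSummary.from_predictors(x),
        covariance_factor=np.linalg.inv(gram),
    )


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo power estimate with its exact provenance."""

    replicates: int
    rejections: int
    empirical_power: float
    mc_standard_error: float
    seed: int
    config_echo: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.rejections <= self.replicates):
            raise InputError("rejections must lie in [0, replicates]")


def _batched_f_reject(
    x: np.ndarray, y: np.ndarray, theta: np.ndarray, crit: float
) -> np.ndarray:
    """Vectorised joint F test across replicates.

    x: (R, n, p); y: (R, n).  Same algebra as :func:`joint_f_test`, batched.
    """
    r, n, p = x.shape
    xf = np.concatenate([np.ones((r, n, 1)), x], axis=2)
    gram = np.einsum("rni,rnj->rij", xf, xf)
    xty = np.einsum("rni,rn->ri", xf, y)
    beta = np.linalg.solve(gram, xty[..., None])[..., 0]
    resid = y - np.einsum("rni,ri->rn", xf, beta)
    sse = np.einsum("rn,rn->r", resid, resid)
    # continuous data: SSX = 0 has probability zero; guard anyway
    if np.any(sse <= 0.0):
        raise SingularDesignError("degenerate replicate with zero residual variance")
    sigma2 = sse / (n - p - 1)
    diff = beta - theta
    qform = np.einsum("ri,rij,rj->r", diff, gram, diff)
    f_stat = qform / (p + 1) / sigma2
    return f_stat > crit


def simulate_power(
    true_effect: EffectSpec,
    null_coefficients,
    predictor: PredictorSpec,
    n: int,
    alpha: float = 0.05,
    replicates: int = 10_000,
    seed: int = 0,
) -> SimulationResult:
    """Empirical power of the joint test over fully regenerated data sets.

    Each replicate redraws both the predictors and the responses — the
    predictors are random, which is exactly what distinguishes the
    unconditional power functions from the conditional one.
    """
    replicates = int(replicates)
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    n = int(n)
    p = true_effect.p
    if n <= p + 1:
        raise InputError(f"need n >= p + 2 = {p + 2}, got {n}")
    theta = np.asarray(null_coefficients, dtype=float).ravel()
    if theta.size != p + 1:
        raise InputError(f"null_coefficients must have length {p + 1}")
    crit = critical_value(p + 1, n - p - 1, alpha)

    children = np.random.SeedSequence(seed).spawn(replicates)
    x = np.empty((replicates, n, p))
    y = np.empty((replicates, n))
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        xk = generate_predictors(predictor, n, rng)
        x[k] = xk
        y[k] = generate_responses(true_effect, xk, rng)
    rejections = int(np.sum(_batched_f_reject(x, y, theta, crit)))

    phat = rejections / replicates
    return SimulationResult(
        replicates=replicates,
        rejections=rejections,
        empirical_power=phat,
        mc_standard_error=float(np.sqrt(phat * (1.0 - phat) / replicates)),
        seed=int(seed),
        config_echo={
            "true_coefficients": true_effect.true_coefficients.tolist(),
            "null_coefficients": theta.tolist(),
            "error_variance": true_effect.error_variance,
            "predictor_mean": predictor.mean.tolist(),
            "predictor_covariance": predictor.covariance.tolist(),
            "family": predictor.family,
            "n": n,
            "alpha": float(alpha),
        },
    )


@dataclass(frozen=True)
class StudyCell:
    """One configuration of a validation-study grid."""

    effect: EffectSpec
    predictor: PredictorSpec
    alpha: float = 0.05
    target_power: float = 0.90


def coefficient_shift_grid(
    d: float = 0.3,
    mus: Sequence[float] = (0.0, 0.5, 1.0),
    variances: Sequence[float] = (0.5, 1.0, 2.0),
    family: str = "normal",
    null_coefficients: Sequence[float] = (0.0, 1.0),
    error_variance: float = 1.0,
    alpha: float = 0.05,
    target_power: float = 0.90,
) -> list[StudyCell]:
    """Benchmark grid: both coefficients shifted by d off the null (0, 1).

    True coefficients (d, 1 + d) against null (0, 1), sigma^2 = 1, crossed
    over predictor means and variances — the standard nine-cell layout
    used to compare exact and approximate power at a 0.90 target.
    """
    b0, b1 = null_coefficients
    effect = EffectSpec.simple(b0 + d, b1 + d, b0, b1, error_variance)
    return [
        StudyCell(
            effect=effect,
            predictor=PredictorSpec.simple(mu, var, family),
            alpha=alpha,
            target_power=target_power,
        )
        for mu in mus
        for var in variances
    ]


def run_validation_study(
    grid: Iterable[StudyCell],
    replicates: int = 10_000,
    seed: int = 0,
    quad: Optional[QuadratureSpec] = None,
) -> pd.DataFrame:
    """Exact-vs-approximate-vs-simulated power over a configuration grid.

    For each cell: find the exact method's minimal N for the cell's target
    power, evaluate both analytic power functions at that N, and estimate
    empirical power by Monte Carlo at the same N.  Errors are analytic
    estimate minus simulated power.  The N and analytic columns are
    deterministic — independent of the seed.
    """
    grid = list(grid)
    cell_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for cell, cell_seed in zip(grid, cell_seeds):
        ss = min_sample_size(
            cell.effect, cell.predictor, cell.alpha, cell.target_power,
            method="exact", quad=quad,
        )
        exact = power_exact(cell.effect, cell.predictor, ss.n, cell.alpha, quad).power
        approx = power_approx(cell.effect, cell.predictor, ss.n, cell.alpha).power
        sim = simulate_power(
            cell.effect, cell.effect.null_coefficients, cell.predictor,
            ss.n, cell.alpha, replicates,
            seed=int(cell_seed.generate_state(1, np.uint32)[0]),
        )
        diff = cell.effect.difference
        rows.append(
            {
                "mu_x": float(cell.predictor.mean[0]),
                "sigma2_x": float(cell.predictor.covariance[0, 0]),
                "family": cell.predictor.family,
                "d": float(diff[1]) if cell.effect.p == 1 else float("nan"),
                "n": ss.n,
                "power_simulated": sim.empirical_power,
                "power_exact": exact,
                "error_exact": exact - sim.empirical_power,
                "power_approx": approx,
                "error_approx": approx - sim.empirical_power,
            }
        )
    return pd.DataFrame(rows)


def write_study_csv(
    table: pd.DataFrame, path, full_precision: bool = False
) -> None:
    """Write a validation table as CSV (4-decimal display by default)."""
    if full_precision:
        table.to_csv(path, index=False)
    else:
        table.to_csv(path, index=False, float_format="%.4f")
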