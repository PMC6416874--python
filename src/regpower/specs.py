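"""Study-configuration types and noncentrality computations.

A validation study of a linear regression formula is described by three
ingredients:

* an :class:`EffectSpec` — the true coefficient vector ``(beta_I, beta_S)``,
  the hypothesised (null) vector, and the error variance ``sigma^2``;
* a :class:`PredictorSpec` — the population mean and covariance of the
  stochastic predictors, plus the distribution family used for simulation;
* optionally a :class:`DesignSummary` — the observed predictor summaries
  (mean and centred scatter matrix) when power conditional on a realised
  design is wanted.

The joint F test of intercept and slopes has a noncentral F distribution
whose noncentrality

    Delta = { N (beta_ID + beta_SD' xbar)^2 + beta_SD' A beta_SD } / sigma^2

depends on the predictors only through ``xbar`` and the scatter ``A``.
Under normal predictors, ``xbar`` and ``A`` are independent with normal and
Wishart distributions, so Delta admits the two-stage representation

    Delta = { N (a + b Z)^2 + d K } / sigma^2,
    Z ~ N(0, 1),  K ~ chi^2(N - 1),

with ``a = beta_ID + beta_SD' mu_X``, ``d = beta_SD' Sigma_X beta_SD`` and
``b = sqrt(d / N)``.  :func:`mixture_representation` computes these mixing
parameters; the power engine integrates over (Z, K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import InputError, UnsupportedMethodError

__all__ = [
    "PREDICTOR_FAMILIES",
    "EffectSpec",
    "PredictorSpec",
    "DesignSummary",
    "MixtureRepresentation",
    "conditional_noncentrality",
    "asymptotic_effect_size",
    "mixture_representation",
]

#: Predictor distribution families the simulator can draw from.  Analytic
#: power methods are derived under normality and accept only ``"normal"``.
PREDICTOR_FAMILIES = ("normal", "exponential", "gamma", "laplace", "uniform")

_SYMMETRY_TOL = 1e-10


def _as_vector(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise InputError(f"{name} must be a 1-D vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise InputError(f"{name} must be finite")
    return v


def _as_matrix(x, name: str) -> np.ndarray:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError(f"{name} must be a square matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InputError(f"{name} must be finite")
    return m


@dataclass(frozen=True)
class EffectSpec:
    """True and hypothesised regression coefficients plus error variance.

    Coefficient vectors are ordered intercept first: ``(beta_I, beta_1, ...,
    beta_p)``.  The coefficient differences are always derived from the two
    stored vectors, never stored separately.

    Parameters
    ----------
    true_coefficients, null_coefficients : array-like, shape (p + 1,)
        Alternative-hypothesis and null-hypothesis coefficient vectors.
    error_variance : float
        Residual variance sigma^2 (> 0).  A variance, not a standard
        deviation.
    """

    true_coefficients: np.ndarray
    null_coefficients: np.ndarray
    error_variance: float

    def __post_init__(self):
        true = _as_vector(self.true_coefficients, "true_coefficients")
        null = _as_vector(self.null_coefficients, "null_coefficients")
        if true.shape != null.shape:
            raise InputError(
                "true_coefficients and null_coefficients must have the same "
                f"length, got {true.size} and {null.size}"
            )
        if true.size < 2:
            raise InputError("need an intercept and at least one slope (p >= 1)")
        sigma2 = float(self.error_variance)
        if not (np.isfinite(sigma2) and sigma2 > 0):
            raise InputError(f"error_variance must be > 0, got {sigma2}")
        true.setflags(write=False)
        null.setflags(write=False)
        object.__setattr__(self, "true_coefficients", true)
        object.__setattr__(self, "null_coefficients", null)
        object.__setattr__(self, "error_variance", sigma2)

    @classmethod
    def simple(
        cls,
        intercept: float,
        slope: float,
        null_intercept: float,
        null_slope: float,
        error_variance: float,
    ) -> "EffectSpec":
        """Scalar constructor for simple linear regression (p = 1)."""
        return cls([intercept, slope], [null_intercept, null_slope], error_variance)

    @property
    def p(self) -> int:
        """Number of slope predictors."""
        return self.true_coefficients.size - 1

    @property
    def difference(self) -> np.ndarray:
        """Coefficient difference vector (beta_ID, beta_SD) = true - null."""
        return self.true_coefficients - self.null_coefficients

    @property
    def intercept_difference(self) -> float:
        return float(self.difference[0])

    @property
    def slope_difference(self) -> np.ndarray:
        return self.difference[1:]

    @property
    def is_null(self) -> bool:
        """True when the true coefficients equal the null values exactly."""
        return bool(np.all(self.difference == 0.0))


@dataclass(frozen=True)
class PredictorSpec:
    """Population distribution of the stochastic predictors.

    Parameters
    ----------
    mean : array-like, shape (p,)
        Predictor mean vector mu_X.
    covariance : array-like, shape (p, p)
        Predictor covariance Sigma_X; must be symmetric positive definite.
        A scalar is accepted for p = 1.
    family : str
        Distribution family used by the simulator; one of
        ``normal | exponential | gamma | laplace | uniform``.  Analytic
        power functions require ``"normal"``.
    """

    mean: np.ndarray
    covariance: np.ndarray
    family: str = "normal"

    def __post_init__(self):
        mean = _as_vector(self.mean, "mean")
        cov = _as_matrix(self.covariance, "covariance")
        if cov.shape != (mean.size, mean.size):
            raise InputError(
                f"covariance shape {cov.shape} does not match mean length {mean.size}"
            )
        scale = max(1.0, float(np.max(np.abs(cov))))
        if np.max(np.abs(cov - cov.T)) > _SYMMETRY_TOL * scale:
            raise InputError("covariance must be symmetric (tolerance 1e-10)")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise InputError("covariance must be positive definite") from None
        if self.family not in PREDICTOR_FAMILIES:
            raise InputError(
                f"unknown predictor family {self.family!r}; "
                f"choose from {PREDICTOR_FAMILIES}"
            )
        mean.setflags(write=False)
        cov.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @classmethod
    def simple(
        cls, mean: float, variance: float, family: str = "normal"
    ) -> "PredictorSpec":
        """Scalar constructor for a single predictor (p = 1)."""
        return cls([mean], [[variance]], family)

    @property
    def p(self) -> int:
        return self.mean.size

    def require_normal(self, context: str) -> None:
        """Raise unless the family is normal (analytic methods only)."""
        if self.family != "normal":
            raise UnsupportedMethodError(
                f"{context} is derived under normal predictors; "
                f"got family {self.family!r} (use the simulation module instead)"
            )


@dataclass(frozen=True)
class DesignSummary:
    """Observed predictor summaries for power conditional on a design.

    ``xbar`` is the predictor sample mean and ``scatter`` the centred
    cross-product matrix A = sum_i (X_i - xbar)(X_i - xbar)' (the scalar SSX
    when p = 1).  These two statistics are all the joint F test's nonnull
    distribution depends on.
    """

    xbar: np.ndarray
    scatter: np.ndarray
    n: int

    def __post_init__(self):
        xbar = _as_vector(self.xbar, "xbar")
        scatter = _as_matrix(self.scatter, "scatter")
        p = xbar.size
        if scatter.shape != (p, p):
            raise InputError(
                f"scatter shape {scatter.shape} does not match xbar length {p}"
            )
        scale = max(1.0, float(np.max(np.abs(scatter))))
        if np.max(np.abs(scatter - scatter.T)) > _SYMMETRY_TOL * scale:
            raise InputError("scatter must be symmetric")
        if np.min(np.linalg.eigvalsh(scatter)) < -_SYMMETRY_TOL * scale:
            raise InputError("scatter must be positive semi-definite")
        n = int(self.n)
        if n < p + 2:
            raise InputError(f"need n >= p + 2 = {p + 2}, got n = {n}")
        xbar.setflags(write=False)
        scatter.setflags(write=False)
        object.__setattr__(self, "xbar", xbar)
        object.__setattr__(self, "scatter", scatter)
        object.__setattr__(self, "n", n)

    @classmethod
    def simple(cls, xbar: float, ssx: float, n: int) -> "DesignSummary":
        """Scalar constructor (p = 1) from xbar and SSX."""
        return cls([xbar], [[ssx]], n)

    @classmethod
    def from_predictors(cls, predictors: np.ndarray) -> "DesignSummary":
        """Summarise an observed n x p predictor matrix."""
        x = np.atleast_2d(np.asarray(predictors, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1:
            x = x.T
        xbar = x.mean(axis=0)
        centred = x - xbar
        return cls(xbar, centred.T @ centred, x.shape[0])

    @property
    def p(self) -> int:
        return self.xbar.size


@dataclass(frozen=True)
class MixtureRepresentation:
    """Mixing parameters of the two-stage noncentrality representation.

    ``Delta = {N (a + b Z)^2 + d K} / sigma^2`` with Z ~ N(0,1) and
    K ~ chi^2(kappa).  ``a`` collects the mean-level discrepancy,
    ``d = beta_SD' Sigma_X beta_SD`` the slope discrepancy weighted by the
    predictor covariance, and ``b = sqrt(d / N)`` the standard deviation of
    the mean-level term induced by the randomness of xbar.
    """

    a: float
    b: float
    d: float
    kappa: int
    nu: int
    n: int
    error_variance: float

    def __post_init__(self):
        if self.d < 0:
            raise InputError("d must be nonnegative")
        if abs(self.b * self.b * self.n - self.d) > 1e-12 * max(1.0, self.d):
            raise InputError("b^2 * n must equal d")
        if self.kappa != self.n - 1:
            raise InputError("kappa must equal n - 1")
        if self.nu < 1:
            raise InputError("residual degrees of freedom nu must be >= 1")

    def noncentrality(self, z: float, k: float) -> float:
        """Evaluate Delta at given values of the mixing variables."""
        return (self.n * (self.a + self.b * z) ** 2 + self.d * k) / self.error_variance


def _check_dims(effect: EffectSpec, p_other: int, what: str) -> None:
    if effect.p != p_other:
        raise InputError(
            f"effect has p = {effect.p} slopes but {what} has p = {p_other}"
        )


def conditional_noncentrality(effect: EffectSpec, design: DesignSummary) -> float:
    """Noncentrality of the joint F test given observed predictor summaries.

    Returns ``{N (beta_ID + beta_SD' xbar)^2 + beta_SD' A beta_SD} /
    sigma^2`` — nonnegative, and zero iff both the mean-level and the
    slope-scatter terms vanish.
    """
    _check_dims(effect, design.p, "design")
    bid = effect.intercept_difference
    bsd = effect.slope_difference
    level = bid + float(bsd @ design.xbar)
    quad = float(bsd @ design.scatter @ bsd)
    return (design.n * level * level + quad) / effect.error_variance


def asymptotic_effect_size(
    effect: EffectSpec, predictor: PredictorSpec
) -> tuple[float, float]:
    """Per-observation effect sizes (exact, approximate).

    The exact value is the large-N limit of Delta / N,

        Delta*_J = { (beta_ID + beta_SD' mu_X)^2 + beta_SD' Sigma_X beta_SD }
                   / sigma^2,

    a convenient single-number summary of detectability per observation.
    The approximate (mean-substitution) counterpart drops the covariance
    term:  Delta*_C = (beta_ID + beta_SD' mu_X)^2 / sigma^2.  Always
    Delta*_C <= Delta*_J, with equality iff beta_SD' Sigma_X beta_SD = 0.
    """
    _check_dims(effect, predictor.p, "predictor")
    bid = effect.intercept_difference
    bsd = effect.slope_difference
    a = bid + float(bsd @ predictor.mean)
    d = float(bsd @ predictor.covariance @ bsd)
    exact = (a * a + d) / effect.error_variance
    approx = a * a / effect.error_variance
    return exact, approx


def mixture_representation(
    effect: EffectSpec, predictor: PredictorSpec, n: int
) -> MixtureRepresentation:
    """Mixing parameters (a, b, d, kappa, nu) at sample size n.

    Valid only for normal predictors — the normal/Wishart distribution of
    (xbar, A) is what turns the random noncentrality into the (Z, K)
    mixture.
    """
    _check_dims(effect, predictor.p, "predictor")
    predictor.require_normal("the two-stage mixture representation")
    n = int(n)
    if n < effect.p + 2:
        raise InputError(f"need n >= p + 2 = {effect.p + 2}, got n = {n}")
    bid = effect.intercept_difference
    bsd = effect.slope_difference
    a = bid + float(bsd @ predictor.mean)
    d = float(bsd @ predictor.covariance @ bsd)
    d = max(d, 0.0)  # guard roundoff for tiny quadratic forms
    return MixtureRepresentation(
        a=a,
        b=float(np.sqrt(d / n)),
        d=d,
        kappa=n - 1,
        nu=n - effect.p - 1,
        n=n,
        error_variance=effect.error_variance,
    )
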