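"""The delta-gamma (zero-inflated gamma) model.

A delta-gamma variable is 0 with probability ``delta`` and otherwise a
gamma(shape, scale) variate; we write it Δ(δ, α, β).  Its variance

    τ = (1 − δ)·αβ² + δ(1 − δ)·(αβ)²

is the estimand of every interval method in this package.  This module
holds the distribution itself (moments, sampling, closed-form approximate
MLEs) and the cube-root normal approximation: the cube root of a
gamma(a, b) variate is approximately normal with

    μ = (ba)^{1/3} (1 − 1/(9a)),    σ² = b^{2/3} / (9 a^{1/3}),

together with the inverse maps that recover the gamma shape, scale, mean
a·b and variance a·b² from (μ, σ²).  Every downstream interval (fiducial,
bootstrap, Bayesian) pushes pivots or posterior draws of (μ, σ²) through
these maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSampleError, InsufficientPositivesError

__all__ = [
    "GammaParams",
    "DeltaGammaParams",
    "ZeroInflatedSample",
    "CubeRootSummary",
    "MleEstimates",
    "as_rng",
    "dg_mean",
    "dg_variance",
    "dg_sample",
    "mle_fit",
    "cube_root_moments",
    "shape_from_moments",
    "scale_from_moments",
    "gamma_mean_from_moments",
    "gamma_variance_from_moments",
]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Return a numpy Generator from a seed, Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GammaParams:
    """Gamma distribution in the shape/scale parameterization.

    The rate view (1/scale) is derived; internally everything is
    shape+scale so that moments are unambiguous.
    """

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError(
                f"gamma shape and scale must be positive, got "
                f"shape={self.shape}, scale={self.scale}"
            )

    @property
    def rate(self) -> float:
        return 1.0 / self.scale

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    @classmethod
    def from_rate(cls, shape: float, rate: float) -> "GammaParams":
        return cls(shape=shape, scale=1.0 / rate)


@dataclass(frozen=True)
class DeltaGammaParams:
    """Δ(δ, α, β): zero with probability ``delta``, else gamma."""

    delta: float
    gamma: GammaParams

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError(f"delta must lie in [0, 1), got {self.delta}")

    @property
    def mean(self) -> float:
        return dg_mean(self)

    @property
    def variance(self) -> float:
        return dg_variance(self)

    # alias used throughout the interval modules
    @property
    def tau(self) -> float:
        return dg_variance(self)


def dg_mean(params: DeltaGammaParams) -> float:
    """E X = (1 − δ)·αβ for X ~ Δ(δ, α, β)."""
    return (1.0 - params.delta) * params.gamma.mean


def dg_variance(params: DeltaGammaParams) -> float:
    """Var X = τ = (1 − δ)·αβ² + δ(1 − δ)·(αβ)²."""
    d = params.delta
    return (1.0 - d) * params.gamma.variance + d * (1.0 - d) * params.gamma.mean**2


class ZeroInflatedSample:
    """A sample of nonnegative reals with exact zeros kept significant.

    Parameters
    ----------
    values : array-like of float
        Observations; each must be >= 0.  Order is preserved.
    """

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1:
            raise ValueError("sample must be one-dimensional")
        if values.size == 0:
            raise ValueError("sample must be nonempty")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("sample values must be finite and nonnegative")
        self.values = values

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n0(self) -> int:
        return int(np.count_nonzero(self.values == 0.0))

    @property
    def n1(self) -> int:
        return self.n - self.n0

    @property
    def positives(self) -> np.ndarray:
        return self.values[self.values > 0.0]

    def cube_root_summary(self) -> "CubeRootSummary":
        """Mean and variance of the cube-root-transformed positives.

        Raises
        ------
        InsufficientPositivesError
            If fewer than two positive observations are present.
        """
        if self.n1 < 2:
            raise InsufficientPositivesError(
                f"need at least 2 positive observations, got n1={self.n1}"
            )
        x = np.cbrt(self.positives)
        return CubeRootSummary(
            xbar=float(np.mean(x)), s2=float(np.var(x, ddof=1)), n1=self.n1
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ZeroInflatedSample(n={self.n}, n0={self.n0}, n1={self.n1})"


@dataclass(frozen=True)
class CubeRootSummary:
    """Sufficient summary of the cube-root-transformed positive values.

    ``s2`` uses the n1−1 denominator, matching the (n1−1)s²/χ² pivot.
    """

    xbar: float
    s2: float
    n1: int


@dataclass(frozen=True)
class MleEstimates:
    """Closed-form approximate MLEs for Δ(δ, α, β).

    ``rate_hat`` is the rate-convention β̂ = α̂/x̄₊; the scale view is
    1/rate_hat.  The implied gamma mean α̂/β̂ equals the positive-part
    sample mean by construction.
    """

    delta_hat: float
    alpha_hat: float
    rate_hat: float
    tau_hat: float

    @property
    def scale_hat(self) -> float:
        return 1.0 / self.rate_hat

    @property
    def gamma_mean_hat(self) -> float:
        return self.alpha_hat / self.rate_hat

    @property
    def gamma_variance_hat(self) -> float:
        return self.alpha_hat / self.rate_hat**2


def dg_sample(
    params: DeltaGammaParams, n: int, seed: int | np.random.Generator | None = None
) -> ZeroInflatedSample:
    """Draw n observations from Δ(δ, α, β).

    Each observation is 0 with probability δ, else gamma(shape, scale),
    so the zero count is Binomial(n, δ).  Identical seeds yield identical
    samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    zero = rng.random(n) < params.delta
    values = rng.gamma(params.gamma.shape, params.gamma.scale, size=n)
    values[zero] = 0.0
    return ZeroInflatedSample(values)


def mle_fit(sample: ZeroInflatedSample) -> MleEstimates:
    """Closed-form delta-gamma MLEs.

    δ̂ = n0/n; on the positives, α̂ = 0.5/(log x̄ − mean log x) (a
    first-order approximation to the gamma likelihood equations) and
    β̂ = α̂/x̄ (rate).  τ̂ plugs these into the delta-gamma variance.
    """
    if sample.n1 < 2:
        raise InsufficientPositivesError(
            f"need at least 2 positive observations, got n1={sample.n1}"
        )
    pos = sample.positives
    xbar = float(np.mean(pos))
    denom = float(np.log(xbar) - np.mean(np.log(pos)))
    if denom <= 0.0:
        raise DegenerateSampleError(
            "all positive observations are (numerically) equal; "
            "the shape estimate diverges"
        )
    delta_hat = sample.n0 / sample.n
    alpha_hat = 0.5 / denom
    rate_hat = alpha_hat / xbar
    gamma_mean = xbar
    gamma_var = xbar**2 / alpha_hat
    tau_hat = (1.0 - delta_hat) * gamma_var + delta_hat * (1.0 - delta_hat) * gamma_mean**2
    return MleEstimates(
        delta_hat=delta_hat, alpha_hat=alpha_hat, rate_hat=rate_hat, tau_hat=tau_hat
    )


# ---------------------------------------------------------------------------
# Cube-root (Wilson-Hilferty) normal approximation and its inverse maps.
# All maps are vectorized: scalar or ndarray (μ, σ²) inputs are accepted.
# ---------------------------------------------------------------------------


def cube_root_moments(g: GammaParams) -> tuple[float, float]:
    """Normal-approximation mean and variance of a gamma variate's cube root."""
    a, b = g.shape, g.scale
    mu = (b * a) ** (1.0 / 3.0) * (1.0 - 1.0 / (9.0 * a))
    sigma2 = b ** (2.0 / 3.0) / (9.0 * a ** (1.0 / 3.0))
    return mu, sigma2


def _check_sigma2(sigma2) -> None:
    if np.any(np.asarray(sigma2) <= 0.0):
        raise ValueError("sigma2 must be positive")


def shape_from_moments(mu, sigma2):
    """Gamma shape implied by cube-root moments (μ, σ²).

    a = (1/9)·{ (1 + ½μ²/σ²) + [ (1 + ½μ²/σ²)² − 1 ]^{1/2} }.
    """
    _check_sigma2(sigma2)
    t = 1.0 + 0.5 * np.square(mu) / np.asarray(sigma2, dtype=float)
    return (t + np.sqrt(np.square(t) - 1.0)) / 9.0


def scale_from_moments(shape, sigma2):
    """Gamma scale implied by (shape, σ²): b = 27·a^{1/2}·(σ²)^{3/2}."""
    _check_sigma2(sigma2)
    if np.any(np.asarray(shape) <= 0.0):
        raise ValueError("shape must be positive")
    return 27.0 * np.sqrt(shape) * np.power(sigma2, 1.5)


def gamma_mean_from_moments(mu, sigma2):
    """Gamma mean a·b implied by cube-root moments.

    M = { μ/2 + √((μ/2)² + σ²) }³.  Defined for any real μ (draws of μ
    may be negative); always positive.
    """
    _check_sigma2(sigma2)
    half = np.asarray(mu, dtype=float) / 2.0
    return np.power(half + np.sqrt(np.square(half) + sigma2), 3)


def gamma_variance_from_moments(mu, sigma2):
    """Gamma variance a·b² implied by cube-root moments.

    V = { (μ + √(μ² + 4σ²)) / (2·9^{−1/4}·(σ²)^{−1/4}) }⁴, i.e.
    9σ²·((μ + √(μ² + 4σ²))/2)⁴; always positive.
    """
    _check_sigma2(sigma2)
    mu = np.asarray(mu, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    root = np.sqrt(np.square(mu) + 4.0 * s2)
    return 9.0 * s2 * np.power((mu + root) / 2.0, 4)
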