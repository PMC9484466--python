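"""Bayesian credible and HPD intervals for the delta-gamma variance.

Three priors are supported, each inducing conjugate-style marginal
posteriors for (δ, σ², μ) on the cube-root scale (counts n0 zeros, n1
positives; x̄, s² the cube-root positive-part mean and variance):

========  ========================  ==============================  =================================
prior     δ | x                     σ² | x                          μ | x
========  ========================  ==============================  =================================
jeffreys  Beta(n0+1/2, n1+3/2)      IG(n1/2, (n1−1)s²/2)            N(x̄, σ²/n1) given each σ² draw
uniform   Beta(n0+1, n1+1)          IG((n1−2)/2, (n1−1)s²/2)        N(x̄, σ²/n1) given each σ² draw
ngb       Beta(n0+1/2, n1+1/2)      IG((n1−1)/2, (n1−1)s²/2)        t_{2(n1−1)}(x̄, s²/n1), independent
========  ========================  ==============================  =================================

The unknown μ in the inverse-gamma scale is replaced by x̄, so every
posterior is sampled in one pass (no Gibbs iteration).  The normal-gamma-
beta (ngb) prior p ∝ λ^{−1}[δ(1−δ)]^{−1/2} (λ = 1/σ²) yields the
location-scale t marginal for μ, drawn independently of σ².  Each
(δ, σ², μ) draw maps through the cube-root inverse maps to a τ draw

    τ = (1 − δ)·V(μ, σ²) + δ(1 − δ)·M(μ, σ²)²,

from which equal-tail (BAY-*) and highest-posterior-density (HPD-*)
intervals are cut.

Note the Jeffreys δ posterior is Beta(n0+1/2, n1+3/2) rather than the
textbook Beta(n0+1/2, n1+1/2); the prior here carries a +1/2 exponent on
(1−δ).  The uniform prior on σ² needs n1 ≥ 3 for a proper posterior.
"""

from __future__ import annotations

import numpy as np

from .core import (
    CubeRootSummary,
    ZeroInflatedSample,
    as_rng,
    gamma_mean_from_moments,
    gamma_variance_from_moments,
)
from .errors import PriorInapplicableError
from .intervals import IntervalEstimate, TauDraws, equal_tail_interval, hpd_interval

__all__ = [
    "PRIORS",
    "posterior_delta_draws",
    "posterior_sigma2_draws",
    "posterior_mu_draws",
    "bayes_tau_draws",
    "bayes_interval",
]

PRIORS = ("jeffreys", "uniform", "ngb")

# (beta offsets for the delta posterior, inverse-gamma shape offset, min n1)
_DELTA_PARAMS = {
    "jeffreys": (0.5, 1.5),
    "uniform": (1.0, 1.0),
    "ngb": (0.5, 0.5),
}
_IG_SHAPE_OFFSET = {"jeffreys": 0, "uniform": 2, "ngb": 1}
_MIN_N1 = {"jeffreys": 2, "uniform": 3, "ngb": 2}


def _check_prior(prior: str) -> None:
    if prior not in PRIORS:
        raise ValueError(f"unknown prior {prior!r}; expected one of {PRIORS}")


def min_n1(prior: str) -> int:
    """Smallest positive count at which the prior's posteriors are proper."""
    _check_prior(prior)
    return _MIN_N1[prior]


def posterior_delta_draws(prior: str, n0: int, n1: int, m: int, seed=None) -> np.ndarray:
    """Beta posterior draws of the zero probability δ."""
    _check_prior(prior)
    if n0 < 0 or n1 < 0 or n0 + n1 == 0:
        raise ValueError("counts must be nonnegative and not both zero")
    a_off, b_off = _DELTA_PARAMS[prior]
    return as_rng(seed).beta(n0 + a_off, n1 + b_off, size=m)


def posterior_sigma2_draws(
    prior: str, summary: CubeRootSummary, m: int, seed=None
) -> np.ndarray:
    """Inverse-gamma posterior draws of the cube-root-scale variance σ²."""
    _check_prior(prior)
    n1 = summary.n1
    shape = (n1 - _IG_SHAPE_OFFSET[prior]) / 2.0
    if shape <= 0:
        raise PriorInapplicableError(
            f"{prior} prior needs n1 >= {_MIN_N1[prior]} positives, got {n1}"
        )
    if summary.s2 <= 0.0:
        raise ValueError("cube-root sample variance must be positive")
    scale = (n1 - 1) * summary.s2 / 2.0
    return scale / as_rng(seed).gamma(shape, 1.0, size=m)


def posterior_mu_draws(
    prior: str,
    summary: CubeRootSummary,
    m: int,
    seed=None,
    sigma2_draws: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior draws of the cube-root-scale mean μ.

    Jeffreys/uniform draw μ | σ² ~ N(x̄, σ²/n1) paired with the supplied
    σ² draws; ngb draws the t_{2(n1−1)} marginal with squared scale s²/n1,
    independent of σ².
    """
    _check_prior(prior)
    rng = as_rng(seed)
    n1, xbar = summary.n1, summary.xbar
    if prior == "ngb":
        df = 2 * (n1 - 1)
        if df <= 0:
            raise PriorInapplicableError(f"ngb prior needs n1 >= 2, got {n1}")
        return xbar + np.sqrt(summary.s2 / n1) * rng.standard_t(df, size=m)
    if sigma2_draws is None:
        raise ValueError(f"{prior} prior draws mu conditionally: pass sigma2_draws")
    if len(sigma2_draws) != m:
        raise ValueError("sigma2_draws length must equal m")
    return xbar + np.sqrt(np.asarray(sigma2_draws) / n1) * rng.standard_normal(m)


def bayes_tau_draws(
    prior: str, sample: ZeroInflatedSample, m: int = 5000, seed=None
) -> TauDraws:
    """m posterior draws of τ under the given prior."""
    _check_prior(prior)
    rng = as_rng(seed)
    summary = sample.cube_root_summary()
    if summary.n1 < _MIN_N1[prior]:
        raise PriorInapplicableError(
            f"{prior} prior needs n1 >= {_MIN_N1[prior]} positives, got {summary.n1}"
        )
    delta = posterior_delta_draws(prior, sample.n0, sample.n1, m, rng)
    sigma2 = posterior_sigma2_draws(prior, summary, m, rng)
    mu = posterior_mu_draws(prior, summary, m, rng, sigma2_draws=sigma2)
    big_m = gamma_mean_from_moments(mu, sigma2)
    big_v = gamma_variance_from_moments(mu, sigma2)
    tau = (1.0 - delta) * big_v + delta * (1.0 - delta) * np.square(big_m)
    return TauDraws(tau, method=f"bay-{_short(prior)}")


def bayes_interval(
    prior: str,
    sample: ZeroInflatedSample,
    level: float = 0.95,
    m: int = 5000,
    seed=None,
    flavor: str = "equal-tail",
) -> IntervalEstimate:
    """Credible (equal-tail) or HPD interval for τ under the given prior."""
    draws = bayes_tau_draws(prior, sample, m, seed)
    if flavor == "equal-tail":
        return equal_tail_interval(draws, level)
    if flavor == "hpd":
        return hpd_interval(draws, level, method=f"hpd-{_short(prior)}")
    raise ValueError(f"unknown flavor {flavor!r}; expected 'equal-tail' or 'hpd'")


def _short(prior: str) -> str:
    return {"jeffreys": "j", "uniform": "u", "ngb": "ngb"}[prior]
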