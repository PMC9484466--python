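"""Fiducial-quantity (FQ) interval for the delta-gamma variance τ.

The construction transfers the classical normal-theory pivots to the gamma
part through the cube-root approximation: with x̄, s² the mean and variance
of the cube-root-transformed positives (count n1),

    Q_σ² = (n1 − 1)s² / χ²_{n1−1}
    Q_μ  = x̄ + Z·√(n1 − 1)/√(χ²_{n1−1}) · s/√n1

with Z ⟂ χ² and the *same* χ² draw entering both members of a pair.  The
zero probability gets its own fiducial distribution, an equal-weight
two-component beta mixture in the zero/positive counts.  Each (Q_μ, Q_σ²,
Q_δ) triple maps to a τ draw

    Q_τ = (1 − Q_δ)·Q_V + Q_δ(1 − Q_δ)·Q_M²

and the interval is the equal-tail percentile cut of the Q_τ vector.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ZeroInflatedSample,
    CubeRootSummary,
    as_rng,
    gamma_mean_from_moments,
    gamma_variance_from_moments,
)
from .errors import BoundaryCountError, DegenerateSampleError
from .intervals import IntervalEstimate, TauDraws, equal_tail_interval

__all__ = ["fq_mu_sigma2_draws", "fq_delta_draws", "fq_tau_draws", "fq_interval"]


def fq_mu_sigma2_draws(
    summary: CubeRootSummary, m: int, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Paired fiducial draws (Q_μ, Q_σ²) from the cube-root summary."""
    if summary.s2 <= 0.0:
        raise DegenerateSampleError("cube-root sample variance is zero")
    rng = as_rng(seed)
    n1, s2 = summary.n1, summary.s2
    chi2 = rng.chisquare(n1 - 1, size=m)
    z = rng.standard_normal(m)
    sigma2 = (n1 - 1) * s2 / chi2
    mu = summary.xbar + z * np.sqrt((n1 - 1) / chi2) * np.sqrt(s2 / n1)
    return mu, sigma2


def fq_delta_draws(
    n0: int,
    n1: int,
    m: int,
    seed=None,
    orientation: str = "zero",
    boundary: str = "raise",
) -> np.ndarray:
    """Fiducial draws of the zero probability δ.

    The default ``orientation="zero"`` samples the equal-weight mixture
    ½·Beta(n0, n1+1) + ½·Beta(n0+1, n1), which concentrates near n0/n.
    ``orientation="printed"`` swaps the roles of the counts, giving
    ½·Beta(n1, n0+1) + ½·Beta(n1+1, n0) — a quantity concentrating near
    the *positive* probability, kept available for sensitivity checks.

    Per draw a fair coin picks the component.  With ``boundary="raise"``
    (default) a zero count on either side raises; ``boundary="component"``
    falls back to the single well-defined component.
    """
    if orientation not in ("zero", "printed"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "zero":
        comp = ((n0, n1 + 1), (n0 + 1, n1))
    else:
        comp = ((n1, n0 + 1), (n1 + 1, n0))
    bad = [p for p in comp if p[0] <= 0 or p[1] <= 0]
    if bad:
        if boundary != "component":
            raise BoundaryCountError(
                f"counts n0={n0}, n1={n1} leave a beta component ill-parameterized"
            )
        comp = tuple(p for p in comp if p[0] > 0 and p[1] > 0)
        if not comp:
            raise BoundaryCountError("no well-defined beta component")
    rng = as_rng(seed)
    if len(comp) == 1:
        return rng.beta(comp[0][0], comp[0][1], size=m)
    first = rng.random(m) < 0.5
    d1 = rng.beta(comp[0][0], comp[0][1], size=m)
    d2 = rng.beta(comp[1][0], comp[1][1], size=m)
    return np.where(first, d1, d2)


def fq_tau_draws(
    sample: ZeroInflatedSample,
    m: int = 5000,
    seed=None,
    orientation: str = "zero",
    boundary: str = "raise",
) -> TauDraws:
    """m fiducial draws of τ for the given sample."""
    rng = as_rng(seed)
    summary = sample.cube_root_summary()
    mu, sigma2 = fq_mu_sigma2_draws(summary, m, rng)
    q_m = gamma_mean_from_moments(mu, sigma2)
    q_v = gamma_variance_from_moments(mu, sigma2)
    q_d = fq_delta_draws(
        sample.n0, sample.n1, m, rng, orientation=orientation, boundary=boundary
    )
    tau = (1.0 - q_d) * q_v + q_d * (1.0 - q_d) * np.square(q_m)
    return TauDraws(tau, method="fq")


def fq_interval(
    sample: ZeroInflatedSample,
    level: float = 0.95,
    m: int = 5000,
    seed=None,
    orientation: str = "zero",
    boundary: str = "raise",
) -> IntervalEstimate:
    """Equal-tail fiducial interval for τ."""
    draws = fq_tau_draws(sample, m, seed, orientation=orientation, boundary=boundary)
    return equal_tail_interval(draws, level)
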