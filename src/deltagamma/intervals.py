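"""Interval containers and the equal-tail / HPD cuts applied to draw vectors."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TauDraws", "IntervalEstimate", "equal_tail_interval", "hpd_interval"]


@dataclass
class TauDraws:
    """A vector of Monte Carlo draws of τ (fiducial, bootstrap, or posterior)."""

    draws: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 1 or self.draws.size == 0:
            raise ValueError("draws must be a nonempty 1-d vector")

    @property
    def m(self) -> int:
        return self.draws.size


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval for τ with its nominal level and provenance."""

    lower: float
    upper: float
    level: float
    method: str
    flavor: str = "equal-tail"  # or "hpd"

    @property
    def length(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _as_draws(draws: TauDraws | np.ndarray) -> tuple[np.ndarray, str]:
    if isinstance(draws, TauDraws):
        return draws.draws, draws.method
    return np.asarray(draws, dtype=float), ""


def equal_tail_interval(
    draws: TauDraws | np.ndarray, level: float, method: str | None = None
) -> IntervalEstimate:
    """Equal-tail interval: the (α/2, 1−α/2) empirical quantiles of the draws.

    Quantiles use linear interpolation between order statistics (the
    ubiquitous "type 7" rule).
    """
    vec, label = _as_draws(draws)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    if vec.size == 0:
        raise ValueError("no draws")
    a = 1.0 - level
    lo, hi = np.quantile(vec, [a / 2.0, 1.0 - a / 2.0], method="linear")
    return IntervalEstimate(float(lo), float(hi), level, method or label, "equal-tail")


def hpd_interval(
    draws: TauDraws | np.ndarray, level: float, method: str | None = None
) -> IntervalEstimate:
    """Empirical highest-posterior-density interval (Chen-Shao rule).

    Among all windows of w = ceil(level·m) consecutive order statistics,
    return the shortest [x_(i), x_(i+w−1)]; ties break toward the smallest
    lower endpoint.  By construction its length never exceeds the
    equal-tail interval cut from the same draws.
    """
    vec, label = _as_draws(draws)
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    m = vec.size
    w = math.ceil(level * m)
    if m < w + 1:
        raise ValueError(f"need at least {w + 1} draws for a {level:.0%} HPD, got {m}")
    x = np.sort(vec)
    lengths = x[w - 1 :] - x[: m - w + 1]
    i = int(np.argmin(lengths))  # argmin takes the first minimum: smallest lower end
    return IntervalEstimate(float(x[i]), float(x[i + w - 1]), level, method or label, "hpd")
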