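"""Occurrence-frequency extinction tests and stratigraphic range extensions.

The occurrence-frequency test asks: if a taxon group still occurred at
per-formation frequency ``f``, what is the probability of finding it in none
of ``N`` suitable formations?  Under independent sampling opportunities this
is ``(1 - f)^N``, and inverting at a chosen probability gives the largest
frequency consistent with total absence.

Range extensions follow the classical constant-recovery (uniform) model: with
``H`` fossil horizons over an observed range ``R``, the one-sided confidence-C
extension is ``R * ((1 - C)^(-1/(H-1)) - 1)``.  A rate-based variant treats
recovery as a Poisson process at ``lambda`` finds/My, giving an extension of
``-ln(1 - C)/lambda`` — appropriate when a per-My recovery rate is better
constrained than a horizon count.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "prob_zero",
    "freq_upper_bound",
    "recovery_rate",
    "strauss_sadler_extension",
    "poisson_extension",
]


def prob_zero(f: float, N: int) -> float:
    """Probability of zero finds in ``N`` formations at occurrence frequency ``f``."""
    if not 0 <= f <= 1:
        raise ValueError("f must be in [0, 1]")
    if N < 0 or N != int(N):
        raise ValueError("N must be a non-negative integer")
    return float((1.0 - f) ** N)


def freq_upper_bound(N: int, p: float) -> float:
    """Largest occurrence frequency giving P(zero finds in N formations) >= p."""
    if N < 1 or N != int(N):
        raise ValueError("N must be a positive integer")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(1.0 - p ** (1.0 / N))


def recovery_rate(n_formations: float, duration_my: float) -> float:
    """Mean recovery potential: fossil-bearing formations per My."""
    if duration_my <= 0:
        raise ValueError("duration must be positive")
    if n_formations < 0:
        raise ValueError("n_formations must be >= 0")
    return n_formations / duration_my


def strauss_sadler_extension(R: float, H: int, C: float) -> float:
    """Classical uniform-recovery range extension (one-sided confidence C)."""
    if R <= 0:
        raise ValueError("observed range R must be positive")
    if H < 2:
        raise ValueError("need at least two fossil horizons")
    if not 0 < C < 1:
        raise ValueError("C must be in (0, 1)")
    return float(R * ((1.0 - C) ** (-1.0 / (H - 1)) - 1.0))


def poisson_extension(rate: float, C: float) -> float:
    """Range extension under Poisson recovery at ``rate`` finds/My."""
    if rate <= 0:
        raise ValueError("recovery rate must be positive")
    if not 0 < C < 1:
        raise ValueError("C must be in (0, 1)")
    return float(-np.log(1.0 - C) / rate)
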