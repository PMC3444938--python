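"""Exponential growth model for pulsed-label experiments.

Under balanced exponential growth the population follows
``P(t) = P0 * 2**(t / t_double)``.  During a heavy-isotope pulse the
pre-existing (light) protein pool is diluted by growth at the rate
``k_dil = ln(2) / t_double`` even in the absence of proteolysis, so a
non-degraded protein accumulates heavy label with an expected
heavy/light ratio of ``2**(t / t_double) - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "GrowthModel",
    "growth_factor_from_counts",
    "doubling_time",
    "expected_ratio",
]


@dataclass(frozen=True)
class GrowthModel:
    """Growth over an observation window.

    Attributes
    ----------
    growth_factor : float
        Fold increase of the population over ``window_h`` (P(t)/P0).
    window_h : float
        Length of the observation window in hours.
    t_double : float
        Doubling time in hours; ``inf`` when the population did not grow.
    k_dil : float
        Growth dilution rate ``ln 2 / t_double`` in 1/h; 0 without growth.
    """

    growth_factor: float
    window_h: float
    t_double: float
    k_dil: float

    @classmethod
    def from_growth_factor(cls, growth_factor: float, window_h: float) -> "GrowthModel":
        if growth_factor <= 0:
            raise ValueError(f"growth_factor must be positive, got {growth_factor}")
        if window_h <= 0:
            raise ValueError(f"window_h must be positive, got {window_h}")
        td = doubling_time(growth_factor, window_h)
        k_dil = 0.0 if math.isinf(td) else math.log(2) / td
        return cls(growth_factor=growth_factor, window_h=window_h, t_double=td, k_dil=k_dil)

    @classmethod
    def from_counts(cls, counts: Sequence[Tuple[float, float]]) -> "GrowthModel":
        g = growth_factor_from_counts(counts)
        times = [t for t, _ in counts]
        window = max(times) - min(times)
        return cls.from_growth_factor(g, window)

    @property
    def t_double_display(self) -> float:
        """Doubling time rounded to the nearest hour, as reported."""
        return self.t_double if math.isinf(self.t_double) else round(self.t_double)


def growth_factor_from_counts(counts: Sequence[Tuple[float, float]]) -> float:
    """Fold increase in cell number over the observation window.

    With exactly two time points this is the plain ratio of the counts.
    With more points a geometric (log-linear least-squares) fit is used
    and the factor is the ratio of fitted counts at the window ends.

    Parameters
    ----------
    counts : sequence of (time_h, cell_count)
        At least two points; counts must be positive.
    """
    if len(counts) < 2:
        raise ValueError("need at least 2 (time, count) points")
    times = np.asarray([t for t, _ in counts], dtype=float)
    vals = np.asarray([c for _, c in counts], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("cell counts must be positive")
    if np.ptp(times) == 0:
        raise ValueError("all time points identical; cannot estimate growth")
    if len(counts) == 2:
        order = np.argsort(times)
        return float(vals[order[1]] / vals[order[0]])
    slope, _ = np.polyfit(times, np.log(vals), 1)
    return float(math.exp(slope * np.ptp(times)))


def doubling_time(growth_factor: float, window_h: float) -> float:
    """Doubling time in hours from a fold increase over a window.

    ``t_double = window_h / log2(growth_factor)``.  A growth factor of
    1.3 over 24 h gives 63.41 h (displayed as 63 h).  For
    ``growth_factor <= 1`` the population is not growing and ``inf`` is
    returned rather than raising.
    """
    if window_h <= 0:
        raise ValueError(f"window_h must be positive, got {window_h}")
    if growth_factor <= 1.0:
        return math.inf
    return window_h / math.log2(growth_factor)


def expected_ratio(t_h: float, t_double: float) -> float:
    """Expected H/L ratio of a protein with zero degradation.

    New (heavy) protein accumulates only through growth, so
    ``H/L = 2**(t/t_double) - 1``: 0 at the start of the pulse and 1.0
    after exactly one doubling.
    """
    if t_h < 0:
        raise ValueError(f"time must be non-negative, got {t_h}")
    if t_double <= 0:
        raise ValueError(f"t_double must be positive, got {t_double}")
    return 2.0 ** (t_h / t_double) - 1.0
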