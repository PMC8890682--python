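"""Circular (phase) arithmetic on hours.

All phases live on a circle of configurable period (24 h by default).
Signed differences are mapped to the half-open interval
(-period/2, +period/2] so that "later" is positive.
"""

from __future__ import annotations

import numpy as np


def wrap(hours, period: float = 24.0):
    """Map hours onto [0, period)."""
    return np.mod(hours, period)


def signed_diff(a, b, period: float = 24.0):
    """Signed circular difference a - b mapped to (-period/2, period/2].

    Positive means `a` is later than `b` along the shorter arc.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), period)
    half = period / 2.0
    # fold (half, period) to negative; keep exactly +half positive
    return np.where(d > half, d - period, d)


def circ_mean(hours, period: float = 24.0) -> float:
    """Circular mean of phases in hours; NaNs are ignored."""
    h = np.asarray(hours, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return float("nan")
    ang = h * 2.0 * np.pi / period
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return float(np.mod(mean_ang * period / (2.0 * np.pi), period))


def circ_sem(hours, period: float = 24.0) -> float:
    """Standard error of the circular mean for concentrated samples.

    Deviations from the circular mean are unwrapped to the common branch
    (-period/2, period/2] and treated linearly; appropriate for the tightly
    clustered phases this package deals with (SD well below a quarter cycle).
    """
    h = np.asarray(hours, dtype=float)
    h = h[~np.isnan(h)]
    if h.size < 2:
        return float("nan")
    m = circ_mean(h, period)
    dev = signed_diff(h, m, period)
    return float(np.std(dev, ddof=1) / np.sqrt(h.size))
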