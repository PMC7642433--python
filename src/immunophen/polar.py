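"""Polar transform of compartmental CD8 densities.

A sample's CD8 infiltration pattern is summarised by the vector of
(tumour-compartment density, stroma-compartment density). Its magnitude
``R`` measures total CD8 quantity and its first-quadrant angle ``theta``
measures stroma-skew: ``theta = 0`` means fully tumour-infiltrated,
``theta = pi/2`` means fully stromal (excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PolarMetrics",
    "to_polar",
    "from_polar",
    "add_polar_columns",
    "metric_correlation",
]


@dataclass(frozen=True)
class PolarMetrics:
    """Quantity/distribution pair for one sample.

    Attributes
    ----------
    R : float
        Magnitude sqrt(tumour^2 + stroma^2), same units as the inputs.
    theta : float
        Angle in radians, in ``[0, pi/2]``.
    degenerate : bool
        True when both input densities were exactly zero; ``theta`` is
        then 0 by convention and carries no information.
    """

    R: float
    theta: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError(f"R must be non-negative, got {self.R}")
        if not (0.0 <= self.theta <= math.pi / 2 + 1e-12):
            raise ValueError(f"theta must lie in [0, pi/2], got {self.theta}")


def to_polar(cd8_tumour_density: float, cd8_stroma_density: float) -> PolarMetrics:
    """Convert a (tumour, stroma) density pair to polar metrics.

    Uses the two-argument arctangent so a zero tumour density is handled
    without division by zero; for non-negative inputs this equals
    ``atan(stroma / tumour)`` wherever the ratio is defined.

    Raises
    ------
    ValueError
        If either density is negative or non-finite.
    """
    t, s = float(cd8_tumour_density), float(cd8_stroma_density)
    if not (math.isfinite(t) and math.isfinite(s)):
        raise ValueError(f"densities must be finite, got ({t}, {s})")
    if t < 0 or s < 0:
        raise ValueError(f"densities must be non-negative, got ({t}, {s})")
    r = math.hypot(t, s)
    if r == 0.0:
        return PolarMetrics(R=0.0, theta=0.0, degenerate=True)
    return PolarMetrics(R=r, theta=math.atan2(s, t), degenerate=False)


def from_polar(metrics: PolarMetrics) -> tuple[float, float]:
    """Invert :func:`to_polar`: returns (tumour, stroma) densities."""
    return (metrics.R * math.cos(metrics.theta), metrics.R * math.sin(metrics.theta))


def add_polar_columns(densities: pd.DataFrame) -> pd.DataFrame:
    """Append ``R``, ``theta`` and ``degenerate_flag`` columns.

    Parameters
    ----------
    densities : DataFrame
        Must contain ``cd8_tumour_density`` and ``cd8_stroma_density``
        columns (cells/mm^2, or any shared unit).
    """
    required = {"cd8_tumour_density", "cd8_stroma_density"}
    missing = required - set(densities.columns)
    if missing:
        raise ValueError(f"densities table missing columns: {sorted(missing)}")
    t = densities["cd8_tumour_density"].to_numpy(dtype=float)
    s = densities["cd8_stroma_density"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t) & np.isfinite(s)):
        raise ValueError("densities must be finite")
    if (t < 0).any() or (s < 0).any():
        raise ValueError("densities must be non-negative")
    out = densities.copy()
    r = np.hypot(t, s)
    theta = np.where(r > 0, np.arctan2(s, t), 0.0)
    out["R"] = r
    out["theta"] = theta
    out["degenerate_flag"] = (t == 0) & (s == 0)
    return out


def metric_correlation(densities: pd.DataFrame) -> float:
    """Pearson correlation of tumour vs stroma densities.

    Returns NaN when either column has zero variance (the coefficient is
    undefined there). Requires at least 3 samples.
    """
    if len(densities) < 3:
        raise ValueError("need at least 3 samples to compute a correlation")
    t = densities["cd8_tumour_density"].to_numpy(dtype=float)
    s = densities["cd8_stroma_density"].to_numpy(dtype=float)
    if np.std(t) == 0 or np.std(s) == 0:
        return float("nan")
    return float(np.corrcoef(t, s)[0, 1])
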