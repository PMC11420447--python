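"""Microenvironmental uncertainty observables.

The central order parameter of the package is the lattice-averaged local
variance <sigma^2>_L: for each cell, the population variance of the phenotype
values of its Moore-neighborhood (the neighbors only, not the focal cell),
averaged over the whole lattice.  Under the Gaussian microenvironment
assumption this is a monotone proxy for the conditional entropy of a cell's
microenvironment, S = 1/2 ln(2 pi e sigma^2), so rising local variance means
rising microenvironmental uncertainty.

The regime-level observable is the time slope of <sigma^2>_L: positive for
lateral-inhibition-like (checkerboard) dynamics, negative for
lateral-induction-like (uniformizing) dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lattice import GridSpec, NeighborhoodSpec, neighbor_aggregate

__all__ = [
    "VarianceTimeSeries",
    "local_variance_field",
    "mean_local_variance",
    "entropy_from_variance",
    "variance_time_slope",
    "nn_correlation",
]

#: Default metric neighborhood: nearest Moore ring, focal cell excluded.
METRIC_NEIGHBORHOOD = NeighborhoodSpec(radius=1, include_focal=False)


@dataclass(frozen=True)
class VarianceTimeSeries:
    """A recorded (time, <sigma^2>_L) trajectory."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("<sigma^2>_L values must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def steady_value(self, fraction: float = 0.1) -> float:
        """Mean of the final ``fraction`` of the series (steady-state summary)."""
        k = max(1, int(round(fraction * len(self.values))))
        return float(np.mean(self.values[-k:]))


def local_variance_field(
    field: np.ndarray,
    grid: GridSpec,
    nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
) -> np.ndarray:
    """Population variance of each cell's neighbor values (focal excluded)."""
    if nbr.include_focal:
        raise ValueError("the local-variance metric neighborhood excludes the focal cell")
    return neighbor_aggregate(field, grid, nbr, stat="variance")


def mean_local_variance(
    field: np.ndarray,
    grid: GridSpec,
    nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
) -> float:
    """Lattice average <sigma^2>_L of the local neighbor variance."""
    return float(np.mean(local_variance_field(field, grid, nbr)))


def entropy_from_variance(sigma2: float, d: int = 1) -> float:
    """Gaussian microenvironmental entropy S = (d/2) ln(2 pi e sigma2^(1/d) ...).

    For the scalar phenotype case (d=1) this is S = 1/2 ln(2 pi e sigma^2);
    for d-dimensional microenvironments sigma2 is interpreted as the
    determinant of the covariance matrix and S = 1/2 ln((2 pi e)^d sigma2).
    Monotone increasing in sigma2 for every d.
    """
    if sigma2 <= 0:
        raise ValueError(f"entropy requires sigma^2 > 0, got {sigma2}")
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    return 0.5 * float(np.log((2.0 * np.pi * np.e) ** d * sigma2))


def variance_time_slope(series: VarianceTimeSeries) -> float:
    """Ordinary-least-squares slope of <sigma^2>_L against time."""
    if len(series) < 2:
        raise ValueError("slope requires at least 2 time points")
    res = stats.linregress(series.times, series.values)
    return float(res.slope)


def nn_correlation(field: np.ndarray, grid: GridSpec) -> float:
    """Pearson correlation of edge-adjacent (von Neumann) cell pairs.

    Strongly negative for checkerboard patterns, ~0 for random fields,
    positive for smooth/uniformizing fields.  Each unordered horizontal and
    vertical wrapped pair enters once.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    a = np.concatenate([field.ravel(), field.ravel()])
    b = np.concatenate(
        [
            np.roll(field, -1, axis=0).ravel(),
            np.roll(field, -1, axis=1).ravel(),
        ]
    )
    if np.allclose(a, a.mean()) or np.allclose(b, b.mean()):
        raise ValueError("nearest-neighbor correlation undefined for constant field")
    return float(np.corrcoef(a, b)[0, 1])
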