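"""Periodic square-lattice geometry and Moore-neighborhood aggregation.

Every simulator and metric in this package lives on a rows x cols square
lattice with periodic (toroidal) boundary conditions.  Cells interact with
their Moore neighborhood of radius ``r``: all cells within Chebyshev distance
``r`` of the focal site.  This module provides the neighborhood bookkeeping
(offset enumeration) and wrapped per-cell aggregation (mean / sum / variance)
that the signaling and phenotype dynamics are built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "GridSpec",
    "NeighborhoodSpec",
    "neighbor_offsets",
    "neighbor_aggregate",
]


@dataclass(frozen=True)
class GridSpec:
    """Shape and boundary of the simulation lattice.

    Only periodic boundaries are supported: every reported pattern regime in
    this package assumes a torus, so edge effects never enter.
    """

    rows: int
    cols: int
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.rows < 3 or self.cols < 3:
            raise ValueError(
                f"lattice must be at least 3x3, got {self.rows}x{self.cols}"
            )
        if self.boundary != "periodic":
            raise ValueError("only periodic boundary conditions are supported")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Moore neighborhood of Chebyshev radius ``radius``.

    ``include_focal`` controls whether the focal cell belongs to its own
    sample; the entropic-force sample includes it while the local-variance
    metric does not, so both conventions are first-class here.
    """

    radius: int = 1
    include_focal: bool = False
    metric: str = "chebyshev"

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError(f"neighborhood radius must be >= 1, got {self.radius}")
        if self.metric != "chebyshev":
            raise ValueError("only the Chebyshev (Moore) neighborhood is supported")

    @property
    def size(self) -> int:
        """Number of cells in the neighborhood sample."""
        full = (2 * self.radius + 1) ** 2
        return full if self.include_focal else full - 1

    def validate_for(self, grid: GridSpec) -> None:
        """Reject radii whose wrapped neighborhood would double-count cells."""
        limit = min(grid.rows, grid.cols) / 2
        if not self.radius < limit:
            raise ValueError(
                f"radius {self.radius} too large for {grid.rows}x{grid.cols} "
                f"periodic lattice (need r < {limit})"
            )


def neighbor_offsets(spec: NeighborhoodSpec) -> list[tuple[int, int]]:
    """Enumerate the (di, dj) offsets of the Moore neighborhood.

    Returns all offsets with max(|di|, |dj|) <= r, dropping (0, 0) unless the
    spec includes the focal cell.  Row-major order, 0-based indexing; offsets
    are applied modulo the lattice shape.
    """
    r = spec.radius
    offsets = [
        (di, dj)
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
        if spec.include_focal or (di, dj) != (0, 0)
    ]
    return offsets


def _check_field(field: np.ndarray, grid: GridSpec) -> np.ndarray:
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError(f"field shape {field.shape} does not match grid {grid.shape}")
    return field


def neighbor_aggregate(
    field: np.ndarray,
    grid: GridSpec,
    spec: NeighborhoodSpec,
    stat: str = "mean",
) -> np.ndarray:
    """Per-cell statistic of ``field`` over the wrapped Moore neighborhood.

    Parameters
    ----------
    field : array of shape ``grid.shape``
    stat : {"mean", "sum", "variance"}
        ``variance`` is the population variance (divisor = sample size) of the
        neighborhood values.

    Returns
    -------
    array of the same shape, where entry (i, j) aggregates the values at
    cells (i+di mod rows, j+dj mod cols) over the neighborhood offsets.
    """
    field = _check_field(field, grid)
    spec.validate_for(grid)
    if stat not in ("mean", "sum", "variance"):
        raise ValueError(f"unknown statistic {stat!r}")

    size = 2 * spec.radius + 1
    n = spec.size
    # separable wrapped box filter: O(1) in radius, exact up to fp rounding
    box_sum = uniform_filter(field, size=size, mode="wrap") * (size * size)
    total = box_sum if spec.include_focal else box_sum - field
    if stat == "sum":
        return total
    if stat == "mean":
        return total / n
    sq = field * field
    box_sum_sq = uniform_filter(sq, size=size, mode="wrap") * (size * size)
    total_sq = box_sum_sq if spec.include_focal else box_sum_sq - sq
    mean = total / n
    var = total_sq / n - mean * mean
    # guard tiny negative round-off from the moment formula
    np.maximum(var, 0.0, out=var)
    return var
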