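"""Deterministic synthetic lattices and samples for tests and calibration.

Three generator families: ideal chessboards (the reference pattern for the
rdf and spectral metrics), i.i.d. random fields (uniform / normal, the SBC
calibration distributions), and jointly Gaussian paired (X, Y) cell samples
with known generating covariances (the oracle inputs for the conditional
covariance / mutual-information pipeline).  Every generator is
bit-reproducible given its spec and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GaussianLatticeSpec",
    "make_chessboard",
    "make_random_field",
    "make_gaussian_xy",
]


def make_chessboard(
    rows: int, cols: int, lo: float = -1.0, hi: float = 1.0
) -> np.ndarray:
    """Ideal chessboard field: ``hi`` where (i + j) is even, ``lo`` where odd.

    Warns for odd dimensions, where the pattern cannot wrap perfectly on the
    torus.
    """
    if rows % 2 or cols % 2:
        warnings.warn(
            "odd lattice dimensions: chessboard is imperfect under periodic wrap",
            stacklevel=2,
        )
    i, j = np.indices((rows, cols))
    return np.where((i + j) % 2 == 0, float(hi), float(lo))


def make_random_field(
    rows: int, cols: int, dist: str = "uniform", seed: int | None = None
) -> np.ndarray:
    """I.i.d. random field: ``uniform`` on (-1, 1) or standard ``normal``."""
    rng = np.random.default_rng(seed)
    if dist == "uniform":
        return rng.uniform(-1.0, 1.0, size=(rows, cols))
    if dist == "normal":
        return rng.standard_normal((rows, cols))
    raise ValueError(f"unknown distribution {dist!r}")


def _check_pd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.linalg.eigvalsh(mat) <= 0):
        raise ValueError(f"{name} must be positive definite")
    return mat


@dataclass(frozen=True)
class GaussianLatticeSpec:
    """Jointly Gaussian paired cell samples Y = A X + eps.

    X ~ N(0, SigmaX) per cell, eps ~ N(0, SigmaY_given_X) independent of X,
    so the implied marginal is SigmaY = A SigmaX A^T + SigmaY_given_X and
    the generating conditional covariance is exactly SigmaY_given_X.  Cells
    are spatially i.i.d. (exchangeable samples, no autocorrelation).
    """

    n_cells: int
    SigmaX: np.ndarray
    SigmaY_given_X: np.ndarray
    coupling: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells")
        object.__setattr__(self, "SigmaX", _check_pd(self.SigmaX, "SigmaX"))
        object.__setattr__(
            self, "SigmaY_given_X", _check_pd(self.SigmaY_given_X, "SigmaY_given_X")
        )
        A = np.asarray(self.coupling, dtype=float)
        if A.shape != (2, 2):
            raise ValueError("coupling must be 2x2")
        object.__setattr__(self, "coupling", A)

    @property
    def implied_SigmaY(self) -> np.ndarray:
        A = self.coupling
        return A @ self.SigmaX @ A.T + self.SigmaY_given_X


def make_gaussian_xy(spec: GaussianLatticeSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw (X, Y) per-cell 2-vectors from the spec; shapes (n_cells, 2)."""
    rng = np.random.default_rng(spec.seed)
    X = rng.multivariate_normal(np.zeros(2), spec.SigmaX, size=spec.n_cells)
    eps = rng.multivariate_normal(np.zeros(2), spec.SigmaY_given_X, size=spec.n_cells)
    Y = X @ spec.coupling.T + eps
    return X, Y
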