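"""Entropy-driven phenotypic Langevin dynamics on the lattice (LEUP model).

Each cell carries a scalar phenotype X in [-1, 1].  Its microenvironment is
the Moore neighborhood of radius r; assuming the neighborhood phenotypes are
Gaussian, the microenvironmental entropy of cell n is

    S_n = 1/2 ln(2 pi e sigma_n^2),

where sigma_n^2 is the population variance of the focal-inclusive sample of
N = (2r+1)^2 phenotypes around cell n.  The phenotype follows an overdamped
Langevin equation driven by the entropy gradient, scaled by the sensitivity
beta:

    dX_n/dt = -beta * dS_n/dX_n + xi_n(t),   <xi xi'> = 2 D delta.

The gradient has the closed form (X_n - mu_n) / (N sigma_n^2): for beta > 0
cells move toward the local mean (entropy reduction, induction-like
consensus), for beta < 0 they flee it (entropy production, inhibition-like
diversification).  Integration is Euler-Maruyama with hard clipping at the
phenotype bounds; the clipping is what pins the multimodal peaks at -1/+1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import uniform_filter

from .lattice import GridSpec, NeighborhoodSpec
from .metrics import METRIC_NEIGHBORHOOD, VarianceTimeSeries, mean_local_variance

__all__ = [
    "LEUPParams",
    "LEUPTrajectory",
    "entropic_force",
    "stability_bound_dt",
    "leup_step",
    "simulate_leup",
    "random_phenotypes",
]


@dataclass(frozen=True)
class LEUPParams:
    """Parameters of the phenotypic Langevin dynamics.

    beta
        Sensitivity to microenvironmental entropy; any sign.
    radius
        Moore interaction radius r of the sensing neighborhood.
    noise_D
        Phenotype-space diffusion constant D; the Langevin noise has
        autocorrelation 2*D*delta.  Default 0: the perfect-sensor /
        zero-noise limit in which the dynamics reduce to the deterministic
        entropy-gradient flow.  D=0.5 corresponds to unit-variance noise.
    dt, n_steps
        Euler-Maruyama step and count; defaults integrate to T = 50.
    clip
        Closed phenotype interval, default [-1, 1].
    variance_floor
        sigma^2 guard below which the entropic force is set to 0 (removes the
        0/0 singularity of a locally uniform neighborhood).
    """

    beta: float
    radius: int = 1
    noise_D: float = 0.0
    dt: float = 0.01
    n_steps: int = 5000
    seed: int | None = None
    clip: tuple[float, float] = (-1.0, 1.0)
    variance_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.noise_D < 0:
            raise ValueError("noise_D must be >= 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if not self.clip[0] < self.clip[1]:
            raise ValueError("clip interval must satisfy lower < upper")


def stability_bound_dt(beta: float, radius: int, sigma2: float) -> float:
    """Largest Euler step that keeps the entropic drift stable at variance ``sigma2``.

    Linearizing the drift around the local mean gives a restoring stiffness
    k = beta / (N sigma^2) with N = (2 r + 1)^2; the explicit update
    multiplies deviations by (1 - dt k), so stability requires
    dt < 2 N sigma^2 / beta.  For beta <= 0 there is no overshoot bound and
    +inf is returned.  Simulations that must resolve a variance collapse down
    to sigma^2 should use a step comfortably below this bound; above it the
    steady variance freezes at an integrator floor ~ dt beta / (2 N).
    """
    if beta <= 0:
        return math.inf
    n_sample = (2 * radius + 1) ** 2
    return 2.0 * n_sample * sigma2 / beta


def random_phenotypes(grid: GridSpec, rng: np.random.Generator,
                      clip: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """I.i.d. uniform initial phenotypes on the clip interval."""
    return rng.uniform(clip[0], clip[1], size=grid.shape)


def _sample_moments(field: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Focal-inclusive neighborhood mean and population variance per cell."""
    size = 2 * radius + 1
    mean = uniform_filter(field, size=size, mode="wrap")
    mean_sq = uniform_filter(field * field, size=size, mode="wrap")
    var = mean_sq - mean * mean
    np.maximum(var, 0.0, out=var)
    return mean, var


def entropic_force(
    field: np.ndarray,
    grid: GridSpec,
    radius: int = 1,
    variance_floor: float = 1e-12,
) -> np.ndarray:
    """Gradient of the microenvironmental entropy with respect to X_n.

    Per cell n the force is (X_n - mu_n) / (N sigma_n^2), where mu_n and
    sigma_n^2 are mean and population variance of the (2r+1)^2 cells within
    Chebyshev distance r INCLUDING the focal cell, and N is that sample size.
    This is algebraically d/dX_n of 1/2 ln(2 pi e sigma_n^2).  Cells whose
    sample variance is below ``variance_floor`` get zero force.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    NeighborhoodSpec(radius=radius, include_focal=True).validate_for(grid)
    n_sample = (2 * radius + 1) ** 2
    mean, var = _sample_moments(field, radius)
    safe = var >= variance_floor
    force = np.zeros_like(field)
    np.divide(field - mean, n_sample * var, out=force, where=safe)
    return force


def leup_step(
    field: np.ndarray,
    params: LEUPParams,
    grid: GridSpec,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One Euler-Maruyama update of every phenotype, clamped to the clip interval."""
    force = entropic_force(field, grid, params.radius, params.variance_floor)
    drift = -params.beta * force
    new = field + params.dt * drift
    if params.noise_D > 0:
        if rng is None:
            raise ValueError("noise_D > 0 requires a random generator")
        new = new + math.sqrt(2.0 * params.noise_D * params.dt) * rng.standard_normal(
            field.shape
        )
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("non-finite phenotype update")
    return np.clip(new, params.clip[0], params.clip[1])


@dataclass
class LEUPTrajectory:
    """Recorded output of a phenotypic Langevin run."""

    times: np.ndarray
    snapshots: list[np.ndarray]
    sigma2: VarianceTimeSeries
    final: np.ndarray = dc_field(repr=False, default=None)

    def steady_sigma2(self, fraction: float = 0.1) -> float:
        return self.sigma2.steady_value(fraction)


def simulate_leup(
    initial: np.ndarray | None,
    params: LEUPParams,
    grid: GridSpec,
    record_every: int = 50,
    metric_nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
) -> LEUPTrajectory:
    """Integrate the phenotypic Langevin equation for ``n_steps`` steps.

    If ``initial`` is None, phenotypes are drawn i.i.d. uniform on the clip
    interval from ``params.seed``.  Snapshots and the <sigma^2>_L series are
    recorded every ``record_every`` steps (state at step 0 included).
    """
    rng = np.random.default_rng(params.seed)
    if initial is None:
        field = random_phenotypes(grid, rng, params.clip)
    else:
        field = np.asarray(initial, dtype=float).copy()
        if field.shape != grid.shape:
            raise ValueError("initial field shape does not match grid")

    times = [0.0]
    snapshots = [field.copy()]
    sigma2 = [mean_local_variance(field, grid, metric_nbr)]
    for step in range(1, params.n_steps + 1):
        field = leup_step(field, params, grid, rng)
        if step % record_every == 0 or step == params.n_steps:
            times.append(step * params.dt)
            snapshots.append(field.copy())
            sigma2.append(mean_local_variance(field, grid, metric_nbr))

    series = VarianceTimeSeries(np.array(times), np.array(sigma2))
    return LEUPTrajectory(times=np.array(times), snapshots=snapshots,
                          sigma2=series, final=field)
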