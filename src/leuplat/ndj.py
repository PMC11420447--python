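"""Mechanistic Notch-Delta-Jagged (NDJ) signaling on the lattice.

Per cell the model tracks Notch receptor N, ligands Delta D and Jagged J,
and the cleaved signal NICD I.  Trans-interaction with neighboring cells'
ligands (at rate kT) releases NICD; same-cell cis-interaction (kC) removes
receptor and ligand without signaling.  NICD feeds back transcriptionally
through shifted Hill functions: it activates Notch and Jagged (fold change
lambda > 1) and shuts off Delta (lambda = 0).  That asymmetric feedback is
what separates the two classic regimes:

* Delta-dominated *lateral inhibition* -- neighbors adopt opposite
  sender/receiver fates, producing checkerboard NICD patterns;
* Jagged-dominated *lateral induction* -- neighbors converge on the same
  hybrid fate, producing spatially uniform NICD.

The NICD level is taken as the cell's phenotype readout.  External ligand
and receptor levels (Next, Dext, Jext) are the neighbor-mean levels over the
Moore neighborhood (per-contact share; a ``sum`` convention is available).
Integration is explicit forward Euler at the reference step dt = 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .lattice import GridSpec, NeighborhoodSpec, neighbor_aggregate
from .metrics import METRIC_NEIGHBORHOOD, VarianceTimeSeries, mean_local_variance

__all__ = [
    "NDJParams",
    "NDJState",
    "IntegrationConfig",
    "NDJTrajectory",
    "shifted_hill",
    "ndj_rhs",
    "simulate_ndj",
    "random_ndj_state",
    "normalize_nicd",
    "nicd_qss",
]

logger = logging.getLogger(__name__)

#: NICD range used for min-max display normalization of steady-state fields.
NICD_NORM_LO = 100.0
NICD_NORM_HI = 1400.0


@dataclass(frozen=True)
class NDJParams:
    """Rate constants of the NDJ circuit (molecules and hours).

    Defaults are the reference parameter set: basal production N0 = 1400,
    degradation gamma = 0.1 (gammaI = 0.5 for NICD), trans-activation
    kT = 5e-5, cis-inhibition kC = 5e-4, NICD Hill threshold I0 = 200 with
    cooperativities (nN, nD, nJ) = (2, 2, 5) and fold changes
    (lamN, lamD, lamJ) = (2, 0, 2).  D0 and J0 are the swept ligand
    production rates (plausible ranges D0 in [500, 2000], J0 in [200, 1300]).

    ext_stat selects how external levels aggregate over the neighborhood:
    ``mean`` (default, per-contact share) or ``sum``.
    """

    D0: float = 1000.0
    J0: float = 800.0
    N0: float = 1400.0
    kT: float = 5e-5
    kC: float = 5e-4
    gamma: float = 0.1
    gammaI: float = 0.5
    I0: float = 200.0
    nN: float = 2.0
    nD: float = 2.0
    nJ: float = 5.0
    lamN: float = 2.0
    lamD: float = 0.0
    lamJ: float = 2.0
    ext_stat: str = "mean"

    def __post_init__(self) -> None:
        for name in ("D0", "J0", "N0", "kT", "kC", "gamma", "gammaI"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        for name in ("nN", "nD", "nJ"):
            if getattr(self, name) < 1:
                raise ValueError(f"Hill coefficient {name} must be >= 1")
        if self.ext_stat not in ("mean", "sum"):
            raise ValueError("ext_stat must be 'mean' or 'sum'")

    @property
    def alpha(self) -> float:
        """Quasi-steady-state NICD gain alpha = kT / gammaI."""
        if self.gammaI == 0:
            raise ValueError("alpha undefined for gammaI = 0")
        return self.kT / self.gammaI


@dataclass
class NDJState:
    """Per-cell Notch / Delta / Jagged / NICD levels at time t."""

    N: np.ndarray
    D: np.ndarray
    J: np.ndarray
    I: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        fields = [np.asarray(f, dtype=float) for f in (self.N, self.D, self.J, self.I)]
        shapes = {f.shape for f in fields}
        if len(shapes) != 1:
            raise ValueError("all species fields must share one shape")
        if any(np.any(f < 0) for f in fields):
            raise ValueError("species levels must be non-negative")
        self.N, self.D, self.J, self.I = fields

    @property
    def species(self) -> tuple[np.ndarray, ...]:
        return (self.N, self.D, self.J, self.I)

    def copy(self) -> "NDJState":
        return NDJState(self.N.copy(), self.D.copy(), self.J.copy(), self.I.copy(), self.t)


@dataclass(frozen=True)
class IntegrationConfig:
    """Forward-Euler integration settings.

    Defaults integrate T = 300 at dt = 0.01 (30000 steps).  If
    ``convergence_tol`` is set, integration stops early once the maximum
    relative change per step over all species falls below it.
    """

    dt: float = 0.01
    n_steps: int = 30000
    seed: int | None = None
    record_every: int = 300
    convergence_tol: float | None = 1e-6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


def shifted_hill(I: np.ndarray | float, I0: float, lam: float, n: float) -> np.ndarray | float:
    """Shifted Hill factor Hs(I) = (1 + lam (I/I0)^n) / (1 + (I/I0)^n).

    Interpolates from 1 at I = 0 to the fold change lam at saturating I:
    transcriptional activation for lam > 1, repression for lam < 1.
    """
    if I0 <= 0:
        raise ValueError("Hill threshold I0 must be positive")
    x = (np.asarray(I, dtype=float) / I0) ** n
    out = (1.0 + lam * x) / (1.0 + x)
    return out if isinstance(I, np.ndarray) else float(out)


def ndj_rhs(
    state: NDJState,
    params: NDJParams,
    grid: GridSpec,
    nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dN, dD, dJ, dI) of the NDJ circuit.

    External levels are the neighbor aggregate (mean by default) of each
    species over the focal-exclusive Moore neighborhood.
    """
    if nbr.include_focal:
        raise ValueError("external aggregation must exclude the focal cell")
    p = params
    N, D, J, I = state.species
    Next = neighbor_aggregate(N, grid, nbr, stat=p.ext_stat)
    Dext = neighbor_aggregate(D, grid, nbr, stat=p.ext_stat)
    Jext = neighbor_aggregate(J, grid, nbr, stat=p.ext_stat)
    Lext = Dext + Jext

    hN = shifted_hill(I, p.I0, p.lamN, p.nN)
    hD = shifted_hill(I, p.I0, p.lamD, p.nD)
    hJ = shifted_hill(I, p.I0, p.lamJ, p.nJ)

    dN = p.N0 * hN - p.kC * N * (D + J) - p.kT * N * Lext - p.gamma * N
    dD = p.D0 * hD - p.kC * N * D - p.kT * D * Next - p.gamma * D
    dJ = p.J0 * hJ - p.kC * N * J - p.kT * J * Next - p.gamma * J
    dI = p.kT * N * Lext - p.gammaI * I
    return dN, dD, dJ, dI


def random_ndj_state(
    grid: GridSpec,
    rng: np.random.Generator,
    level_range: tuple[float, float] = (0.0, 2000.0),
) -> NDJState:
    """Initial condition: each species i.i.d. uniform per cell."""
    lo, hi = level_range
    draw = lambda: rng.uniform(lo, hi, size=grid.shape)  # noqa: E731
    return NDJState(draw(), draw(), draw(), draw(), t=0.0)


@dataclass
class NDJTrajectory:
    """Recorded output of an NDJ integration."""

    times: np.ndarray
    snapshots: list[NDJState]
    sigma2: VarianceTimeSeries  # of the normalized NICD phenotype
    final: NDJState
    converged_at: int | None = None  # step index of early convergence, if any

    def steady_sigma2(self, fraction: float = 0.1) -> float:
        return self.sigma2.steady_value(fraction)


def simulate_ndj(
    initial: NDJState | None,
    params: NDJParams,
    config: IntegrationConfig = IntegrationConfig(),
    grid: GridSpec = GridSpec(24, 24),
    nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
    metric_nbr: NeighborhoodSpec = METRIC_NEIGHBORHOOD,
) -> NDJTrajectory:
    """Integrate the NDJ circuit by explicit forward Euler.

    If ``initial`` is None, a random state is drawn from ``config.seed``.
    Components driven below zero by an Euler overshoot are clamped to 0 (with
    a logged warning).  The <sigma^2>_L series is recorded on the min-max
    normalized NICD field.  Raises ``FloatingPointError`` naming the step if
    the integration diverges.
    """
    rng = np.random.default_rng(config.seed)
    state = random_ndj_state(grid, rng) if initial is None else initial.copy()

    times = [state.t]
    snapshots = [state.copy()]
    sigma2 = [mean_local_variance(normalize_nicd(state.I), grid, metric_nbr)]
    warned_clamp = False
    converged_at = None
    eps = 1e-9

    for step in range(1, config.n_steps + 1):
        derivs = ndj_rhs(state, params, grid, nbr)
        max_rel = 0.0
        for name, arr, d in zip("NDJI", state.species, derivs):
            upd = config.dt * d
            arr += upd
            if config.convergence_tol is not None:
                rel = np.max(np.abs(upd) / (np.abs(arr) + eps))
                max_rel = max(max_rel, float(rel))
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"NDJ integration diverged in species {name} at step {step}"
                )
            if np.any(arr < 0):
                if not warned_clamp:
                    logger.warning(
                        "clamping negative %s levels to 0 at step %d", name, step
                    )
                    warned_clamp = True
                np.maximum(arr, 0.0, out=arr)
        state.t += config.dt

        done = step == config.n_steps
        if config.convergence_tol is not None and max_rel < config.convergence_tol:
            converged_at = step
            done = True
        if step % config.record_every == 0 or done:
            times.append(state.t)
            snapshots.append(state.copy())
            sigma2.append(mean_local_variance(normalize_nicd(state.I), grid, metric_nbr))
        if done:
            break

    series = VarianceTimeSeries(np.array(times), np.array(sigma2))
    return NDJTrajectory(times=np.array(times), snapshots=snapshots,
                         sigma2=series, final=state, converged_at=converged_at)


def normalize_nicd(field: np.ndarray) -> np.ndarray:
    """Min-max display normalization (I - 100) / 1300 of NICD levels."""
    return (np.asarray(field, dtype=float) - NICD_NORM_LO) / (NICD_NORM_HI - NICD_NORM_LO)


def nicd_qss(
    N: np.ndarray | float, Lext: np.ndarray | float, params: NDJParams
) -> np.ndarray | float:
    """Quasi-steady-state NICD level I = (kT / gammaI) N Lext.

    Valid because NICD turns over much faster than receptor and ligands
    (gammaI >> gamma), so its production-degradation balance is effectively
    instantaneous on the N/D/J timescale.
    """
    return params.alpha * np.asarray(N, dtype=float) * np.asarray(Lext, dtype=float) \
        if isinstance(N, np.ndarray) or isinstance(Lext, np.ndarray) \
        else params.alpha * N * Lext
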