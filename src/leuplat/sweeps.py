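"""Phase-diagram sweeps over the two model families.

This layer only orchestrates the simulators, the beta pipeline and the
pattern statistics; it recomputes no model math of its own.  Each sweep
returns a tidy DataFrame with one row per (parameter coordinate, seed),
fully reproducible from the seed list.

The two headline phase diagrams: steady-state <sigma^2>_L over the
(beta, r) plane of the entropy-driven phenotype model, and the
beta-estimate / modality-index / spectral-order maps over the (D0, J0)
plane of the NDJ model, whose signs agree across the lateral-inhibition
vs lateral-induction divide.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .beta import UndefinedBetaError, beta_from_state
from .lattice import GridSpec
from .leup import LEUPParams, simulate_leup
from .metrics import nn_correlation, variance_time_slope
from .ndj import IntegrationConfig, NDJParams, normalize_nicd, simulate_ndj
from .patterns import modality_index, pattern_auc_metric, sarle_bimodality

__all__ = ["sweep_leup", "sweep_ndj", "sign_agreement"]

from dataclasses import replace


def sweep_leup(
    beta_grid: Sequence[float],
    r_grid: Sequence[int],
    seeds: Sequence[int],
    base_params: LEUPParams = LEUPParams(beta=0.0),
    grid: GridSpec = GridSpec(24, 24),
    record_every: int = 50,
) -> pd.DataFrame:
    """Simulate the phenotypic Langevin model over a (beta, r) grid.

    One row per (beta, r, seed) with the steady-state <sigma^2>_L (mean of
    the final 10% of snapshots), the variance time slope, and the SBC /
    modality index of the final phenotype distribution.
    """
    if not len(beta_grid) or not len(r_grid) or not len(seeds):
        raise ValueError("beta_grid, r_grid and seeds must be nonempty")
    rows = []
    for beta in beta_grid:
        for r in r_grid:
            for seed in seeds:
                params = replace(base_params, beta=float(beta), radius=int(r),
                                 seed=int(seed))
                traj = simulate_leup(None, params, grid, record_every=record_every)
                sbc = sarle_bimodality(traj.final)
                rows.append(
                    {
                        "beta": float(beta),
                        "r": int(r),
                        "seed": int(seed),
                        "sigma2_steady": traj.steady_sigma2(),
                        "sigma2_initial": float(traj.sigma2.values[0]),
                        "variance_slope": variance_time_slope(traj.sigma2),
                        "sbc": sbc,
                        "modality_index": 5.0 / 9.0 - sbc,
                    }
                )
    return pd.DataFrame(rows)


def sweep_ndj(
    d0_grid: Sequence[float],
    j0_grid: Sequence[float],
    seeds: Sequence[int],
    base_params: NDJParams = NDJParams(),
    config: IntegrationConfig = IntegrationConfig(),
    grid: GridSpec = GridSpec(24, 24),
    n_permutations: int = 20,
) -> pd.DataFrame:
    """Simulate the NDJ model over a (D0, J0) grid and score each run.

    One row per (D0, J0, seed): steady <sigma^2>_L and its time slope,
    SBC / modality index of the final NICD distribution, nearest-neighbor
    NICD correlation, spectral AUC metric, and every beta component.
    Runs in the beta ~ 0 regime are flagged (beta_defined = False) with
    NaN beta, never dropped.
    """
    if not len(d0_grid) or not len(j0_grid) or not len(seeds):
        raise ValueError("d0_grid, j0_grid and seeds must be nonempty")
    rows = []
    for d0 in d0_grid:
        for j0 in j0_grid:
            for seed in seeds:
                params = replace(base_params, D0=float(d0), J0=float(j0))
                cfg = replace(config, seed=int(seed))
                traj = simulate_ndj(None, params, cfg, grid)
                nicd = traj.final.I
                norm = normalize_nicd(nicd)
                auc, auc_rand, auc_metric = pattern_auc_metric(
                    norm, grid, n_permutations=n_permutations, seed=int(seed)
                )
                row = {
                    "D0": float(d0),
                    "J0": float(j0),
                    "seed": int(seed),
                    "sigma2_steady": traj.steady_sigma2(),
                    "variance_slope": variance_time_slope(traj.sigma2),
                    "sbc": sarle_bimodality(nicd),
                    "modality_index": modality_index(nicd),
                    "nn_corr": nn_correlation(nicd, grid),
                    "auc": auc,
                    "auc_random_mean": auc_rand,
                    "auc_metric": auc_metric,
                    "converged_at": traj.converged_at,
                }
                try:
                    comp = beta_from_state(traj.final, params, grid)
                    row.update(
                        beta=comp.beta,
                        beta_defined=True,
                        ln_det_dY=comp.ln_det_dY,
                        ln_det_dX=comp.ln_det_dX,
                        S_Y=comp.S_Y,
                        mi=comp.mi,
                        c=comp.c,
                        boundary_q=comp.boundary_q,
                        quad_term=comp.quad_term,
                    )
                except UndefinedBetaError:
                    row.update(
                        beta=np.nan,
                        beta_defined=False,
                        ln_det_dY=np.nan,
                        ln_det_dX=np.nan,
                        S_Y=np.nan,
                        mi=np.nan,
                        c=np.nan,
                        boundary_q=np.nan,
                        quad_term=np.nan,
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def sign_agreement(a: Sequence[float], b: Sequence[float]) -> float:
    """Fraction of entries whose signs match after naive thresholding.

    Values are discretized to +1 (>= 0) / -1 (< 0); NaN entries are excluded
    pairwise.  Raises on empty overlap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("sign vectors must have equal length")
    mask = np.isfinite(a) & np.isfinite(b)
    if not mask.any():
        raise ValueError("no overlapping defined entries")
    sa = np.where(a[mask] >= 0, 1, -1)
    sb = np.where(b[mask] >= 0, 1, -1)
    return float(np.mean(sa == sb))
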