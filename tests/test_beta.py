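"""Sensitivity-parameter pipeline: reduced flow, Jacobians, covariances, beta."""

import math

import numpy as np
import pytest

from leuplat.beta import (
    CovarianceSet,
    DegenerateSteadyStateError,
    ReducedState,
    SingularCovarianceError,
    UndefinedBetaError,
    beta_from_state,
    boundary_quantity,
    capacity_constant,
    covariances_from_samples,
    drift_det_dX,
    drift_det_dY,
    drift_jacobian_X,
    estimate_beta,
    external_entropy,
    g_tilde,
    lattice_covariances,
    mutual_information,
    quad_correction,
    reduce_state,
)
from leuplat.lattice import GridSpec, neighbor_aggregate
from leuplat.ndj import NDJParams, NDJState
from leuplat.synthetic import GaussianLatticeSpec, make_gaussian_xy


def g_reference(N, L, Next, Lext, p):
    """Independent scalar re-evaluation of the linearized intrinsic flow."""
    alpha = p.kT / p.gammaI
    arg = alpha * N * Lext - p.I0
    g1 = ((p.lamN + 1) * p.N0 / 2
          + p.nN * p.N0 * (p.lamN - 1) / (4 * p.I0) * arg
          - p.kC * N * L - p.kT * N * Lext)
    g2 = ((p.lamD + 1) * p.D0 / 2
          + p.nD * p.D0 * (p.lamD - 1) / (4 * p.I0) * arg
          + (p.lamJ + 1) * p.J0 / 2
          + p.nJ * p.J0 * (p.lamJ - 1) / (4 * p.I0) * arg
          - p.kC * N * L - p.kT * L * Next)
    return g1, g2


def fd_jacobian_Y(p, N, L, Next, Lext, h_rel=1e-5):
    jac = np.zeros((2, 2))
    y = [Next, Lext]
    for j in range(2):
        h = h_rel * max(abs(y[j]), 1.0)
        hi, lo = list(y), list(y)
        hi[j] += h
        lo[j] -= h
        g_hi = g_tilde(N, L, hi[0], hi[1], p)
        g_lo = g_tilde(N, L, lo[0], lo[1], p)
        jac[0, j] = (g_hi[0] - g_lo[0]) / (2 * h)
        jac[1, j] = (g_hi[1] - g_lo[1]) / (2 * h)
    return jac


def test_g_tilde_at_expansion_point():
    # alpha*N*Lext = I0 kills the Taylor increment
    p = NDJParams(D0=1200.0, J0=900.0)
    N, L, Next, Lext = 1000.0, 1500.0, 800.0, 2000.0
    assert p.alpha * N * Lext == pytest.approx(p.I0)
    g1, g2 = g_tilde(N, L, Next, Lext, p)
    assert g1 == pytest.approx((p.lamN + 1) * p.N0 / 2 - p.kC * N * L - p.kT * N * Lext)
    assert g2 == pytest.approx((p.lamD + 1) * p.D0 / 2 + (p.lamJ + 1) * p.J0 / 2
                               - p.kC * N * L - p.kT * L * Next)


def test_g_tilde_trivial_fold_changes():
    p = NDJParams(D0=1000.0, J0=500.0, lamN=1.0, lamD=1.0, lamJ=1.0)
    g1, g2 = g_tilde(700.0, 1200.0, 600.0, 900.0, p)
    assert g1 == pytest.approx(p.N0 - p.kC * 700 * 1200 - p.kT * 700 * 900)
    assert g2 == pytest.approx(p.D0 + p.J0 - p.kC * 700 * 1200 - p.kT * 1200 * 600)


def test_g_tilde_matches_independent_oracle():
    p = NDJParams()
    ours = g_tilde(1000.0, 1500.0, 1000.0, 1500.0, p)
    ref = g_reference(1000.0, 1500.0, 1000.0, 1500.0, p)
    assert ours[0] == pytest.approx(ref[0], rel=1e-12)
    assert ours[1] == pytest.approx(ref[1], rel=1e-12)


def test_drift_det_dY_closed_form():
    # lamN=1 removes the Hill slope: |det| = kT^2 N L
    p = NDJParams(lamN=1.0)
    assert drift_det_dY(p, 1000.0, 1000.0) == pytest.approx(2.5e-3, rel=1e-9)
    assert drift_det_dY(p, 0.0, 1000.0) == 0.0


def test_drift_det_dY_against_fd_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        p = NDJParams(
            D0=rng.uniform(500, 2000), J0=rng.uniform(200, 1300),
            lamN=rng.uniform(1.1, 3.0), lamJ=rng.uniform(1.1, 3.0),
        )
        N, L = rng.uniform(100, 5000, size=2)
        Next, Lext = rng.uniform(100, 5000, size=2)
        fd = abs(np.linalg.det(fd_jacobian_Y(p, N, L, Next, Lext)))
        assert drift_det_dY(p, N, L) == pytest.approx(fd, rel=1e-4)


def test_drift_jacobian_X_degenerate_cases():
    # no couplings, flat Hills: G constant in X
    p = NDJParams(kT=0.0, kC=0.0, lamN=1.0, lamD=1.0, lamJ=1.0)
    np.testing.assert_allclose(drift_jacobian_X(p, 1000.0, 1000.0, 1000.0, 1000.0),
                               0.0, atol=1e-9)
    # cis-inhibition only: rank-1 Jacobian, zero determinant
    p = NDJParams(kT=0.0, lamN=1.0, lamD=1.0, lamJ=1.0)
    det = drift_det_dX(p, 1000.0, 1500.0, 1000.0, 1000.0)
    assert det == pytest.approx(0.0, abs=1e-6)


def test_drift_jacobian_X_fd_matches_analytic():
    rng = np.random.default_rng(23)
    for _ in range(50):
        p = NDJParams(D0=rng.uniform(500, 2000), J0=rng.uniform(200, 1300))
        N, L, Next, Lext = rng.uniform(100, 5000, size=4)
        fd = drift_jacobian_X(p, N, L, Next, Lext, method="fd")
        an = drift_jacobian_X(p, N, L, Next, Lext, method="analytic")
        np.testing.assert_allclose(fd, an, rtol=1e-4, atol=1e-10)


def test_reduce_state_linearity(grid5, moore1):
    rng = np.random.default_rng(2)
    state = NDJState(*(rng.uniform(0, 2000, grid5.shape) for _ in range(4)))
    red = reduce_state(state, grid5, moore1)
    np.testing.assert_allclose(red.Lin, state.D + state.J)
    np.testing.assert_allclose(
        red.Lext,
        neighbor_aggregate(state.D, grid5, moore1, "mean")
        + neighbor_aggregate(state.J, grid5, moore1, "mean"),
        rtol=1e-12,
    )
    const = NDJState(*(np.full(grid5.shape, v) for v in (3.0, 4.0, 5.0, 0.0)))
    red = reduce_state(const, grid5, moore1)
    np.testing.assert_allclose(red.Next, 3.0)
    np.testing.assert_allclose(red.Lext, 9.0)


def test_conditional_covariance_independent_limit():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(20000, 2))
    Y = rng.normal(size=(20000, 2))
    cov = covariances_from_samples(X, Y)
    np.testing.assert_allclose(cov.SigmaY_given_X, cov.SigmaY, atol=0.05)
    assert mutual_information(cov) < 0.01


def test_conditional_covariance_deterministic_limit():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(5000, 2))
    A = np.array([[1.0, 0.5], [-0.2, 2.0]])
    Y = X @ A.T
    cov = covariances_from_samples(X, Y)
    assert abs(np.linalg.det(cov.SigmaY_given_X)) < 1e-12 * np.linalg.det(cov.SigmaY)


def test_gaussian_fixture_recovery():
    spec = GaussianLatticeSpec(
        n_cells=10000,
        SigmaX=np.array([[2.0, 0.6], [0.6, 1.0]]),
        SigmaY_given_X=np.array([[1.0, 0.2], [0.2, 0.8]]),
        coupling=np.array([[0.8, -0.4], [0.3, 1.2]]),
        seed=31,
    )
    X, Y = make_gaussian_xy(spec)
    cov = covariances_from_samples(X, Y)
    det_true = np.linalg.det(spec.SigmaY_given_X)
    assert np.linalg.det(cov.SigmaY_given_X) == pytest.approx(det_true, rel=0.1)
    mi = mutual_information(cov)
    mi_true = 0.5 * math.log(np.linalg.det(spec.implied_SigmaY) / det_true)
    assert mi == pytest.approx(mi_true, rel=0.15)
    assert mi >= 0.0


def test_singular_covariance_rejected(grid5, moore1):
    const = NDJState(*(np.full(grid5.shape, v) for v in (3.0, 4.0, 5.0, 0.0)))
    with pytest.raises(SingularCovarianceError):
        lattice_covariances(reduce_state(const, grid5, moore1))


def test_mutual_information_log_arithmetic():
    cov = CovarianceSet(
        SigmaX=np.eye(2), SigmaY=np.diag([np.e, 1.0]),
        SigmaXY=np.zeros((2, 2)), SigmaYX=np.zeros((2, 2)),
        SigmaY_given_X=np.diag([1.0 / np.e, 1.0]),
    )
    # det SigmaY = e^2 * det SigmaY|X  =>  I = 1
    assert mutual_information(cov) == pytest.approx(1.0)
    assert external_entropy(cov) == pytest.approx(
        0.5 * math.log((2 * math.pi * math.e) ** 2 * np.e)
    )


def test_capacity_constant_values():
    assert capacity_constant(5000 * math.sqrt(2), 2) == pytest.approx(
        math.log(5000 * math.sqrt(2)) + 1.0
    )
    assert capacity_constant(5000 * math.sqrt(2), 2) == pytest.approx(9.864, abs=1e-3)
    assert capacity_constant(1.0, 0) == 0.0
    assert capacity_constant(math.e, 2) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        capacity_constant(0.0, 2)


def test_estimate_beta_arithmetic():
    c = capacity_constant(5000 * math.sqrt(2), 2)
    assert estimate_beta(ln_det_dY=c - 4.0, S_Y=4.0, c=c, mi=0.5) == pytest.approx(0.0)
    assert estimate_beta(-5.0, 4.0, 9.864, 0.5) == pytest.approx(21.728)
    with pytest.raises(UndefinedBetaError):
        estimate_beta(-5.0, 4.0, 9.864, 1e-12)


def test_quad_correction_cases(grid5, moore1):
    # constant external field: Y equals its neighbor mean exactly
    red = ReducedState(*(np.full(grid5.shape, v) for v in (5.0, 5.0, 3.0, 4.0)))
    assert quad_correction(red, np.eye(2), grid5, moore1) == 0.0
    # a random non-steady field gives a strictly positive quadratic form
    rng = np.random.default_rng(12)
    red = ReducedState(*(rng.uniform(1, 10, grid5.shape) for _ in range(4)))
    assert quad_correction(red, np.eye(2), grid5, moore1) > 0.0
    with pytest.raises(SingularCovarianceError):
        quad_correction(red, np.zeros((2, 2)), grid5, moore1)


def test_boundary_quantity_wiring(grid5):
    p = NDJParams(D0=1600.0, J0=700.0)
    rng = np.random.default_rng(4)
    red = ReducedState(*(rng.uniform(500, 2000, grid5.shape) for _ in range(4)))
    Nns, Lns, Next, Lext = red.means
    expected = (math.log(drift_det_dX(p, Nns, Lns, Next, Lext))
                - math.log(drift_det_dY(p, Nns, Lns)))
    assert boundary_quantity(p, red) == pytest.approx(expected, rel=1e-12)
    zero = ReducedState(np.zeros((3, 3)), np.zeros((3, 3)),
                        np.zeros((3, 3)), np.zeros((3, 3)))
    with pytest.raises(DegenerateSteadyStateError):
        boundary_quantity(p, zero)


def test_beta_pipeline_on_simulated_state(converged_induction_run, grid12):
    params, traj = converged_induction_run
    comp = beta_from_state(traj.final, params, grid12)
    assert comp.c == pytest.approx(math.log(comp.M) + comp.d / 2)
    assert comp.mi > 0
    assert comp.beta == pytest.approx(
        -(comp.ln_det_dY + comp.S_Y - comp.c) / comp.mi
    )
    assert comp.boundary_q == pytest.approx(comp.ln_det_dX - comp.ln_det_dY)
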