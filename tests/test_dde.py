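"""Solver checks against the classical scalar test problem
y'(t) = -y(t - 1), y = 1 for t <= 0, whose exact solution is the
piecewise polynomial produced by the method of steps."""
import numpy as np
import pytest
from numba import njit

import pilsync as ps
from pilsync.dde import solve_test_dde


@njit(cache=True)
def _neg_lag_rhs(t, y, ylag, p, rep):
    return -1.0 * ylag


def exact_solution(t_grid, horizon):
    """Method-of-steps oracle: integrate segment polynomials exactly."""
    from numpy.polynomial import Polynomial

    segs = [Polynomial([1.0])]  # y(k + s) on s in [0, 1]
    for _ in range(int(np.ceil(horizon))):
        prev = segs[-1]
        integ = prev.integ()
        start = segs[-1](1.0) if len(segs) > 1 else 1.0
        segs.append(Polynomial([start]) - integ)
    # segs[0] is history on [-1, 0]; y(t) for t in [k, k+1] uses segs[k+1]
    out = np.empty_like(t_grid)
    for i, t in enumerate(t_grid):
        if t <= 0:
            out[i] = 1.0
        else:
            k = min(int(np.floor(t - 1e-12)), len(segs) - 2)
            out[i] = segs[k + 1](t - k)
    return out


@pytest.fixture(scope="module")
def scalar_solution():
    tq, Y = solve_test_dde(_neg_lag_rhs, [1.0], tau=1.0, t_end=4.0, output_dt=0.01)
    return tq, Y[:, 0]


def test_scalar_dde_known_values(scalar_solution):
    tq, y = scalar_solution
    assert y[np.searchsorted(tq, 1.0)] == pytest.approx(0.0, abs=1e-8)
    assert y[np.searchsorted(tq, 2.0)] == pytest.approx(-0.5, abs=1e-8)


def test_scalar_dde_max_error(scalar_solution):
    tq, y = scalar_solution
    assert np.max(np.abs(y - exact_solution(tq, 4.0))) < 1e-6


def test_linear_segment_interpolation(scalar_solution):
    # y(t) = 1 - t on [0, 1]; the dense output reproduces the midpoint
    tq, y = scalar_solution
    i = np.searchsorted(tq, 0.55)
    assert y[i] == pytest.approx(0.45, abs=1e-9)


def test_tightening_tolerances_never_hurts():
    horizon = 10.0  # long enough that truncation error is nontrivial
    errs = []
    for rtol in (1e-3, 1e-6, 1e-9):
        tq, Y = solve_test_dde(
            _neg_lag_rhs, [1.0], tau=1.0, t_end=horizon, output_dt=0.01,
            rel_tol=rtol, abs_tol=rtol * 1e-2,
        )
        errs.append(np.max(np.abs(Y[:, 0] - exact_solution(tq, horizon))))
    assert errs[0] >= errs[1] >= errs[2]


def test_equilibrium_state_stays_put():
    # with dimerization off, the closed-form fixed point is invariant;
    # start there (history included) and check nothing moves
    p = ps.ParameterSet().replace(gamma_aB=0.0, gamma_aAB=0.0, gamma_aAF=0.0)
    y = np.zeros(10)
    y[0] = p.alpha_BR / p.delta_BR
    y[1] = p.alpha_bin / (p.delta_bin + p.delta_brb * y[0])
    y[2] = p.alpha_BZR / (p.delta_bzr + p.delta_bzb * y[1])
    y[9] = p.alpha_bP / (p.delta_PIL + p.delta_PBR * y[0])
    y[5] = p.alpha_A / (p.delta_A + p.T * y[9])
    y[6] = p.alpha_bx / (p.delta_bx + p.delta_aux * y[5])
    y[7] = p.alpha_ARF / (p.delta_ARF + p.theta * y[6])
    # note: lagged channels (BZR^D, ARF^D) are zero at this point, matching
    # a constant history equal to the fixed point
    traj = ps.integrate(p, ps.ScenarioSpec(), history=ps.HistorySpec(y), t_end=300.0)
    assert np.max(np.abs(traj.states - y[None, :])) < 1e-6


def test_full_model_stays_bounded(wt_trajectory):
    assert wt_trajectory.states.min() >= -1e-9
    assert wt_trajectory.states.max() < 1e6
    assert wt_trajectory.times[0] == 0.0
    assert wt_trajectory.times[-1] == 300.0
    assert len(wt_trajectory.times) == 3001


def test_integration_determinism(ref_params):
    a = ps.integrate(ref_params, ps.ScenarioSpec(), t_end=50.0)
    b = ps.integrate(ref_params, ps.ScenarioSpec(), t_end=50.0)
    np.testing.assert_array_equal(a.states, b.states)


def test_query_grid_time_exact(wt_trajectory):
    i = 1234
    t = wt_trajectory.times[i]
    np.testing.assert_array_equal(ps.query(wt_trajectory, t), wt_trajectory.states[i])


def test_query_out_of_range(wt_trajectory):
    with pytest.raises(ValueError):
        ps.query(wt_trajectory, -1.0)
    with pytest.raises(ValueError):
        ps.query(wt_trajectory, 300.1)


def test_integration_failure_carries_time(ref_params):
    with pytest.raises(ps.IntegrationError) as exc:
        ps.integrate(ref_params, ps.ScenarioSpec(), t_end=300.0, max_steps=50)
    assert 0.0 <= exc.value.time <= 300.0


def test_invalid_arguments_rejected(ref_params):
    with pytest.raises(ValueError):
        ps.integrate(ref_params, t_end=-1.0)
    with pytest.raises(ValueError):
        ps.integrate(ref_params, t_end=10.0, output_dt=0.0)
    with pytest.raises(ValueError):
        ps.HistorySpec(np.array([-1.0] * 10))
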