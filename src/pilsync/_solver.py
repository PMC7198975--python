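"""Low-level constant-lag DDE integrator (method of steps).

An embedded Dormand-Prince 5(4) pair with its quartic dense-output
interpolant, stepped adaptively.  The lagged state is evaluated from the
solver's own accepted-step interpolants (binary search over step start
times), which is exact method-of-steps continuation because steps never
exceed the lag and always land on the discontinuity mesh t = k * tau.
Everything here is numba-compiled; the friendly wrapper lives in
:mod:`pilsync.dde`.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["solve_dde", "dense_sample", "STATUS_OK", "STATUS_UNDERFLOW", "STATUS_MAXSTEPS",
           "STATUS_NONFINITE"]

STATUS_OK = 0
STATUS_UNDERFLOW = 1
STATUS_MAXSTEPS = 2
STATUS_NONFINITE = 3

# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B = _A[6].copy()
_E = np.array([71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40])
# quartic interpolant coefficients (order-4 dense output of the pair)
_P = np.array([
    [1.0, -8048581381 / 2820520608, 8663915743 / 2820520608, -12715105075 / 11282082432],
    [0.0, 0.0, 0.0, 0.0],
    [0.0, 131558114200 / 32700410799, -68118460800 / 10900136933, 87487479700 / 32700410799],
    [0.0, -1754552775 / 470086768, 14199869525 / 1410260304, -10690763975 / 1880347072],
    [0.0, 127303824393 / 49829197408, -318862633887 / 49829197408, 701980252875 / 199316789632],
    [0.0, -282668133 / 205662961, 2019193451 / 616988883, -1453857185 / 822651844],
    [0.0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
])


@njit(cache=True)
def _interp_step(t0, h, y0, Q, t):
    """Evaluate one step's dense-output polynomial at t in [t0, t0 + h]."""
    x = (t - t0) / h
    n = y0.shape[0]
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        xp = x
        for j in range(4):
            acc += Q[i, j] * xp
            xp *= x
        out[i] = y0[i] + h * acc
    return out


@njit(cache=True)
def _state_at(tq, hist, t_start, nacc, ts, hs, y0s, Qs):
    """Solution (or constant history) at any past time tq."""
    if nacc == 0 or tq <= t_start:
        return hist.copy()
    lo, hi = 0, nacc - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if ts[mid] <= tq:
            lo = mid
        else:
            hi = mid - 1
    t0 = ts[lo]
    h = hs[lo]
    if tq > t0 + h:
        tq = t0 + h
    return _interp_step(t0, h, y0s[lo], Qs[lo], tq)


@njit(cache=True)
def solve_dde(rhs, pvec, rep, hist, tau, mesh, rtol, atol, max_steps):
    """Integrate y' = rhs(t, y, y(t - tau), pvec, rep) over the mesh span.

    ``hist`` is the constant history for t <= mesh[0]; ``mesh`` is a strictly
    increasing array of times the solver must land on exactly (the
    discontinuity points k * tau plus the horizon).  Returns
    ``(status, fail_time, nacc, ts, hs, y0s, Qs, naccept, nreject)`` where
    the step arrays define the piecewise dense output.
    """
    n = hist.shape[0]
    cap = 4096
    ts = np.empty(cap)
    hs = np.empty(cap)
    y0s = np.empty((cap, n))
    Qs = np.empty((cap, n, 4))
    K = np.empty((7, n))

    t_start = mesh[0]
    t_end = mesh[-1]
    t = t_start
    y = hist.copy()
    max_step = tau if tau < (t_end - t_start) else (t_end - t_start)
    h = min(1e-2, max_step)
    nacc = 0
    nrej = 0
    imesh = 1
    fcur = rhs(t, y, hist, pvec, rep)

    while t < t_end - 1e-12:
        if nacc >= cap:
            cap2 = cap * 2
            ts2 = np.empty(cap2)
            hs2 = np.empty(cap2)
            y0s2 = np.empty((cap2, n))
            Qs2 = np.empty((cap2, n, 4))
            ts2[:cap] = ts
            hs2[:cap] = hs
            y0s2[:cap] = y0s
            Qs2[:cap] = Qs
            ts, hs, y0s, Qs, cap = ts2, hs2, y0s2, Qs2, cap2
        if nacc + nrej > max_steps:
            return STATUS_MAXSTEPS, t, nacc, ts, hs, y0s, Qs, nacc, nrej

        tb = mesh[imesh]
        if h > max_step:
            h = max_step
        hstep = h
        if t + hstep >= tb - 1e-12:
            hstep = tb - t
        if hstep < 1e-13 * max(1.0, abs(t)):
            return STATUS_UNDERFLOW, t, nacc, ts, hs, y0s, Qs, nacc, nrej

        # stages; each lagged argument lies in already-completed territory
        for i in range(7):
            if i == 0:
                K[0] = fcur
                continue
            yi = y.copy()
            for j in range(i):
                aij = _A[i, j]
                if aij != 0.0:
                    for m in range(n):
                        yi[m] += hstep * aij * K[j, m]
            tq = t + _C[i] * hstep - tau
            ylag = _state_at(tq, hist, t_start, nacc, ts, hs, y0s, Qs)
            K[i] = rhs(t + _C[i] * hstep, yi, ylag, pvec, rep)

        ynew = y.copy()
        for j in range(7):
            bj = _B[j]
            if bj != 0.0:
                for m in range(n):
                    ynew[m] += hstep * bj * K[j, m]

        bad = False
        errn = 0.0
        for m in range(n):
            if not np.isfinite(ynew[m]):
                bad = True
                break
            e = 0.0
            for j in range(7):
                if _E[j] != 0.0:
                    e += _E[j] * K[j, m]
            e *= hstep
            sc = atol + rtol * max(abs(y[m]), abs(ynew[m]))
            q = e / sc
            errn += q * q
        if bad:
            if hstep < 2e-13 * max(1.0, abs(t)):
                return STATUS_NONFINITE, t, nacc, ts, hs, y0s, Qs, nacc, nrej
            h = hstep * 0.2
            nrej += 1
            continue
        errn = np.sqrt(errn / n)

        if errn <= 1.0:
            ts[nacc] = t
            hs[nacc] = hstep
            for m in range(n):
                y0s[nacc, m] = y[m]
                for c in range(4):
                    acc = 0.0
                    for j in range(7):
                        acc += K[j, m] * _P[j, c]
                    Qs[nacc, m, c] = acc
            nacc += 1
            t = t + hstep
            y = ynew
            fcur = K[6].copy()  # FSAL
            if t >= tb - 1e-12:
                t = tb
                imesh += 1
                # lagged channel derivative may jump at mesh points
                ylag = _state_at(t - tau, hist, t_start, nacc, ts, hs, y0s, Qs)
                fcur = rhs(t, y, ylag, pvec, rep)
            if errn > 1e-10:
                fac = 0.9 * errn ** -0.2
                if fac > 10.0:
                    fac = 10.0
            else:
                fac = 10.0
            h = hstep * fac
        else:
            nrej += 1
            fac = 0.9 * errn ** -0.2
            if fac < 0.2:
                fac = 0.2
            h = hstep * fac

    return STATUS_OK, t, nacc, ts, hs, y0s, Qs, nacc, nrej


@njit(cache=True)
def dense_sample(tq_arr, hist, t_start, nacc, ts, hs, y0s, Qs):
    """Sample the piecewise dense output at the given query times."""
    n = y0s.shape[1]
    out = np.empty((tq_arr.shape[0], n))
    for k in range(tq_arr.shape[0]):
        out[k] = _state_at(tq_arr[k], hist, t_start, nacc, ts, hs, y0s, Qs)
    return out
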