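"""Numba-compiled numerical core: reaction kinetics and the ODE integrator.

Everything in this module operates on plain float64 arrays so it can be
JIT-compiled and called hundreds of thousands of times from the optimizer
loops.  The public, documented surface lives in :mod:`rabswitch.model`.

The integrator is an adaptive second-order Rosenbrock scheme (the classic
ode23s pair: L-stable, one Jacobian factorization and three linear solves
per step) with an analytic 4x4 Jacobian and cubic-Hermite dense output at
the requested sample times.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# exponent clamp: sigmoid saturates instead of overflowing
_EXP_CLAMP = 700.0

# ode23s coefficients
_D = 1.0 / (2.0 + np.sqrt(2.0))
_E32 = 6.0 + np.sqrt(2.0)

# integrate() status codes
STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1
STATUS_TOO_MANY_STEPS = 2


@njit(cache=True)
def _sig(a):
    """1 / (1 + exp(a)) with the argument clamped to +-700."""
    if a > _EXP_CLAMP:
        a = _EXP_CLAMP
    elif a < -_EXP_CLAMP:
        a = -_EXP_CLAMP
    return 1.0 / (1.0 + np.exp(a))


@njit(cache=True)
def rates10(t, y, c):
    """The ten reaction rates v1..v10 at state y=(r5, R5, r7, R7), time t."""
    r5, R5, r7, R7 = y[0], y[1], y[2], y[3]
    sig2 = _sig((c[2] - R5) * c[3])
    R7p = R7 if R7 > 0.0 else 0.0
    P = R7p ** c[7]
    v = np.empty(10)
    v[0] = c[0]
    v[1] = c[1] * r5 * sig2 * (t / (100.0 + t))
    v[2] = c[4] * r5
    v[3] = c[5]
    v[4] = c[6] * r7 * P / (c[8] + P)
    v[5] = c[9] * r7 * _sig((c[10] - R5) * c[11])
    v[6] = c[12] * R5 * _sig((c[13] - R7) * c[14])
    v[7] = c[15] * r7
    v[8] = c[16] * R5
    v[9] = c[17] * R7
    return v


@njit(cache=True)
def rhs(t, y, c):
    """Time derivatives (dr5, dR5, dr7, dR7)/dt."""
    v = rates10(t, y, c)
    out = np.empty(4)
    out[0] = v[0] + v[6] + v[8] - v[1] - v[2]
    out[1] = v[1] - v[6] - v[8]
    out[2] = v[3] + v[9] - v[4] - v[5] - v[7]
    out[3] = v[4] + v[5] - v[9]
    return out


@njit(cache=True)
def jac(t, y, c):
    """Analytic Jacobian d(rhs)/dy, 4x4."""
    r5, R5, r7, R7 = y[0], y[1], y[2], y[3]
    tau = t / (100.0 + t)
    sig2 = _sig((c[2] - R5) * c[3])
    dv2_dr5 = c[1] * sig2 * tau
    dv2_dR5 = c[1] * r5 * tau * c[3] * sig2 * (1.0 - sig2)
    R7p = R7 if R7 > 0.0 else 0.0
    P = R7p ** c[7]
    dP = c[7] * R7p ** (c[7] - 1.0) if R7p > 0.0 else 0.0
    den = c[8] + P
    dv5_dr7 = c[6] * P / den
    dv5_dR7 = c[6] * r7 * c[8] * dP / (den * den)
    sig6 = _sig((c[10] - R5) * c[11])
    dv6_dr7 = c[9] * sig6
    dv6_dR5 = c[9] * r7 * c[11] * sig6 * (1.0 - sig6)
    sig7 = _sig((c[13] - R7) * c[14])
    dv7_dR5 = c[12] * sig7
    dv7_dR7 = c[12] * R5 * c[14] * sig7 * (1.0 - sig7)
    J = np.zeros((4, 4))
    J[0, 0] = -dv2_dr5 - c[4]
    J[0, 1] = dv7_dR5 + c[16] - dv2_dR5
    J[0, 3] = dv7_dR7
    J[1, 0] = dv2_dr5
    J[1, 1] = dv2_dR5 - dv7_dR5 - c[16]
    J[1, 3] = -dv7_dR7
    J[2, 1] = -dv6_dR5
    J[2, 2] = -dv5_dr7 - dv6_dr7 - c[15]
    J[2, 3] = c[17] - dv5_dR7
    J[3, 1] = dv6_dR5
    J[3, 2] = dv5_dr7 + dv6_dr7
    J[3, 3] = dv5_dR7 - c[17]
    return J


@njit(cache=True)
def dfdt(t, y, c):
    """Explicit time derivative of the RHS (only v2 carries the t/(100+t) ramp)."""
    r5, R5 = y[0], y[1]
    sig2 = _sig((c[2] - R5) * c[3])
    d = 100.0 + t
    dv2 = c[1] * r5 * sig2 * (100.0 / (d * d))
    out = np.zeros(4)
    out[0] = -dv2
    out[1] = dv2
    return out


@njit(cache=True)
def _solve4(W, b):
    """Solve the 4x4 system W x = b (Gaussian elimination, partial pivoting)."""
    A = W.copy()
    x = b.copy()
    for k in range(3):
        p = k
        amax = abs(A[k, k])
        for i in range(k + 1, 4):
            if abs(A[i, k]) > amax:
                amax = abs(A[i, k])
                p = i
        if p != k:
            for j in range(4):
                tmp = A[k, j]
                A[k, j] = A[p, j]
                A[p, j] = tmp
            tmp = x[k]
            x[k] = x[p]
            x[p] = tmp
        for i in range(k + 1, 4):
            m = A[i, k] / A[k, k]
            for j in range(k + 1, 4):
                A[i, j] -= m * A[k, j]
            x[i] -= m * x[k]
    out = np.empty(4)
    for i in range(3, -1, -1):
        s = x[i]
        for j in range(i + 1, 4):
            s -= A[i, j] * out[j]
        out[i] = s / A[i, i]
    return out


@njit(cache=True)
def integrate(c, y0, t_eval, rtol, atol, max_steps=500_000):
    """Integrate the switch model and sample the solution at ``t_eval``.

    Parameters are the 18 kinetic constants ``c``; the state starts from
    ``y0`` at ``t_eval[0]``.  Returns ``(status, Y)`` where ``Y`` has shape
    ``(len(t_eval), 4)``; ``status`` is nonzero on step-size underflow, a
    non-finite state, or exceeding ``max_steps`` step attempts (the caller
    maps any failure to a penalty or an exception).  The step cap exists
    because some infeasible parameter combinations drive the step size to
    near-stagnation without ever underflowing.
    """
    n_out = t_eval.shape[0]
    Y = np.empty((n_out, 4))
    t = t_eval[0]
    tend = t_eval[n_out - 1]
    y = y0.copy()
    f0 = rhs(t, y, c)
    iout = 0
    while iout < n_out and t_eval[iout] <= t:
        for j in range(4):
            Y[iout, j] = y[j]
        iout += 1
    h = 1e-3
    hmin = 1e-12
    n_steps = 0
    while t < tend and iout < n_out:
        n_steps += 1
        if n_steps > max_steps:
            return STATUS_TOO_MANY_STEPS, Y
        if h < hmin or not np.isfinite(h):
            return STATUS_STEP_UNDERFLOW, Y
        if t + h > tend:
            h = tend - t
        J = jac(t, y, c)
        T = dfdt(t, y, c)
        W = np.eye(4) - (h * _D) * J
        k1 = _solve4(W, f0 + (h * _D) * T)
        f1 = rhs(t + 0.5 * h, y + 0.5 * h * k1, c)
        k2 = _solve4(W, f1 - k1) + k1
        ynew = y + h * k2
        tnew = t + h
        f2 = rhs(tnew, ynew, c)
        k3 = _solve4(W, f2 - _E32 * (k2 - f1) - 2.0 * (k1 - f0) + (h * _D) * T)
        errnorm = 0.0
        finite = True
        for j in range(4):
            e = (h / 6.0) * (k1[j] - 2.0 * k2[j] + k3[j])
            ya = abs(y[j])
            yb = abs(ynew[j])
            sc = atol + rtol * (ya if ya > yb else yb)
            v = abs(e) / sc
            if not np.isfinite(v):
                finite = False
                break
            if v > errnorm:
                errnorm = v
        if finite and errnorm <= 1.0:
            # accept: cubic Hermite dense output on [t, tnew]
            while iout < n_out and t_eval[iout] <= tnew:
                s = (t_eval[iout] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) * (1.0 - s)
                h10 = s * (1.0 - s) * (1.0 - s)
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for j in range(4):
                    Y[iout, j] = (h00 * y[j] + h10 * h * f0[j]
                                  + h01 * ynew[j] + h11 * h * f2[j])
                iout += 1
            t = tnew
            y = ynew
            f0 = f2
            fac = 5.0 if errnorm == 0.0 else 0.8 * errnorm ** (-1.0 / 3.0)
            if fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            if not finite:
                h *= 0.1
            else:
                fac = 0.8 * errnorm ** (-1.0 / 3.0)
                if fac < 0.1:
                    fac = 0.1
                h *= fac
    return STATUS_OK, Y
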