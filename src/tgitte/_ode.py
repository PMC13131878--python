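"""Compiled adaptive RK45 integrator for the TGI ODE on log tumor volume.

Population estimation evaluates tens of thousands of tumor-volume
trajectories, so the right-hand side and a Dormand-Prince 5(4) stepper
are compiled with numba. The state is u = log TV; dose times and
requested output times are mandatory step boundaries, so the bolus
discontinuities in Cp(t) never fall inside a step and no dense output is
needed. The pure-scipy LSODA path in :mod:`tgitte.tgi` serves as an
independent cross-check of this integrator.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["integrate_log_tv"]


@njit(cache=True)
def _rhs(t, u, l0, l1, psi, k, kc50, c0, ke, dose_times):
    cp = 0.0
    if c0 > 0.0:
        for td in dose_times:
            if t >= td:
                cp += c0 * np.exp(-ke * (t - td))
    if kc50 > 0.0:
        effect = k * cp / (kc50 + cp)
    else:
        effect = k * cp
    x = psi * (u + np.log(l0 / l1))
    if x > 0.0:  # stable logaddexp(0, x) / psi
        lb = (x + np.log1p(np.exp(-x))) / psi
    else:
        lb = np.log1p(np.exp(x)) / psi
    return l0 * np.exp(-lb) - effect


# Dormand-Prince RK45 tableau
_C = np.array([0.0, 1.0 / 5, 3.0 / 10, 4.0 / 5, 8.0 / 9, 1.0, 1.0])
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3.0 / 40, 9.0 / 40, 0.0, 0.0, 0.0, 0.0],
        [44.0 / 45, -56.0 / 15, 32.0 / 9, 0.0, 0.0, 0.0],
        [19372.0 / 6561, -25360.0 / 2187, 64448.0 / 6561, -212.0 / 729, 0.0, 0.0],
        [9017.0 / 3168, -355.0 / 33, 46732.0 / 5247, 49.0 / 176, -5103.0 / 18656, 0.0],
    ]
)
_B5 = np.array([35.0 / 384, 0.0, 500.0 / 1113, 125.0 / 192, -2187.0 / 6784, 11.0 / 84, 0.0])
_B4 = np.array(
    [
        5179.0 / 57600,
        0.0,
        7571.0 / 16695,
        393.0 / 640,
        -92097.0 / 339200,
        187.0 / 2100,
        1.0 / 40,
    ]
)


@njit(cache=True)
def _step_interval(
    t0, t1, u0, l0, l1, psi, k, kc50, c0, ke, dose_times, rtol, atol
):
    """Integrate u' = f over [t0, t1] with adaptive RK45; return u(t1)."""
    t = t0
    u = u0
    h = t1 - t0
    kstages = np.empty(7)
    while t < t1:
        if t + h > t1:
            h = t1 - t
        # stages
        kstages[0] = _rhs(t, u, l0, l1, psi, k, kc50, c0, ke, dose_times)
        for s in range(1, 6):
            du = 0.0
            for j in range(s):
                du += _A[s, j] * kstages[j]
            kstages[s] = _rhs(t + _C[s] * h, u + h * du, l0, l1, psi, k, kc50, c0, ke, dose_times)
        u5 = u
        for j in range(6):
            u5 += h * _B5[j] * kstages[j]
        kstages[6] = _rhs(t + h, u5, l0, l1, psi, k, kc50, c0, ke, dose_times)
        u4 = u
        for j in range(7):
            u4 += h * _B4[j] * kstages[j]
        err = np.abs(u5 - u4)
        tol = atol + rtol * max(np.abs(u), np.abs(u5))
        if err <= tol or h <= 1e-10 * (t1 - t0 + 1.0):
            t = t + h
            u = u5
            if err > 0.0:
                fac = 0.9 * (tol / err) ** 0.2
            else:
                fac = 5.0
            h = h * min(5.0, max(0.2, fac))
        else:
            h = h * max(0.2, 0.9 * (tol / err) ** 0.2)
    return u


@njit(cache=True)
def integrate_log_tv(u0, knots, l0, l1, psi, k, kc50, c0, ke, dose_times, rtol, atol):
    """u = log TV at every knot time; knots sorted ascending, knots[0] = 0."""
    out = np.empty(len(knots))
    out[0] = u0
    u = u0
    for i in range(1, len(knots)):
        u = _step_interval(
            knots[i - 1], knots[i], u, l0, l1, psi, k, kc50, c0, ke, dose_times, rtol, atol
        )
        out[i] = u
    return out
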