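"""Fixed-step integrator for the fitting hot path.

Multi-start estimation evaluates the post-addition model trajectory tens
of thousands of times per product.  This module provides a compiled
classical Runge-Kutta (RK4) integrator for the ratio-dependent model so
the objective stays cheap; user-facing simulation (`model.simulate_assay`)
keeps the adaptive stiff-capable solver.  Agreement between the two
routes is asserted in the test suite.

The step size is the sampling interval divided by ``SUBSTEPS``; with
15-minute sampling and the bounded parameter space the fastest rates are
a few per hour, so the local truncation error is far below the data
noise floor.  States are clipped at zero before each rate evaluation,
matching the right-hand side used by the adaptive solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: RK4 substeps per output interval
SUBSTEPS = 4


@njit(cache=True)
def _rates(T, C, TC, kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd):
    if T < 0.0:
        T = 0.0
    if C < 0.0:
        C = 0.0
    if TC < 0.0:
        TC = 0.0
    # ratio-dependent Hill killing, written as 1/(1+(Kmr/r)^n) for
    # stability at extreme ratios
    fc = 0.0
    if T > 0.0 and C > 0.0:
        ratio = C / T
        denom = 1.0 + (Kmr / ratio) ** n
        if np.isfinite(denom):
            fc = kc * T / denom
    fp = 0.0
    if fc > 0.0:
        d2 = 1.0 + (Kmp / fc) ** 2
        if np.isfinite(d2):
            fp = kp2 * C / d2
    n_eff = C + TC
    if n_eff < 1.0:
        n_eff = 1.0
    g = np.log(CE / n_eff)
    dT = kp1 * T * (1.0 - T / CT) - fc
    dC = fp * g - kd * C
    dTC = -kd * TC
    return dT, dC, dTC


@njit(cache=True)
def integrate_grid(y0, params, t_grid, substeps):
    """RK4 integration of the ratio-dependent model on ``t_grid``.

    ``params`` is the 9-vector (kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd).
    Returns an array of shape ``(len(t_grid), 3)`` with columns
    (T, CART, TC); the first row equals ``y0``.
    """
    kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd = (
        params[0], params[1], params[2], params[3], params[4],
        params[5], params[6], params[7], params[8],
    )
    out = np.empty((t_grid.shape[0], 3))
    T, C, TC = y0[0], y0[1], y0[2]
    out[0, 0] = T
    out[0, 1] = C
    out[0, 2] = TC
    for i in range(t_grid.shape[0] - 1):
        h = (t_grid[i + 1] - t_grid[i]) / substeps
        for _ in range(substeps):
            k1 = _rates(T, C, TC, kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd)
            k2 = _rates(
                T + 0.5 * h * k1[0], C + 0.5 * h * k1[1], TC + 0.5 * h * k1[2],
                kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd,
            )
            k3 = _rates(
                T + 0.5 * h * k2[0], C + 0.5 * h * k2[1], TC + 0.5 * h * k2[2],
                kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd,
            )
            k4 = _rates(
                T + h * k3[0], C + h * k3[1], TC + h * k3[2],
                kp1, CT, kc, Kmr, n, kp2, Kmp, CE, kd,
            )
            T += h / 6.0 * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0])
            C += h / 6.0 * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1])
            TC += h / 6.0 * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2])
            if T < 0.0:
                T = 0.0
            if C < 0.0:
                C = 0.0
            if TC < 0.0:
                TC = 0.0
        out[i + 1, 0] = T
        out[i + 1, 1] = C
        out[i + 1, 2] = TC
    return out


def integrate_post_addition(y_add, params_array, t_rel, substeps=SUBSTEPS):
    """Post-addition trajectory from the state just after effector addition.

    ``t_rel`` are times relative to effector addition (first entry 0).
    """
    y0 = np.asarray(y_add, dtype=float)
    t = np.ascontiguousarray(t_rel, dtype=float)
    return integrate_grid(y0, np.asarray(params_array, dtype=float), t, substeps)
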