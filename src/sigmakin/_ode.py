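"""Jitted numerical kernels: Dormand-Prince 5(4) integration of the
transcription-control ODE, Pearson objective, and the simulated-annealing
chain.  Kept free of Python objects so a full annealing chain (tens of
thousands of ODE solves) runs in milliseconds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) coefficients (the pair behind Matlab's ode45).
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0


@njit(cache=True)
def _interp_clamped(t, xs, ys):
    n = xs.shape[0]
    if t <= xs[0]:
        return ys[0]
    if t >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= t:
            lo = mid
        else:
            hi = mid
    f = (t - xs[lo]) / (xs[hi] - xs[lo])
    return ys[lo] + f * (ys[hi] - ys[lo])


@njit(cache=True)
def _rhs(t, y, xs, rv, k1, k2, w, b):
    a = w * _interp_clamped(t, xs, rv) + b
    if a < -500.0:
        a = -500.0
    elif a > 500.0:
        a = 500.0
    return k1 / (1.0 + np.exp(-a)) - k2 * y


@njit(cache=True)
def dopri_solve(xs, rv, k1, k2, w, b, y0, t_eval, rtol, atol):
    """Integrate dy/dt = k1*sigmoid(w*R(t)+b) - k2*y on t_eval with DP 5(4).

    R(t) is piecewise linear through (xs, rv), clamped outside.  Adaptive
    step-size control with the standard embedded 4th-order error estimate.
    """
    n_out = t_eval.shape[0]
    out = np.empty(n_out)
    t = t_eval[0]
    y = y0
    out[0] = y
    f1 = _rhs(t, y, xs, rv, k1, k2, w, b)
    h_prop = 0.05
    for i in range(1, n_out):
        t_end = t_eval[i]
        while t < t_end - 1e-12:
            h = h_prop
            if h > t_end - t:
                h = t_end - t
            f2 = _rhs(t + _C2 * h, y + h * _A21 * f1, xs, rv, k1, k2, w, b)
            f3 = _rhs(t + _C3 * h, y + h * (_A31 * f1 + _A32 * f2), xs, rv, k1, k2, w, b)
            f4 = _rhs(t + _C4 * h, y + h * (_A41 * f1 + _A42 * f2 + _A43 * f3), xs, rv, k1, k2, w, b)
            f5 = _rhs(
                t + _C5 * h,
                y + h * (_A51 * f1 + _A52 * f2 + _A53 * f3 + _A54 * f4),
                xs, rv, k1, k2, w, b,
            )
            f6 = _rhs(
                t + h,
                y + h * (_A61 * f1 + _A62 * f2 + _A63 * f3 + _A64 * f4 + _A65 * f5),
                xs, rv, k1, k2, w, b,
            )
            y_new = y + h * (_B1 * f1 + _B3 * f3 + _B4 * f4 + _B5 * f5 + _B6 * f6)
            f7 = _rhs(t + h, y_new, xs, rv, k1, k2, w, b)
            err_raw = h * (
                _E1 * f1 + _E3 * f3 + _E4 * f4 + _E5 * f5 + _E6 * f6 + _E7 * f7
            )
            ay = abs(y)
            ayn = abs(y_new)
            scale = atol + rtol * (ay if ay > ayn else ayn)
            err = abs(err_raw) / scale
            if err <= 1.0:
                t += h
                y = y_new
                f1 = f7
                if err > 1e-30:
                    fac = 0.9 * err ** -0.2
                    if fac > 5.0:
                        fac = 5.0
                else:
                    fac = 5.0
                h_prop = h * fac
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h_prop = h * fac
            if h_prop < 1e-10:
                h_prop = 1e-10
        out[i] = y
    return out


@njit(cache=True)
def pearson(a, b):
    n = a.shape[0]
    ma = 0.0
    mb = 0.0
    for i in range(n):
        ma += a[i]
        mb += b[i]
    ma /= n
    mb /= n
    saa = 0.0
    sbb = 0.0
    sab = 0.0
    for i in range(n):
        da = a[i] - ma
        db = b[i] - mb
        saa += da * da
        sbb += db * db
        sab += da * db
    if saa <= 0.0 or sbb <= 0.0:
        return np.nan
    return sab / np.sqrt(saa * sbb)


@njit(cache=True)
def _objective_sim(y_meas, xs, rv, k1, k2, w, b, y0, rtol, atol):
    y_sim = dopri_solve(xs, rv, k1, k2, w, b, y0, xs, rtol, atol)
    c = pearson(y_meas, y_sim)
    if np.isnan(c):
        return 2.0  # constant simulated profile: worst case, keeps chain alive
    return 1.0 - c


@njit(cache=True, inline="always")
def _reflect(x, lo, hi):
    # fold a proposal back into [lo, hi] by reflection at the bounds
    span = hi - lo
    for _ in range(64):
        if x < lo:
            x = 2.0 * lo - x
        elif x > hi:
            x = 2.0 * hi - x
        else:
            return x
        if x < lo - 4.0 * span or x > hi + 4.0 * span:
            return lo + 0.5 * span
    return lo + 0.5 * span


@njit(cache=True)
def anneal_chain(
    y_meas,
    xs,
    rv,
    y0,
    p_init,
    scales,
    lo,
    hi,
    t0,
    alpha,
    n_per_temp,
    t_min,
    stop_f,
    seed,
    rtol,
    atol,
):
    """One simulated-annealing chain over (k1, k2, w, b).

    Gaussian single-parameter proposals with scale shrinking as sqrt(T),
    reflection into [lo, hi] per parameter (positivity of k1, k2, w),
    Metropolis acceptance on F = 1 - c.  Stops early once the best F
    reaches stop_f.  Deterministic per seed.
    """
    np.random.seed(seed)
    p = p_init.copy()
    f = _objective_sim(y_meas, xs, rv, p[0], p[1], p[2], p[3], y0, rtol, atol)
    best_p = p.copy()
    best_f = f
    temp = t0
    while temp > t_min:
        step = np.sqrt(temp)
        for _ in range(n_per_temp):
            j = np.random.randint(0, 4)
            old = p[j]
            cand = _reflect(old + np.random.normal() * scales[j] * step, lo[j], hi[j])
            p[j] = cand
            f_new = _objective_sim(y_meas, xs, rv, p[0], p[1], p[2], p[3], y0, rtol, atol)
            df = f_new - f
            if df <= 0.0 or np.random.random() < np.exp(-df / temp):
                f = f_new
                if f < best_f:
                    best_f = f
                    for q in range(4):
                        best_p[q] = p[q]
                    if best_f <= stop_f:
                        return best_p, best_f
            else:
                p[j] = old
        temp *= alpha
    return best_p, best_f
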