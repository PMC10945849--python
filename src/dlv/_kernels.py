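"""Numba kernels for the fixed-step log-domain Euler integrators.

All integrators advance y = ln(x), so x = exp(y) stays strictly positive
for any step size and immigration rate.  The per-step derivative is

    dy/dt = 1 - x - (A @ x) - ... + lam / x

with A the coupling matrix whose diagonal is exactly zero (so the matrix
product equals the sum over j != i).
"""

from __future__ import annotations

import numpy as np
from numba import njit

DIVERGED = 1
NONFINITE = 2


@njit
def lv_step(A, y, x, dt, lam):
    """Advance y = ln x one step; returns max of y (checked pre-exp so a
    runaway state is caught before exp overflows)."""
    c = np.dot(A, x)
    S = y.shape[0]
    ymax = -1e300
    for i in range(S):
        y[i] += dt * (1.0 - x[i] - c[i] + lam / x[i])
        if y[i] > ymax:
            ymax = y[i]
    if ymax < 700.0:
        for i in range(S):
            x[i] = np.exp(y[i])
    return ymax


@njit
def integrate_lv(A, y0, dt, n_burn, n_run, stride, lam, div_threshold):
    """Integrate the community; record every `stride` steps after burn-in.

    Returns (stored, n_stored, status, t_stop):
    status 0 = completed, 1 = diverged (abundance above div_threshold),
    2 = non-finite state.  t_stop is the time of early termination.
    """
    S = y0.shape[0]
    y = y0.copy()
    x = np.exp(y)
    y_cap = np.log(div_threshold)
    n_store = n_run // stride
    stored = np.empty((n_store, S))
    k = 0
    for step in range(n_burn + n_run):
        ymax = lv_step(A, y, x, dt, lam)
        if not np.isfinite(ymax):
            return stored, k, NONFINITE, (step + 1) * dt
        if ymax > y_cap:
            return stored, k, DIVERGED, (step + 1) * dt
        s = step + 1 - n_burn
        if s > 0 and s % stride == 0 and k < n_store:
            stored[k] = x
            k += 1
    return stored, k, 0, (n_burn + n_run) * dt


@njit
def relax_to_equilibrium(A, y0, dt, tol, t_max):
    """Integrate with lam = 0 until max_i |dx_i/dt| < tol or t_max.

    Returns (x, converged, diverged).
    """
    S = y0.shape[0]
    y = y0.copy()
    x = np.exp(y)
    n_max = int(t_max / dt)
    for step in range(n_max):
        c = np.dot(A, x)
        vmax = 0.0
        xmax = 0.0
        for i in range(S):
            dy = 1.0 - x[i] - c[i]
            v = x[i] * dy
            if abs(v) > vmax:
                vmax = abs(v)
            y[i] += dt * dy
            x[i] = np.exp(y[i])
            if x[i] > xmax:
                xmax = x[i]
        if not np.isfinite(xmax) or xmax > 1e6:
            return x, False, True
        if vmax < tol:
            return x, True, False
    return x, False, False


@njit
def lyapunov_benettin(A, y0, dt, n_burn, n_total, eps, renorm_every, lam):
    """Two-trajectory maximal Lyapunov estimate in log-abundance space.

    A companion state is offset by `eps` (L2 in ln x), both are advanced
    together, and every `renorm_every` steps the log-separation growth is
    recorded and the companion is rescaled back to distance eps.

    Returns (episode_rates, n_episodes, status).
    """
    S = y0.shape[0]
    y_cap = np.log(1e6)
    y = y0.copy()
    x = np.exp(y)
    for step in range(n_burn):
        ymax = lv_step(A, y, x, dt, lam)
        if not np.isfinite(ymax) or ymax > y_cap:
            return np.zeros(1), 0, DIVERGED
    # companion offset along a fixed direction, normalized to eps
    y2 = y.copy()
    y2[0] += eps
    x2 = np.exp(y2)
    n_ep = n_total // renorm_every
    rates = np.empty(n_ep)
    k = 0
    for ep in range(n_ep):
        for step in range(renorm_every):
            ymax = lv_step(A, y, x, dt, lam)
            ymax2 = lv_step(A, y2, x2, dt, lam)
            if not (np.isfinite(ymax) and np.isfinite(ymax2)) or ymax > y_cap:
                return rates, k, DIVERGED
        d = 0.0
        for i in range(S):
            d += (y2[i] - y[i]) ** 2
        d = np.sqrt(d)
        if d == 0.0:
            d = 1e-300
        rates[k] = np.log(d / eps) / (renorm_every * dt)
        k += 1
        f = eps / d
        for i in range(S):
            y2[i] = y[i] + (y2[i] - y[i]) * f
            x2[i] = np.exp(y2[i])
    return rates, k, 0


@njit
def integrate_focal(k, u, lam, eta, dt, stride):
    """Log-Euler focal-species SDE driven by a precomputed OU path.

    dx/dt = x * (-k + u * eta(t) - x) + lam, advanced as y = ln x.
    Returns (stored series, full-resolution time-mean of x).
    """
    n = eta.shape[0]
    y = np.log(lam / max(k, 1e-3)) if k > 0 else 0.0
    x = np.exp(y)
    n_store = n // stride
    out = np.empty(n_store)
    acc = 0.0
    m = 0
    for step in range(n):
        y += dt * (-k + u * eta[step] - x + lam / x)
        x = np.exp(y)
        acc += x
        s = step + 1
        if s % stride == 0 and m < n_store:
            out[m] = x
            m += 1
    return out, acc / n
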