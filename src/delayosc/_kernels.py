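"""Numba-compiled inner loops: fixed-step DDE schemes and the pair sums of
the correlation integral. Model kinds are passed as integer codes
(synthesis: 0 monotonic, 1 non-monotonic; degradation: 0 saturable,
1 non-saturable) so one compiled kernel serves the whole family."""

from __future__ import annotations

import numpy as np
from numba import njit

SYN_MONOTONIC = 0
SYN_NON_MONOTONIC = 1
DEG_SATURABLE = 0
DEG_NON_SATURABLE = 1


@njit(cache=True, inline="always")
def _rhs(syn, deg, beta, gamma, n, x_delayed, x_now):
    if syn == SYN_MONOTONIC:
        f = beta / (1.0 + x_delayed**n)
    else:
        f = beta * x_delayed / (1.0 + x_delayed**n)
    if deg == DEG_SATURABLE:
        g = gamma * x_now / (1.0 + x_now)
    else:
        g = gamma * x_now
    return f - g


@njit(cache=True)
def euler_dde(syn, deg, beta, gamma, n, history, nsteps, dt):
    """Explicit Euler. ``history`` holds x at the d+1 grid nodes t<=0 where
    d = len(history)-1 is the delay in steps. Returns the full node array
    (history included) and the index of the first non-finite value (-1 if
    none)."""
    d = history.shape[0] - 1
    out = np.empty(d + nsteps + 1)
    out[: d + 1] = history
    for k in range(d, d + nsteps):
        xd = out[k - d]
        x = out[k]
        xn = x + dt * _rhs(syn, deg, beta, gamma, n, xd, x)
        if not np.isfinite(xn):
            out[k + 1 :] = np.nan
            return out, k + 1
        out[k + 1] = xn
    return out, -1


@njit(cache=True)
def rk4_dde(syn, deg, beta, gamma, n, history, nsteps, dt):
    """Classical RK4 with linear interpolation of the stored past for the
    half-step delayed values. For zero delay the delayed coordinate is the
    current stage state (plain ODE)."""
    d = history.shape[0] - 1
    out = np.empty(d + nsteps + 1)
    out[: d + 1] = history
    for k in range(d, d + nsteps):
        x = out[k]
        if d == 0:
            k1 = _rhs(syn, deg, beta, gamma, n, x, x)
            x2 = x + 0.5 * dt * k1
            k2 = _rhs(syn, deg, beta, gamma, n, x2, x2)
            x3 = x + 0.5 * dt * k2
            k3 = _rhs(syn, deg, beta, gamma, n, x3, x3)
            x4 = x + dt * k3
            k4 = _rhs(syn, deg, beta, gamma, n, x4, x4)
        else:
            xd0 = out[k - d]
            xd1 = out[k - d + 1]
            xdh = 0.5 * (xd0 + xd1)
            k1 = _rhs(syn, deg, beta, gamma, n, xd0, x)
            k2 = _rhs(syn, deg, beta, gamma, n, xdh, x + 0.5 * dt * k1)
            k3 = _rhs(syn, deg, beta, gamma, n, xdh, x + 0.5 * dt * k2)
            k4 = _rhs(syn, deg, beta, gamma, n, xd1, x + dt * k3)
        xn = x + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(xn):
            out[k + 1 :] = np.nan
            return out, k + 1
        out[k + 1] = xn
    return out, -1


@njit(cache=True)
def correlation_counts(x, m_max, lag, theiler, epsilons):
    """Pair counts of the correlation sum for all embedding dimensions
    1..m_max at once.

    For each admissible pair (i, j) with j - i > theiler the max-norm
    distance is accumulated coordinate by coordinate, so the distance for
    embedding dimension m is the running maximum after m coordinates. Counts
    are histogrammed on the (sorted, log-spaced) ``epsilons`` grid; entry
    [m-1, e] is the number of pairs with distance < epsilons[e].

    Returns (counts[m_max, n_eps], n_pairs). All dimensions share the vector
    count N - (m_max - 1) * lag so every m sees the same pair set.
    """
    n_eps = epsilons.shape[0]
    nv = x.shape[0] - (m_max - 1) * lag
    counts = np.zeros((m_max, n_eps), dtype=np.int64)
    n_pairs = 0
    for i in range(nv):
        for j in range(i + theiler + 1, nv):
            n_pairs += 1
            dist = 0.0
            for m in range(m_max):
                dv = abs(x[i + m * lag] - x[j + m * lag])
                if dv > dist:
                    dist = dv
                # first epsilon index with eps > dist (strict Heaviside)
                lo = 0
                hi = n_eps
                while lo < hi:
                    mid = (lo + hi) // 2
                    if epsilons[mid] > dist:
                        hi = mid
                    else:
                        lo = mid + 1
                if lo < n_eps:
                    counts[m, lo] += 1
    # histogram -> cumulative: pairs with dist < eps[e]
    for m in range(m_max):
        acc = 0
        for e in range(n_eps):
            acc += counts[m, e]
            counts[m, e] = acc
    return counts, n_pairs
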