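"""Switched-ODE reductions of the monotonic-synthesis delay models.

For large Hill coefficient the repressor synthesis term is nearly a step,
taking only two values. Replacing it with a binary switch variable s turns
the infinite chain of delayed coordinates u_k' = f(u_{k+1}) - g(u_k) into a
finite system:

first order (one ODE + switch)
    x' = s - g(x),   s in {s_high, s_low},
    with s flipping when x reaches the switching points X_A / X_B — the
    values the free flow reaches from the equilibrium x* after exactly one
    delay, i.e. the roots of  Int_{x*}^{X} dz / (s - g(z)) = tau;

second order (two ODEs + switch)
    u1' = f(u2) - g(u1),   u2' = s - g(u2),
    with s flipping when the phase point (u1, u2) crosses one of two
    boundary curves — the images of the bounding flows z' = s_level - g(z)
    run for one delay, between which every trajectory of the full DDE is
    pinned.

Switch levels are either the synthesis extremes (F_min, F_max) or, for the
non-saturable model, the self-consistent pair (rho1, rho2) solving
rho1 = f(rho2/gamma), rho2 = f(rho1/gamma) — the 2-cycle of the decreasing
one-delay return map, which tightens the step approximation at finite n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import IntegrationWarning, quad, solve_ivp
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .integrate import HistoryFunction, TimeSeries, integrate_dde
from .metrics import NoOscillationError, period_amplitude
from .models import (
    DegradationKind,
    ModelSpec,
    SynthesisKind,
    find_equilibria,
    synthesis_extremes,
)

__all__ = [
    "SwitchConfig",
    "SwitchPoints",
    "BoundaryCurve",
    "ReducedTrajectory",
    "ReductionConfigError",
    "LevelsError",
    "flow_map",
    "flow_time",
    "first_order_switch_points",
    "switch_points_by_quadrature",
    "self_consistent_levels",
    "first_order_period",
    "simulate_first_order",
    "boundary_curves",
    "simulate_second_order",
    "reduction_error_report",
]


class ReductionConfigError(ValueError):
    """Switch levels incompatible with a monotone approach/escape flow."""


class LevelsError(RuntimeError):
    """The self-consistent level system has no genuine two-cycle."""


@dataclass(frozen=True)
class SwitchConfig:
    """The two synthesis levels the switch variable alternates between."""

    s_high: float
    s_low: float
    mode: str = "extremes"  # "extremes" | "self_consistent"

    def __post_init__(self):
        if not (self.s_high > self.s_low >= 0):
            raise ValueError("need s_high > s_low >= 0")

    @classmethod
    def from_extremes(cls, spec: ModelSpec) -> "SwitchConfig":
        f_min, f_max = synthesis_extremes(spec)
        return cls(s_high=f_max, s_low=f_min, mode="extremes")


@dataclass(frozen=True)
class SwitchPoints:
    """Upper / lower turning values of the first-order reduction."""

    X_A: float
    X_B: float


@dataclass
class BoundaryCurve:
    """One switching curve in the (u1, u2) plane, stored as a polyline
    u1 = phi(u2) with monotone cubic interpolation."""

    side: str  # "lower" | "upper"
    u2: np.ndarray
    u1: np.ndarray
    _interp: PchipInterpolator = field(default=None, repr=False)

    def __post_init__(self):
        order = np.argsort(self.u2)
        self.u2 = np.asarray(self.u2, dtype=float)[order]
        self.u1 = np.asarray(self.u1, dtype=float)[order]
        self._interp = PchipInterpolator(self.u2, self.u1, extrapolate=True)

    def __call__(self, u2):
        return self._interp(u2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u1": self.u1, "u2": self.u2, "side": self.side})


@dataclass
class ReducedTrajectory:
    """Sampled reduced system: state columns, binary switch signal, events."""

    dt: float
    states: np.ndarray  # (n_samples, order)
    switch_signal: np.ndarray  # s value per sample
    switch_times: np.ndarray
    switch_values: np.ndarray  # s value adopted at each event
    order: int
    t0: float = 0.0
    chattering: bool = False

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.states))

    @property
    def u1(self) -> np.ndarray:
        return self.states[:, 0]

    def to_timeseries(self, transient: float = 0.0) -> TimeSeries:
        return TimeSeries(
            dt=self.dt,
            values=self.states[:, 0],
            t0=self.t0,
            transient_end=int(round(transient / self.dt)),
        )

    def event_period(self) -> float:
        """Mean spacing of same-direction switch events (one per cycle)."""
        if len(self.switch_times) < 3:
            raise NoOscillationError("fewer than three switch events")
        same = self.switch_times[::2]
        return float(np.mean(np.diff(same)))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.t}
        for k in range(self.order):
            cols[f"u{k + 1}"] = self.states[:, k]
        cols["s"] = self.switch_signal
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# scalar bounding flow x' = s - g(x)


def _flow_time_closed(spec: ModelSpec, s: float, x0: float, x1: float) -> float:
    """Closed-form travel time of x' = s - g(x) from x0 to x1 (same branch,
    no equilibrium in between)."""
    gam = spec.gamma
    if spec.degradation_kind is DegradationKind.NON_SATURABLE:
        # x' = s - gam x  ->  t = (1/gam) ln((x0 - s/gam)/(x1 - s/gam))
        xi = s / gam
        return math.log((x0 - xi) / (x1 - xi)) / gam
    # saturable: x' = (s + (s - gam) x) / (1 + x)
    c = s - gam
    if s == 0.0:
        # x' = -gam x/(1+x): t = (1/gam) (ln(x0/x1) + x0 - x1)
        return (math.log(x0 / x1) + x0 - x1) / gam
    if c == 0.0:
        # x' = s/(1+x): t = (x1 - x0 + (x1^2 - x0^2)/2)/s
        return (x1 - x0 + 0.5 * (x1 * x1 - x0 * x0)) / s
    return (x1 - x0) / c - gam / c**2 * math.log((s + c * x1) / (s + c * x0))


def flow_time(spec: ModelSpec, s_level: float, x0: float, x1: float) -> float:
    """Time for the bounding flow x' = s_level - g(x) to travel x0 -> x1."""
    if x0 == x1:
        return 0.0
    v0 = s_level - float(spec.degradation(x0))
    if v0 == 0.0 or (x1 - x0) * v0 < 0:
        raise ReductionConfigError(
            f"flow at level {s_level} does not run from {x0} to {x1}"
        )
    return _flow_time_closed(spec, s_level, x0, x1)


def _flow_equilibrium(spec: ModelSpec, s: float) -> float | None:
    """Rest point of x' = s - g(x), if any, as x -> g^{-1}(s)."""
    gam = spec.gamma
    if spec.degradation_kind is DegradationKind.NON_SATURABLE:
        return s / gam
    # g(x) = gam x/(1+x) < gam: saturable flow has a rest point iff s < gam
    if s < gam:
        return s / (gam - s)
    return None


def flow_map(spec: ModelSpec, s_level: float, x0: float, duration: float) -> float:
    """State of the bounding flow x' = s_level - g(x) after ``duration``.

    Uses the exact exponential solution in the non-saturable case and the
    closed-form implicit travel time (inverted with Brent's method) in the
    saturable case.
    """
    if x0 < 0 or duration < 0:
        raise ValueError("need x0 >= 0 and duration >= 0")
    if duration == 0.0:
        return float(x0)
    gam = spec.gamma
    if spec.degradation_kind is DegradationKind.NON_SATURABLE:
        xi = s_level / gam
        return float(xi + (x0 - xi) * math.exp(-gam * duration))
    v0 = s_level - float(spec.degradation(x0))
    if v0 == 0.0:
        return float(x0)
    x_eq = _flow_equilibrium(spec, s_level)
    if v0 > 0:
        if x_eq is not None:
            lo, hi = x0, x_eq
            # approach is asymptotic: bracket strictly inside
            hi = x_eq - 1e-15 * max(1.0, x_eq)
            if hi <= lo:
                return float(x0)
        else:
            hi = max(2.0 * x0, 1.0)
            while _flow_time_closed(spec, s_level, x0, hi) < duration:
                hi *= 2.0
            lo = x0
    else:
        lo = x_eq if x_eq is not None else 0.0
        lo = lo + 1e-15 * max(1.0, lo) if x_eq is not None else 1e-300
        hi = x0
    func = lambda x: _flow_time_closed(spec, s_level, x0, x) - duration
    # travel time is monotone along the flow direction
    a, b = (lo, hi) if v0 > 0 else (hi, lo)
    lo_, hi_ = min(a, b), max(a, b)
    f_lo, f_hi = func(lo_), func(hi_)
    if f_lo == 0.0:
        return float(lo_)
    if f_hi == 0.0:
        return float(hi_)
    if f_lo * f_hi > 0:
        # duration outruns the bracket (asymptotic tail): return the limit
        return float(x_eq) if x_eq is not None else float(hi_)
    return float(brentq(func, lo_, hi_, xtol=1e-14, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# switching points and levels


def _positive_equilibrium(spec: ModelSpec) -> float:
    eqs = [e for e in find_equilibria(spec) if not e.is_trivial]
    if not eqs:
        raise ReductionConfigError("model has no positive equilibrium")
    return eqs[0].x_star


def first_order_switch_points(
    spec: ModelSpec, switches: SwitchConfig
) -> SwitchPoints:
    """Switching points of the first-order reduction.

    X_A (upper) is where the s_high flow arrives one delay after leaving
    x*; X_B (lower) likewise for the s_low flow. Requires monotonic
    synthesis and s_low < g(x*) < s_high so both flows actually leave the
    equilibrium.
    """
    if spec.synthesis_kind is not SynthesisKind.MONOTONIC:
        raise ReductionConfigError("reductions require monotonic synthesis")
    x_star = _positive_equilibrium(spec)
    g_star = float(spec.degradation(x_star))
    if not (switches.s_low < g_star < switches.s_high):
        raise ReductionConfigError(
            f"need s_low < g(x*) = {g_star:g} < s_high for a monotone "
            "approach/escape"
        )
    X_A = flow_map(spec, switches.s_high, x_star, spec.tau)
    X_B = flow_map(spec, switches.s_low, x_star, spec.tau)
    return SwitchPoints(X_A=X_A, X_B=X_B)


def switch_points_by_quadrature(
    spec: ModelSpec, switches: SwitchConfig
) -> SwitchPoints:
    """Independent evaluation of the switching points directly from the
    integral equations Int_{x*}^{X} dz/(s - g(z)) = tau, solved with
    adaptive quadrature inside a bracketing root search."""
    if spec.synthesis_kind is not SynthesisKind.MONOTONIC:
        raise ReductionConfigError("reductions require monotonic synthesis")
    x_star = _positive_equilibrium(spec)

    def solve(s: float, upward: bool) -> float:
        def transit(X: float) -> float:
            with warnings.catch_warnings():
                # near the flow's rest point the integrand is steep but the
                # singularity is integrable; accuracy is root-checked anyway
                warnings.simplefilter("ignore", IntegrationWarning)
                val, _ = quad(
                    lambda z: 1.0 / (s - float(spec.degradation(z))),
                    x_star,
                    X,
                    limit=200,
                    epsabs=1e-13,
                    epsrel=1e-13,
                )
            return val - spec.tau

        if spec.tau == 0:
            return x_star
        if upward:
            x_eq = _flow_equilibrium(spec, s)
            hi = x_eq - 1e-12 if x_eq is not None else None
            if hi is None:
                hi = max(2 * x_star, 1.0)
                while transit(hi) < 0:
                    hi *= 2
            return brentq(transit, x_star, hi, xtol=1e-13)
        lo = _flow_equilibrium(spec, s)
        lo = (lo + 1e-12) if lo is not None and lo > 0 else 1e-12
        return brentq(transit, lo, x_star, xtol=1e-13)

    g_star = float(spec.degradation(x_star))
    if not (switches.s_low < g_star < switches.s_high):
        raise ReductionConfigError("levels do not straddle g(x*)")
    return SwitchPoints(
        X_A=solve(switches.s_high, upward=True),
        X_B=solve(switches.s_low, upward=False),
    )


def self_consistent_levels(spec: ModelSpec, tol: float = 1e-12) -> SwitchConfig:
    """Self-consistent switch levels for the non-saturable monotonic model.

    Each level is the synthesis evaluated at the extreme concentration the
    other level produces (x -> s/gamma at rest):

        rho1 = f(rho2 / gamma),   rho2 = f(rho1 / gamma).

    Solved by damped fixed-point iteration on the decreasing map
    h(rho) = f(rho/gamma) with a Brent root solve on h(h(rho)) = rho as
    fallback; raises ``LevelsError`` when the two-cycle collapses onto the
    fixed point (|h'| <= 1 there, i.e. the synthesis is not steep enough).
    """
    if (
        spec.synthesis_kind is not SynthesisKind.MONOTONIC
        or spec.degradation_kind is not DegradationKind.NON_SATURABLE
    ):
        raise ReductionConfigError(
            "self-consistent levels apply to the monotonic + non-saturable model"
        )
    gam = spec.gamma

    def h(rho: float) -> float:
        return float(spec.synthesis(rho / gam))

    rho1, rho2 = float(spec.beta), 0.0
    converged = False
    for _ in range(500):
        new1 = 0.5 * rho1 + 0.5 * h(rho2)
        new2 = 0.5 * rho2 + 0.5 * h(new1)
        if abs(new1 - rho1) + abs(new2 - rho2) < tol:
            rho1, rho2 = new1, new2
            converged = True
            break
        rho1, rho2 = new1, new2
    if not converged or abs(rho1 - rho2) < 1e-8 * spec.beta:
        # fixed point of h (rho1 = rho2 solution), to bracket above it
        rho_fix = brentq(lambda r: h(r) - r, 0.0, spec.beta, xtol=1e-14)
        G = lambda r: h(h(r)) - r
        lo, hi = rho_fix * (1 + 1e-6) + 1e-12, spec.beta
        if G(lo) * G(hi) > 0:
            raise LevelsError(
                "no genuine two-cycle: synthesis not steep enough (need the "
                "one-delay return map unstable at its fixed point)"
            )
        rho1 = brentq(G, lo, hi, xtol=1e-14)
        rho2 = h(rho1)
    res = abs(rho1 - h(rho2)) + abs(rho2 - h(rho1))
    if res >= 1e-10:
        raise LevelsError(f"level residual {res} too large")
    if abs(rho1 - rho2) < 1e-8 * spec.beta:
        raise LevelsError("two-cycle collapsed onto the fixed point")
    return SwitchConfig(s_high=max(rho1, rho2), s_low=min(rho1, rho2),
                        mode="self_consistent")


# ---------------------------------------------------------------------------
# first-order simulation


def first_order_period(spec: ModelSpec, switches: SwitchConfig) -> float:
    """Closed-form period of the first-order reduction: the two-branch
    transit time X_B -> X_A at s_high plus X_A -> X_B at s_low."""
    pts = first_order_switch_points(spec, switches)
    t_up = flow_time(spec, switches.s_high, pts.X_B, pts.X_A)
    t_down = flow_time(spec, switches.s_low, pts.X_A, pts.X_B)
    return t_up + t_down


def simulate_first_order(
    spec: ModelSpec,
    switches: SwitchConfig,
    t_end: float,
    dt: float = 1e-3,
    x0: float | None = None,
    rtol: float = 1e-10,
) -> ReducedTrajectory:
    """Integrate x' = s - g(x) with s flipping at the switching points.

    s starts high at the equilibrium (the repressor is on its high branch
    below x*) and flips high -> low when x rises to X_A, low -> high when it
    falls to X_B. After the first event the orbit is exactly periodic.
    """
    pts = first_order_switch_points(spec, switches)
    x_star = _positive_equilibrium(spec)
    if x0 is None:
        x0 = x_star
    s = switches.s_high if x0 < pts.X_A else switches.s_low

    n_samples = int(np.floor(t_end / dt + 1e-9)) + 1
    t_grid = dt * np.arange(n_samples)
    xs = np.empty(n_samples)
    ss = np.empty(n_samples)
    ev_times: list[float] = []
    ev_values: list[float] = []

    t_cur, x_cur = 0.0, float(x0)
    filled = 0
    min_gap = np.inf
    while t_cur < t_end and filled < n_samples:
        target = pts.X_A if s == switches.s_high else pts.X_B

        def rhs(t, y):
            return [s - float(spec.degradation(y[0]))]

        def event(t, y):
            return y[0] - target

        event.terminal = True
        event.direction = 1.0 if s == switches.s_high else -1.0
        sol = solve_ivp(
            rhs,
            (t_cur, t_end),
            [x_cur],
            events=event,
            dense_output=True,
            rtol=rtol,
            atol=1e-12,
            max_step=max(spec.tau / 4.0, 10 * dt),
        )
        t_stop = sol.t[-1]
        sel = (t_grid >= t_cur - 1e-12) & (t_grid <= t_stop + 1e-12)
        idx = np.flatnonzero(sel)
        if len(idx):
            xs[idx] = sol.sol(t_grid[idx])[0]
            ss[idx] = s
            filled = idx[-1] + 1
        if sol.t_events[0].size:
            t_ev = float(sol.t_events[0][0])
            if ev_times:
                min_gap = min(min_gap, t_ev - ev_times[-1])
            s = switches.s_low if s == switches.s_high else switches.s_high
            ev_times.append(t_ev)
            ev_values.append(s)
            t_cur, x_cur = t_ev, float(sol.y_events[0][0][0])
        else:
            t_cur = t_stop
            x_cur = float(sol.y[0][-1])
            if t_cur >= t_end - 1e-12:
                break
    if min_gap < 2 * dt:
        raise ReductionConfigError(
            f"switch events only {min_gap:g} apart; decrease dt"
        )
    return ReducedTrajectory(
        dt=dt,
        states=xs[:, None],
        switch_signal=ss,
        switch_times=np.asarray(ev_times),
        switch_values=np.asarray(ev_values),
        order=1,
    )


# ---------------------------------------------------------------------------
# second-order reduction


def boundary_curves(
    spec: ModelSpec,
    switches: SwitchConfig,
    u2_band: tuple[float, float] | None = None,
    n_samples: int = 2000,
) -> tuple[BoundaryCurve, BoundaryCurve]:
    """Lower and upper switching curves on the (u1, u2) plane.

    The lower curve is the one-delay image of the slowest flow: points
    (flow_map(s_low, c, tau), c) over initial values c — every DDE
    trajectory projected onto (x(t), x(t - tau)) stays to its right.
    The upper curve uses s_high and bounds the trajectory on the left.
    """
    if spec.synthesis_kind is not SynthesisKind.MONOTONIC:
        raise ReductionConfigError("reductions require monotonic synthesis")
    if u2_band is None:
        try:
            pts = first_order_switch_points(spec, switches)
            u2_band = (max(pts.X_B * 0.25, 0.0), pts.X_A * 2.0)
        except ReductionConfigError:
            x_star = _positive_equilibrium(spec)
            u2_band = (0.0, 3.0 * x_star)
    c_grid = np.linspace(u2_band[0], u2_band[1], n_samples)
    lower = np.asarray(
        [flow_map(spec, switches.s_low, c, spec.tau) for c in c_grid]
    )
    upper = np.asarray(
        [flow_map(spec, switches.s_high, c, spec.tau) for c in c_grid]
    )
    return (
        BoundaryCurve(side="lower", u2=c_grid, u1=lower),
        BoundaryCurve(side="upper", u2=c_grid, u1=upper),
    )


def simulate_second_order(
    spec: ModelSpec,
    switches: SwitchConfig,
    t_end: float,
    dt: float = 1e-3,
    u0: tuple[float, float] | None = None,
    curves: tuple[BoundaryCurve, BoundaryCurve] | None = None,
    rtol: float = 1e-9,
) -> ReducedTrajectory:
    """Integrate the two-variable reduction with boundary-curve switching.

    u1 plays the instantaneous coordinate, u2 the once-delayed one:
    u1' = f(u2) - g(u1), u2' = s - g(u2). One curve guards each switch
    direction: while s is low the phase point drifts toward the lower-right
    rest state and flips to s_high on crossing the upper curve outward;
    while s is high it drifts upper-left and flips to s_low on crossing the
    lower curve outward. (Watching both curves in both states deadlocks:
    right after a flip the point lingers at the curve it just crossed —
    its u1-motion only reverses once u2 has responded — grazes it again
    and flips straight back.)
    """
    if curves is None:
        curves = boundary_curves(spec, switches)
    lower, upper = curves
    x_star = _positive_equilibrium(spec)
    if u0 is None:
        u0 = (1.05 * x_star, 1.05 * x_star)
    s = switches.s_high if u0[1] < x_star else switches.s_low

    f = spec.synthesis
    g = spec.degradation

    def rhs(t, y):
        u1, u2 = y
        u1 = max(u1, 0.0)
        u2 = max(u2, 0.0)
        return [float(f(u2)) - float(g(u1)), s - float(g(u2))]

    def ev_upper(t, y):
        return y[0] - float(upper(max(y[1], 0.0)))

    ev_upper.terminal = True
    ev_upper.direction = 1.0  # leaving through the upper curve (s low)

    def ev_lower(t, y):
        return y[0] - float(lower(max(y[1], 0.0)))

    ev_lower.terminal = True
    ev_lower.direction = -1.0  # leaving through the lower curve (s high)

    n_samples = int(np.floor(t_end / dt + 1e-9)) + 1
    t_grid = dt * np.arange(n_samples)
    states = np.empty((n_samples, 2))
    ss = np.empty(n_samples)
    ev_times: list[float] = []
    ev_values: list[float] = []

    t_cur = 0.0
    y_cur = [float(u0[0]), float(u0[1])]
    guard = 0
    blank = max(2.0 * dt, 1e-6)  # event holdoff after a flip: the state sits
    # exactly on the curve there and would retrigger at t0 otherwise
    armed = True
    while t_cur < t_end:
        t_stop = t_end if armed else min(t_cur + blank, t_end)
        watch = ev_lower if s == switches.s_high else ev_upper
        sol = solve_ivp(
            rhs,
            (t_cur, t_stop),
            y_cur,
            events=(watch,) if armed else None,
            dense_output=True,
            rtol=rtol,
            atol=1e-12,
            max_step=max(spec.tau / 10.0, 10 * dt),
        )
        sel = (t_grid >= t_cur - 1e-12) & (t_grid <= sol.t[-1] + 1e-12)
        idx = np.flatnonzero(sel)
        if len(idx):
            vals = sol.sol(t_grid[idx])
            states[idx, 0] = vals[0]
            states[idx, 1] = vals[1]
            ss[idx] = s
        hit = armed and sol.t_events[0].size
        if hit:
            t_ev = float(sol.t_events[0][0])
            y_cur = list(sol.y_events[0][0])
            s = switches.s_low if s == switches.s_high else switches.s_high
            ev_times.append(t_ev)
            ev_values.append(s)
            t_cur = t_ev
            armed = False
            guard += 1
            if guard > 10_000:
                break
        else:
            t_cur = sol.t[-1]
            y_cur = [float(sol.y[0][-1]), float(sol.y[1][-1])]
            armed = True
            if t_cur >= t_end - 1e-12:
                break

    chattering = False
    if len(ev_times) >= 4:
        mean_period = float(np.mean(np.diff(np.asarray(ev_times)[::2])))
        window = mean_period if mean_period > 0 else t_end
        rate = len(ev_times) / max(t_end / window, 1.0)
        chattering = rate > 10
    return ReducedTrajectory(
        dt=dt,
        states=states,
        switch_signal=ss,
        switch_times=np.asarray(ev_times),
        switch_values=np.asarray(ev_values),
        order=2,
        chattering=chattering,
    )


# ---------------------------------------------------------------------------
# comparison against the full DDE


def default_switches(spec: ModelSpec, order: int) -> SwitchConfig:
    """Levels used by default: synthesis extremes, except the second-order
    non-saturable reduction which uses the self-consistent pair."""
    if (
        order == 2
        and spec.degradation_kind is DegradationKind.NON_SATURABLE
    ):
        return self_consistent_levels(spec)
    return SwitchConfig.from_extremes(spec)


def reduction_error_report(
    specs: list[ModelSpec],
    orders: tuple[int, ...] = (1, 2),
    t_end: float = 400.0,
    dt: float = 1e-3,
    transient: float | None = None,
) -> pd.DataFrame:
    """Periods/amplitudes of the full DDE and its reductions, with relative
    errors, one row per (spec, order)."""
    rows = []
    for spec in specs:
        x_star = _positive_equilibrium(spec)
        history = HistoryFunction(value=1.1 * x_star)
        ts = integrate_dde(spec, history, t_end, dt, transient=transient)
        try:
            dde_stats = period_amplitude(ts, level=x_star)
        except NoOscillationError:
            continue
        for order in orders:
            switches = default_switches(spec, order)
            if order == 1:
                period = first_order_period(spec, switches)
                pts = first_order_switch_points(spec, switches)
                amplitude = pts.X_A - pts.X_B
            else:
                traj = simulate_second_order(spec, switches, t_end, dt)
                red_ts = traj.to_timeseries(
                    transient=min(10 * spec.tau, 0.5 * t_end)
                )
                red_stats = period_amplitude(red_ts, level=x_star)
                period = red_stats.period
                amplitude = red_stats.amplitude
            rows.append(
                dict(
                    synthesis=spec.synthesis_kind.value,
                    degradation=spec.degradation_kind.value,
                    n=spec.n,
                    tau=spec.tau,
                    order=order,
                    period=period,
                    amplitude=amplitude,
                    dde_period=dde_stats.period,
                    dde_amplitude=dde_stats.amplitude,
                    period_rel_err=(period - dde_stats.period) / dde_stats.period,
                    amplitude_rel_err=(amplitude - dde_stats.amplitude)
                    / dde_stats.amplitude,
                )
            )
    return pd.DataFrame(rows)
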