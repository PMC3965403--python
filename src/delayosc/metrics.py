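"""Period and amplitude by the level-crossing protocol, and (n, tau) sweeps.

A cycle is delimited by the times the trajectory crosses a reference level
(the calibrated equilibrium x*) from above. The period is the mean spacing
of the last K such crossings, the amplitude the max - min of the samples
over the final cycle. Chaotic regimes still report a "period" — the mean
crossing interval — flagged by a high coefficient of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .integrate import HistoryFunction, IntegrationError, TimeSeries, integrate_dde
from .models import calibrate_to_equilibrium

__all__ = [
    "CycleStats",
    "SweepGrid",
    "NoOscillationError",
    "detect_down_crossings",
    "period_amplitude",
    "sweep_observable",
]

logger = logging.getLogger(__name__)

#: cycles averaged for the period estimate
K_CYCLES = 10
#: coefficient of variation above which a rhythm is flagged irregular
CV_IRREGULAR = 0.1


class NoOscillationError(RuntimeError):
    """Fewer than three level crossings after the transient."""


@dataclass(frozen=True)
class CycleStats:
    period: float
    amplitude: float
    n_cycles_used: int
    cv: float  # coefficient of variation of the crossing intervals


@dataclass
class SweepGrid:
    """Observable values over an (n, tau) grid; NaN marks grid points where
    oscillations are absent or estimation failed."""

    n_values: np.ndarray
    tau_values: np.ndarray
    observable: str
    values: np.ndarray  # shape (len(n_values), len(tau_values))
    flags: np.ndarray = field(default=None)  # "irregular" CV flag, same shape

    def __post_init__(self):
        self.n_values = np.asarray(self.n_values, dtype=float)
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.n_values), len(self.tau_values)):
            raise ValueError("values shape does not match the grids")
        if self.flags is None:
            self.flags = np.zeros_like(self.values, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (n, tau) with value and irregular flag."""
        rows = []
        for i, n in enumerate(self.n_values):
            for j, tau in enumerate(self.tau_values):
                rows.append(
                    dict(
                        n=n,
                        tau=tau,
                        value=self.values[i, j],
                        flag="irregular" if self.flags[i, j] else "",
                    )
                )
        return pd.DataFrame(rows)


def detect_down_crossings(ts: TimeSeries, level: float) -> np.ndarray:
    """Times where the post-transient signal passes from above ``level`` to
    at-or-below it, refined by linear interpolation between the bracketing
    non-level samples. A tangential graze (touching the level without a sign
    change) is not a crossing."""
    v = ts.post_transient
    if len(v) < 2:
        return np.asarray([])
    w = v - level
    s = np.sign(w)
    nz = np.flatnonzero(s)
    if len(nz) < 2:
        return np.asarray([])
    signs = s[nz]
    down = np.flatnonzero((signs[:-1] > 0) & (signs[1:] < 0))
    t_base = ts.post_transient_t0
    times = np.empty(len(down))
    for k, idx in enumerate(down):
        i, j = nz[idx], nz[idx + 1]
        # linear interpolation of the zero of w between samples i and j
        frac = w[i] / (w[i] - w[j])
        times[k] = t_base + ts.dt * (i + frac * (j - i))
    return times


def period_amplitude(
    ts: TimeSeries,
    level: float,
    k_cycles: int = K_CYCLES,
    min_amplitude: float = 1e-6,
) -> CycleStats:
    """Cycle statistics from the down-crossing protocol.

    Period: mean of the successive crossing differences over the last
    ``k_cycles`` cycles. Amplitude: max - min of the samples between the
    last two crossings (one-cycle window). Raises ``NoOscillationError``
    with fewer than three crossings, or when the residual amplitude is
    below ``min_amplitude`` (a trajectory settled onto the equilibrium
    still wiggles at rounding level)."""
    times = detect_down_crossings(ts, level)
    if len(times) < 3:
        raise NoOscillationError(
            f"only {len(times)} down-crossings after the transient"
        )
    intervals = np.diff(times)[-k_cycles:]
    period = float(np.mean(intervals))
    cv = float(np.std(intervals) / period) if period > 0 else np.inf
    # samples spanning the last full cycle
    i0 = int(np.ceil((times[-2] - ts.t0) / ts.dt))
    i1 = int(np.floor((times[-1] - ts.t0) / ts.dt)) + 1
    window = ts.values[i0:i1]
    amplitude = float(np.max(window) - np.min(window))
    if amplitude < min_amplitude:
        raise NoOscillationError(
            f"residual amplitude {amplitude:g} below {min_amplitude:g}"
        )
    return CycleStats(
        period=period,
        amplitude=amplitude,
        n_cycles_used=len(intervals),
        cv=cv,
    )


def sweep_observable(
    synthesis_kind,
    degradation_kind,
    n_grid,
    tau_grid,
    observable: str = "period",
    gamma: float = 1.0,
    x_target: float = 1.0,
    dt: float = 1e-3,
    t_end: float = 500.0,
    transient: float | None = None,
    history_seed: int = 0,
    jitter: float = 0.0,
    d2_kwargs: dict | None = None,
) -> SweepGrid:
    """Map an observable over an (n, tau) grid with row-by-row continuation.

    Within each row (fixed n) the final state of one run seeds the next grid
    point's history, mimicking the incremental protocol used to build the
    parameter-plane diagrams. Observables: "period", "amplitude" (crossing
    protocol at the calibrated x*) or "corrdim" (correlation dimension of
    the post-transient series).
    """
    if observable not in ("period", "amplitude", "corrdim"):
        raise ValueError(f"unknown observable {observable!r}")
    n_grid = np.atleast_1d(np.asarray(n_grid, dtype=float))
    tau_grid = np.atleast_1d(np.asarray(tau_grid, dtype=float))
    if len(n_grid) == 0 or len(tau_grid) == 0:
        raise ValueError("grids must be non-empty")
    values = np.full((len(n_grid), len(tau_grid)), np.nan)
    flags = np.zeros_like(values, dtype=bool)

    for i, n in enumerate(n_grid):
        spec0 = calibrate_to_equilibrium(
            synthesis_kind, degradation_kind, n=n, tau=0.0,
            x_target=x_target, gamma=gamma,
        )
        hist_value = 1.1 * x_target
        for j, tau in enumerate(tau_grid):
            spec = spec0.with_tau(float(tau))
            history = HistoryFunction(
                kind="perturbed_constant" if jitter > 0 else "constant",
                value=hist_value,
                jitter_amplitude=jitter,
                seed=history_seed + 1000 * i + j,
            )
            try:
                ts = integrate_dde(spec, history, t_end, dt, transient=transient)
            except IntegrationError as exc:
                logger.warning("integration failed at n=%g tau=%g: %s", n, tau, exc)
                continue
            hist_value = max(float(ts.values[-1]), 0.0)
            if abs(hist_value - x_target) < 1e-3 * x_target:
                # the previous point settled onto the equilibrium; re-perturb
                # so the continuation can pick up oscillations past onset
                hist_value = 1.1 * x_target
            try:
                if observable == "corrdim":
                    from .corrdim import estimate_d2

                    est = estimate_d2(ts, **(d2_kwargs or {}))
                    values[i, j] = est.d2
                    flags[i, j] = est.plateau_quality > 0.15
                else:
                    stats = period_amplitude(ts, level=x_target)
                    values[i, j] = getattr(stats, observable)
                    flags[i, j] = stats.cv > CV_IRREGULAR
            except NoOscillationError:
                continue
    return SweepGrid(n_grid, tau_grid, observable, values, flags)
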