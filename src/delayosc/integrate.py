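"""Fixed-step integration of the scalar DDE with constant-history data.

The state over one delay interval is carried on the time grid itself: a
delay of tau corresponds to d = round(tau / dt) grid steps, and the delayed
coordinate x(t - tau) is read d nodes back. tau = 0 degenerates to a plain
ODE. Euler is the production scheme; classical RK4 (with linear
interpolation of the past at half-steps) is provided as a cross-check, the
same validation the study conditions prescribe for choosing dt.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .models import DegradationKind, ModelSpec, SynthesisKind

__all__ = [
    "HistoryFunction",
    "TimeSeries",
    "IntegrationError",
    "integrate_dde",
    "validate_step",
    "default_transient",
]

DEFAULT_DT = 1e-3


class IntegrationError(RuntimeError):
    """The state became non-finite; reports the first bad step."""


def _kind_codes(spec: ModelSpec) -> tuple[int, int]:
    syn = (
        _kernels.SYN_MONOTONIC
        if spec.synthesis_kind is SynthesisKind.MONOTONIC
        else _kernels.SYN_NON_MONOTONIC
    )
    deg = (
        _kernels.DEG_SATURABLE
        if spec.degradation_kind is DegradationKind.SATURABLE
        else _kernels.DEG_NON_SATURABLE
    )
    return syn, deg


@dataclass(frozen=True)
class HistoryFunction:
    """Initial data on [-tau, 0]: a constant, optionally with seeded uniform
    jitter per grid node (clamped at zero) to break symmetry in chaotic
    regimes."""

    kind: str = "constant"  # "constant" | "perturbed_constant"
    value: float = 1.0
    jitter_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("constant", "perturbed_constant"):
            raise ValueError(f"unknown history kind {self.kind!r}")
        if self.value < 0:
            raise ValueError("history value must be >= 0")
        if self.jitter_amplitude < 0:
            raise ValueError("jitter_amplitude must be >= 0")

    def sample(self, n_nodes: int) -> np.ndarray:
        """History values at the n_nodes grid nodes t = -(n_nodes-1)dt .. 0."""
        vals = np.full(n_nodes, float(self.value))
        if self.kind == "perturbed_constant" and self.jitter_amplitude > 0:
            rng = np.random.default_rng(self.seed)
            vals = vals + rng.uniform(
                -self.jitter_amplitude, self.jitter_amplitude, n_nodes
            )
            np.clip(vals, 0.0, None, out=vals)
        return vals


@dataclass
class TimeSeries:
    """Uniformly sampled trajectory with a transient marker.

    ``values[k]`` is x(t0 + k dt); samples before index ``transient_end``
    are discarded by the metric extractors.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0
    transient_end: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        self.transient_end = int(min(self.transient_end, len(self.values)))

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def post_transient(self) -> np.ndarray:
        return self.values[self.transient_end :]

    @property
    def post_transient_t0(self) -> float:
        return self.t0 + self.dt * self.transient_end

    def __len__(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Two-column CSV (time,value) with '#' comment header carrying the
        sampling step, transient marker and any model parameters."""
        buf = io.StringIO()
        for key in sorted(self.meta):
            buf.write(f"# {key} = {self.meta[key]}\n")
        buf.write(f"# dt = {self.dt!r}\n")
        buf.write(f"# transient_end = {self.transient_end}\n")
        buf.write("time,value\n")
        for ti, vi in zip(self.t, self.values):
            buf.write(f"{float(ti)!r},{float(vi)!r}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        meta: dict = {}
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line[1:].partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if line.lower().startswith("time"):
                continue
            a, _, b = line.partition(",")
            rows.append((float(a), float(b)))
        arr = np.asarray(rows)
        if len(arr) < 2:
            raise ValueError("need at least two samples")
        dt = float(meta.pop("dt", arr[1, 0] - arr[0, 0]))
        transient_end = int(meta.pop("transient_end", 0))
        return cls(
            dt=dt,
            values=arr[:, 1],
            t0=float(arr[0, 0]),
            transient_end=transient_end,
            meta=meta,
        )


def default_transient(tau: float, t_end: float) -> float:
    """Transient discarded before metrics: max(50 tau, 200) time units,
    clamped to 80% of the run when the run is shorter."""
    return min(max(50.0 * tau, 200.0), 0.8 * t_end)


def integrate_dde(
    spec: ModelSpec,
    history: HistoryFunction,
    t_end: float,
    dt: float = DEFAULT_DT,
    method: str = "euler",
    transient: float | None = None,
) -> TimeSeries:
    """Integrate dx/dt = f(x(t - tau)) - g(x) from constant(-ish) history.

    Returns floor(t_end/dt) + 1 samples on [0, t_end]. The effective delay is
    round(tau/dt) steps. A non-finite state raises ``IntegrationError`` with
    the first bad step.
    """
    if not (dt > 0 and t_end > 0):
        raise ValueError("dt and t_end must be > 0")
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown method {method!r}")
    d = int(round(spec.tau / dt))
    nsteps = int(np.floor(t_end / dt + 1e-9))
    hist = history.sample(d + 1)
    syn, deg = _kind_codes(spec)
    kernel = _kernels.euler_dde if method == "euler" else _kernels.rk4_dde
    out, bad = kernel(
        syn, deg, float(spec.beta), float(spec.gamma), float(spec.n),
        hist, nsteps, float(dt),
    )
    if bad >= 0:
        raise IntegrationError(
            f"state became non-finite at step {bad - d} (t = {(bad - d) * dt:g})"
        )
    values = out[d:]
    if transient is None:
        transient = default_transient(spec.tau, t_end)
    ts = TimeSeries(
        dt=dt,
        values=values,
        t0=0.0,
        transient_end=int(round(transient / dt)),
        meta=dict(spec.to_dict(), method=method),
    )
    return ts


def validate_step(
    spec: ModelSpec,
    history: HistoryFunction,
    t_end: float,
    dt: float = DEFAULT_DT,
    tolerance: float = 1e-3,
) -> tuple[float, bool]:
    """Run Euler and RK4 on the same grid; report the largest pointwise gap
    and whether it stays below ``tolerance`` (the step-size adequacy check
    the study conditions prescribe)."""
    ts_e = integrate_dde(spec, history, t_end, dt, method="euler")
    ts_r = integrate_dde(spec, history, t_end, dt, method="rk4")
    gap = float(np.max(np.abs(ts_e.values - ts_r.values)))
    return gap, bool(gap < tolerance)
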