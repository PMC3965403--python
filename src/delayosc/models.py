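"""The four-model family of single-gene delay oscillators.

All models are scalar delay differential equations

    dx/dt = f(x(t - tau)) - g(x(t))

where ``x`` is a protein concentration, ``f`` is delayed synthesis and ``g``
instantaneous degradation. Synthesis is either a Hill repressor (monotonic,
pure negative feedback)

    f(x) = beta / (1 + x**n)

or a Hill-type term with the substrate in the numerator (non-monotonic,
positive feedback at low concentration turning negative at high)

    f(x) = beta * x / (1 + x**n)

and degradation is either Michaelis-Menten (saturable)

    g(x) = gamma * x / (1 + x)

or first-order (non-saturable)

    g(x) = gamma * x.

Both Michaelis constants are set to 1, i.e. absorbed into the concentration
unit; this loses no generality once they are taken equal. The non-monotonic,
non-saturable member is the Mackey-Glass equation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SynthesisKind",
    "DegradationKind",
    "ModelSpec",
    "Equilibrium",
    "LinearCoeffs",
    "CalibrationError",
    "EquilibriumSearchError",
    "evaluate_rates",
    "find_equilibria",
    "calibrate_to_equilibrium",
    "linearize",
    "synthesis_extremes",
]

#: residual bound every returned equilibrium must satisfy
EQUILIBRIUM_RESIDUAL_TOL = 1e-10
#: absolute tolerance of the bisection refinement on x
_ROOT_XTOL = 1e-13


class SynthesisKind(str, Enum):
    MONOTONIC = "monotonic"
    NON_MONOTONIC = "non_monotonic"


class DegradationKind(str, Enum):
    SATURABLE = "saturable"
    NON_SATURABLE = "non_saturable"


class CalibrationError(ValueError):
    """No positive synthesis factor satisfies the equilibrium constraint."""


class EquilibriumSearchError(RuntimeError):
    """No sign change of f - g found; retry with a larger ``x_max``."""


@dataclass(frozen=True)
class ModelSpec:
    """One member of the four-model family with its parameters.

    Parameters
    ----------
    synthesis_kind, degradation_kind
        Which synthesis / degradation term the model uses.
    beta
        Synthesis factor (concentration / time), > 0.
    gamma
        Degradation factor (1 / time for non-saturable, concentration / time
        for saturable), > 0.
    n
        Hill cooperativity coefficient (dimensionless), >= 1.
    tau
        Discrete time delay, >= 0.
    """

    synthesis_kind: SynthesisKind
    degradation_kind: DegradationKind
    beta: float
    gamma: float
    n: float
    tau: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "synthesis_kind", SynthesisKind(self.synthesis_kind))
        object.__setattr__(
            self, "degradation_kind", DegradationKind(self.degradation_kind)
        )
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (self.gamma > 0):
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not (self.n >= 1):
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (self.tau >= 0):
            raise ValueError(f"tau must be >= 0, got {self.tau}")

    # -- model terms -------------------------------------------------------

    def synthesis(self, x):
        """f(x), vectorized over non-negative concentrations."""
        x = _check_nonneg(x, "x")
        if self.synthesis_kind is SynthesisKind.MONOTONIC:
            return self.beta / (1.0 + x**self.n)
        return self.beta * x / (1.0 + x**self.n)

    def degradation(self, x):
        """g(x), vectorized over non-negative concentrations."""
        x = _check_nonneg(x, "x")
        if self.degradation_kind is DegradationKind.SATURABLE:
            return self.gamma * x / (1.0 + x)
        return self.gamma * x

    def synthesis_prime(self, x):
        """df/dx."""
        x = _check_nonneg(x, "x")
        xn = x**self.n
        if self.synthesis_kind is SynthesisKind.MONOTONIC:
            # d/dx beta/(1+x^n) = -beta n x^(n-1) / (1+x^n)^2
            return -self.beta * self.n * x ** (self.n - 1.0) / (1.0 + xn) ** 2
        # d/dx beta x/(1+x^n) = beta (1 + (1-n) x^n) / (1+x^n)^2
        return self.beta * (1.0 + (1.0 - self.n) * xn) / (1.0 + xn) ** 2

    def degradation_prime(self, x):
        """dg/dx; equals gamma exactly in the non-saturable case."""
        x = _check_nonneg(x, "x")
        if self.degradation_kind is DegradationKind.SATURABLE:
            return self.gamma / (1.0 + x) ** 2
        return self.gamma * np.ones_like(np.asarray(x, dtype=float))[()]

    def with_tau(self, tau: float) -> "ModelSpec":
        return replace(self, tau=tau)

    def with_n(self, n: float) -> "ModelSpec":
        return replace(self, n=n)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "synthesis_kind": self.synthesis_kind.value,
            "degradation_kind": self.degradation_kind.value,
            "beta": self.beta,
            "gamma": self.gamma,
            "n": self.n,
            "tau": self.tau,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass(frozen=True)
class Equilibrium:
    """A root x* of f(x) = g(x); trivial means x* = 0."""

    x_star: float
    is_trivial: bool
    residual: float


@dataclass(frozen=True)
class LinearCoeffs:
    """Coefficients of the linearization y' = a y(t - tau) - b y(t) about x*.

    ``a`` is the synthesis derivative at the delayed coordinate, ``b`` the
    degradation derivative at the instantaneous coordinate, both evaluated at
    the equilibrium x*.
    """

    a: float
    b: float
    x_star: float


def _check_nonneg(x, name: str):
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr[()] if arr.ndim == 0 else arr


def evaluate_rates(spec: ModelSpec, x_delayed, x_now):
    """Return (synthesis_rate, degradation_rate) at the given coordinates.

    Synthesis is evaluated at the delayed concentration, degradation at the
    instantaneous one; negative concentrations raise ``ValueError``.
    """
    return spec.synthesis(x_delayed), spec.degradation(x_now)


def find_equilibria(
    spec: ModelSpec,
    x_max: float | None = None,
    grid_points: int = 10_000,
) -> list[Equilibrium]:
    """All equilibria of the model on [0, x_max], sorted ascending.

    A dense sign scan of f(x) - g(x) on (0, x_max] brackets the roots, each
    refined by Brent's method to ~1e-13 in x. The trivial equilibrium x = 0
    is included for non-monotonic models (their synthesis vanishes there).
    Monotonic models are guaranteed exactly one positive equilibrium; if the
    scan finds no sign change the interval was too small and
    ``EquilibriumSearchError`` is raised.
    """
    if x_max is None:
        x_max = max(10.0, 10.0 * spec.beta / spec.gamma)
    if not (x_max > 0):
        raise ValueError("x_max must be > 0")
    if grid_points < 100:
        raise ValueError("grid_points must be >= 100")

    def h(x: float) -> float:
        return float(spec.synthesis(x) - spec.degradation(x))

    xs = np.linspace(0.0, x_max, grid_points + 1)[1:]
    vals = spec.synthesis(xs) - spec.degradation(xs)

    roots: list[float] = []
    for i in range(len(xs) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(float(xs[i]))
        elif v0 * v1 < 0.0:
            roots.append(brentq(h, xs[i], xs[i + 1], xtol=_ROOT_XTOL))
    if vals[-1] == 0.0:
        roots.append(float(xs[-1]))

    out: list[Equilibrium] = []
    if spec.synthesis_kind is SynthesisKind.NON_MONOTONIC:
        out.append(Equilibrium(0.0, True, 0.0))
    for r in sorted(set(roots)):
        res = abs(h(r))
        assert res < EQUILIBRIUM_RESIDUAL_TOL, (r, res)
        out.append(Equilibrium(float(r), False, res))

    if spec.synthesis_kind is SynthesisKind.MONOTONIC and not any(
        not e.is_trivial for e in out
    ):
        raise EquilibriumSearchError(
            f"no sign change of f - g in (0, {x_max}]; call with a larger x_max"
        )
    return out


def calibrate_to_equilibrium(
    synthesis_kind: SynthesisKind | str,
    degradation_kind: DegradationKind | str,
    n: float,
    tau: float,
    x_target: float = 1.0,
    gamma: float = 1.0,
) -> ModelSpec:
    """Solve for the synthesis factor beta placing an equilibrium at x_target.

    For the monotonic family beta = g(x_target) (1 + x_target**n); for the
    non-monotonic family beta = g(x_target) (1 + x_target**n) / x_target.
    The figure protocol of the study keeps x* fixed while n and tau vary.
    """
    if not (x_target > 0):
        raise CalibrationError("x_target must be > 0")
    if not (gamma > 0):
        raise CalibrationError("gamma must be > 0")
    synthesis_kind = SynthesisKind(synthesis_kind)
    degradation_kind = DegradationKind(degradation_kind)
    if degradation_kind is DegradationKind.SATURABLE:
        gx = gamma * x_target / (1.0 + x_target)
    else:
        gx = gamma * x_target
    if synthesis_kind is SynthesisKind.MONOTONIC:
        beta = gx * (1.0 + x_target**n)
    else:
        beta = gx * (1.0 + x_target**n) / x_target
    if not (beta > 0 and math.isfinite(beta)):
        raise CalibrationError(f"calibration produced beta = {beta}")
    return ModelSpec(synthesis_kind, degradation_kind, beta, gamma, n, tau)


def linearize(spec: ModelSpec, eq: Equilibrium) -> LinearCoeffs:
    """Linearization coefficients about an equilibrium.

    Writing x = x* + y and Taylor-expanding gives y' = a y(t - tau) - b y(t)
    with a = f'(x*) and b = g'(x*). About the trivial equilibrium of a
    non-monotonic model a = beta > 0 (positive feedback); that case is
    permitted but a warning is emitted.
    """
    if eq.residual >= EQUILIBRIUM_RESIDUAL_TOL:
        raise ValueError(f"equilibrium residual {eq.residual} too large")
    a = float(spec.synthesis_prime(eq.x_star))
    b = float(spec.degradation_prime(eq.x_star))
    if eq.is_trivial and spec.synthesis_kind is SynthesisKind.NON_MONOTONIC:
        warnings.warn(
            "linearizing a non-monotonic model about x* = 0: feedback is "
            "positive there (a > 0)",
            stacklevel=2,
        )
    return LinearCoeffs(a=a, b=b, x_star=eq.x_star)


def synthesis_extremes(spec: ModelSpec) -> tuple[float, float]:
    """(F_min, F_max): infimum and supremum of f over x >= 0.

    The monotonic repressor spans (0, beta]: F_max = f(0) = beta, F_min = 0
    (the x -> infinity limit). The non-monotonic term vanishes at both ends
    and peaks at x = (n - 1)**(-1/n) for n > 1.
    """
    if spec.synthesis_kind is SynthesisKind.MONOTONIC:
        return 0.0, spec.beta
    if spec.n <= 1:
        # beta x/(1+x): increasing, supremum beta approached at infinity
        return 0.0, spec.beta
    x_peak = (1.0 / (spec.n - 1.0)) ** (1.0 / spec.n)
    return 0.0, float(spec.synthesis(x_peak))
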