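"""Linear stability of the delay model: Hopf points, bifurcation curves,
unstable-pair counts and analytic dimension-line slopes.

The linearization about an equilibrium is y' = a y(t - tau) - b y(t); the
ansatz y = e^(lambda t) yields the transcendental characteristic equation

    lambda + b - a exp(-lambda tau) = 0.

A purely imaginary root lambda = i omega requires, separating real and
imaginary parts,

    a cos(omega tau) = b,        omega = -a sin(omega tau),

so omega = sqrt(a^2 - b^2) exists iff |a| > |b|, and roots cross the axis at
the delays tau_j = (theta + 2 pi j) / omega, where theta in (0, 2 pi) is the
phase fixed jointly by the two conditions. Counting the branches already
crossed gives the number of unstable conjugate pairs, which accrues at the
rate omega / (2 pi) per unit delay — the slope of the dimension lines for
the non-robust (non-monotonic) models.

Everything here works in (a, b, tau); the map to the Hill coefficient n goes
through calibration + linearization, so one core serves all four models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    CalibrationError,
    DegradationKind,
    EquilibriumSearchError,
    LinearCoeffs,
    SynthesisKind,
    calibrate_to_equilibrium,
    find_equilibria,
    linearize,
)

__all__ = [
    "HopfPoint",
    "StabilityCount",
    "DimensionLine",
    "crossing_frequency",
    "critical_delay",
    "hopf_curve",
    "count_unstable_pairs",
    "unstable_pairs_oracle",
    "dimension_line_slope",
    "characteristic_value",
]

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class HopfPoint:
    """Critical delay and crossing frequency on branch j."""

    omega: float
    tau_crit: float
    branch_j: int


@dataclass(frozen=True)
class StabilityCount:
    """Number of conjugate characteristic-exponent pairs with Re > 0."""

    pairs: int


@dataclass(frozen=True)
class DimensionLine:
    """Slope (per unit delay) of the analytic dimension line; the offset is
    not predicted analytically and is left to an external fit."""

    slope: float
    offset: float | None = None
    has_crossing: bool = True


def characteristic_value(coeffs: LinearCoeffs, lam: complex, tau: float) -> complex:
    """lambda + b - a exp(-lambda tau)."""
    return lam + coeffs.b - coeffs.a * np.exp(-lam * tau)


def crossing_frequency(coeffs: LinearCoeffs) -> float | None:
    """Frequency at which a conjugate pair can sit on the imaginary axis,
    omega = sqrt(a^2 - b^2); ``None`` when |a| <= |b| (no Hopf at any
    delay)."""
    disc = coeffs.a**2 - coeffs.b**2
    if disc <= 0:
        return None
    return math.sqrt(disc)


def _crossing_phase(coeffs: LinearCoeffs, omega: float) -> float:
    """theta in (0, 2 pi) with cos theta = b/a and sin theta = -omega/a,
    the quadrant forced by requiring an actual imaginary-axis root."""
    theta = math.atan2(-omega / coeffs.a, coeffs.b / coeffs.a)
    if theta <= 0:
        theta += _TWO_PI
    return theta


def critical_delay(coeffs: LinearCoeffs, branch_j: int = 0) -> HopfPoint | None:
    """Delay at which branch j's conjugate pair crosses the imaginary axis,
    tau_j = (theta + 2 pi j)/omega; ``None`` if no crossing frequency
    exists. The characteristic residual at (i omega, tau_j) is verified to
    < 1e-10."""
    if branch_j < 0:
        raise ValueError("branch_j must be >= 0")
    omega = crossing_frequency(coeffs)
    if omega is None:
        return None
    theta = _crossing_phase(coeffs, omega)
    tau_crit = (theta + _TWO_PI * branch_j) / omega
    res = abs(characteristic_value(coeffs, 1j * omega, tau_crit))
    scale = max(1.0, abs(coeffs.a), abs(coeffs.b), omega)
    assert res < 1e-10 * scale, res
    return HopfPoint(omega=omega, tau_crit=tau_crit, branch_j=branch_j)


def count_unstable_pairs(coeffs: LinearCoeffs, tau: float) -> StabilityCount:
    """Number of conjugate pairs with positive real part at delay tau: the
    number of branches j with tau_j strictly below tau (a pair exactly on
    the axis is not counted)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    omega = crossing_frequency(coeffs)
    if omega is None:
        return StabilityCount(0)
    theta = _crossing_phase(coeffs, omega)
    frac = (omega * tau - theta) / _TWO_PI
    pairs = int(math.ceil(frac)) if frac > 0 else 0
    return StabilityCount(pairs)


def unstable_pairs_oracle(
    coeffs: LinearCoeffs,
    tau: float,
    search_box: tuple[float, float] | None = None,
    n_base: int = 4096,
    max_refine: int = 8,
) -> int:
    """Brute-force count of right-half-plane conjugate pairs by the argument
    principle.

    Evaluates the winding number of h(lambda) = lambda + b - a e^(-lambda
    tau) along a rectangle [delta, R] x [-I, I] enclosing every unstable
    root (|lambda| <= |a| + |b| for Re lambda >= 0), tracking the continuous
    phase on an adaptively refined sampling. Requires a < 0 <= b, which
    excludes real unstable roots, so the zero count inside is twice the pair
    count. Independent of the branch formula it checks.
    """
    if not (coeffs.a < 0 <= coeffs.b):
        raise ValueError("oracle requires a < 0 <= b (no real unstable roots)")
    if search_box is None:
        bound = abs(coeffs.a) + abs(coeffs.b) + 1.0
        search_box = (bound, bound)
    R, I = search_box
    delta = 1e-6

    corners = [
        complex(delta, -I),
        complex(R, -I),
        complex(R, I),
        complex(delta, I),
        complex(delta, -I),
    ]

    for attempt in range(3):
        try:
            winding = 0.0
            for z0, z1 in zip(corners[:-1], corners[1:]):
                winding += _segment_phase_change(
                    coeffs, tau, z0, z1, n_base, max_refine
                )
            total = winding / _TWO_PI
            count = int(round(total))
            if abs(total - count) > 1e-3:
                raise ArithmeticError(f"non-integer winding {total}")
            if count % 2:
                raise ArithmeticError(f"odd zero count {count}")
            return count // 2
        except ArithmeticError:
            # contour too close to a root: jitter and retry
            delta *= 7.3
            R += 0.37 * attempt + 0.11
            I += 0.29 * attempt + 0.13
            corners = [
                complex(delta, -I),
                complex(R, -I),
                complex(R, I),
                complex(delta, I),
                complex(delta, -I),
            ]
    raise ArithmeticError("argument-principle contour failed after retries")


def _segment_phase_change(coeffs, tau, z0, z1, n_base, max_refine) -> float:
    n = n_base
    for _ in range(max_refine):
        ts = np.linspace(0.0, 1.0, n)
        zs = z0 + (z1 - z0) * ts
        h = zs + coeffs.b - coeffs.a * np.exp(-zs * tau)
        if np.min(np.abs(h)) < 1e-8:
            raise ArithmeticError("contour passes within 1e-8 of a zero")
        ph = np.unwrap(np.angle(h))
        steps = np.abs(np.diff(ph))
        if steps.max(initial=0.0) < 0.5:
            return float(ph[-1] - ph[0])
        n *= 2
    raise ArithmeticError("phase sampling did not resolve")


def _coeffs_for(
    synthesis_kind, degradation_kind, n, gamma, x_target
) -> LinearCoeffs:
    spec = calibrate_to_equilibrium(
        synthesis_kind, degradation_kind, n=n, tau=0.0,
        x_target=x_target, gamma=gamma,
    )
    eqs = [e for e in find_equilibria(spec) if not e.is_trivial]
    eq = min(eqs, key=lambda e: abs(e.x_star - x_target))
    return linearize(spec, eq)


def hopf_curve(
    synthesis_kind: SynthesisKind | str,
    degradation_kind: DegradationKind | str,
    n_grid,
    gamma: float = 1.0,
    x_target: float = 1.0,
    branch_j: int = 0,
) -> pd.DataFrame:
    """Bifurcation curve tau_crit(n) for one branch of a calibrated family.

    For each n the model is calibrated to keep the equilibrium at
    ``x_target``, linearized there, and the branch's critical delay
    computed. Grid points with no crossing frequency (or failed calibration)
    are omitted with a logged warning. Columns: n, tau_crit, omega,
    branch_j.
    """
    rows = []
    for n in np.atleast_1d(np.asarray(n_grid, dtype=float)):
        if n < 1:
            raise ValueError("n grid values must be >= 1")
        try:
            coeffs = _coeffs_for(synthesis_kind, degradation_kind, n, gamma, x_target)
        except (CalibrationError, EquilibriumSearchError) as exc:
            logger.warning("calibration failed at n = %g: %s", n, exc)
            continue
        hp = critical_delay(coeffs, branch_j)
        if hp is None:
            logger.warning("no crossing frequency at n = %g; point omitted", n)
            continue
        rows.append(
            dict(n=float(n), tau_crit=hp.tau_crit, omega=hp.omega, branch_j=branch_j)
        )
    return pd.DataFrame(rows, columns=["n", "tau_crit", "omega", "branch_j"])


def dimension_line_slope(
    synthesis_kind: SynthesisKind | str,
    degradation_kind: DegradationKind | str,
    n: float,
    gamma: float = 1.0,
    x_target: float = 1.0,
) -> DimensionLine:
    """Slope of the analytic dimension line at Hill coefficient n.

    Unstable pairs accrue one per 2 pi / omega of delay, so the predicted
    rate of growth of attractor dimension with tau is omega / (2 pi). Zero
    (flagged) when the calibrated model has no crossing frequency.
    """
    coeffs = _coeffs_for(synthesis_kind, degradation_kind, n, gamma, x_target)
    omega = crossing_frequency(coeffs)
    if omega is None:
        return DimensionLine(slope=0.0, has_crossing=False)
    return DimensionLine(slope=omega / _TWO_PI)
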