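# Methods

## The model family

All four models are scalar DDEs `x'(t) = f(x(t−τ)) − g(x(t))` for a protein
concentration `x ≥ 0`. Synthesis is a Hill repressor `f(x) = β/(1+xⁿ)`
(monotonic — pure negative feedback) or the mixed-feedback form
`f(x) = βx/(1+xⁿ)` (rises up to `x = (n−1)^{−1/n}`, then falls); degradation
is Michaelis–Menten `g(x) = γx/(1+x)` (saturable) or first-order `g(x) = γx`.
The two Michaelis constants are taken equal and absorbed into the
concentration unit, so concentrations are measured in units of the
half-saturation constant; likewise `γ = 1` fixes the time unit in all
defaults. The mixed-feedback, first-order-degradation member is then exactly
the Mackey–Glass equation up to time rescaling.

Assumptions inherited from this construction: a single protein species, a
single discrete delay lumping transcription/translation/transport lags,
deterministic kinetics, and no explicit cell growth or dilution term.

### Calibration

The figure protocol holds the equilibrium fixed while `n` and `τ` vary, so
`β` is solved from `f(x*) = g(x*)` at a target `x* = 1` by default
(`β = g(x*)(1+x*ⁿ)` for the repressor, `β = g(x*)(1+x*ⁿ)/x*` for the
mixed-feedback form). With `γ = 1, x* = 1` the calibrated Mackey–Glass
member has `β = 2γ`, i.e. the classic chaotic parameter set sped up tenfold.

### Equilibria and linearization

Equilibria are roots of `f(x) − g(x)`: a dense sign scan (10,000 points on
`(0, max(10, 10β/γ)]`, a range on which the difference is eventually
negative) brackets each root, Brent's method refines it to ~1e−13 in `x`,
and every returned equilibrium satisfies `|f(x*) − g(x*)| < 1e−10`.
Monotonic models provably have exactly one positive equilibrium;
mixed-feedback models always carry the trivial equilibrium `x = 0` as well.
Writing `x = x* + y` gives the linear delay equation
`y' = a y(t−τ) − b y(t)` with `a = f'(x*)`, `b = g'(x*)`.

## Linear stability and the dimension line

The ansatz `y = e^{λt}` gives the transcendental characteristic equation
`λ + b − a e^{−λτ} = 0`. On the imaginary axis `λ = iω`:
`a cos ωτ = b` and `ω = −a sin ωτ`, so a crossing frequency
`ω = √(a² − b²)` exists iff `|a| > |b|`, and the crossing delays are
`τ_j = (θ + 2πj)/ω` with `θ ∈ (0, 2π)` fixed by both conditions jointly
(the residual of the characteristic equation at `(iω, τ_j)` is asserted
below 1e−10). The count of unstable conjugate pairs at delay `τ` is the
number of branches strictly below `τ`; a pair exactly on the axis is not
counted (the boundary convention is ours; the count changes only on a
measure-zero set). Transversality — roots migrating left to right as `τ`
grows — is assumed and verified numerically, not proven.

An independent oracle counts right-half-plane zeros by the argument
principle: the winding number of the characteristic function along a
rectangle `[δ, R] × [−I, I]` with `R = I = |a| + |b| + 1` (a bound on any
unstable root), sampled adaptively until phase steps fall below 0.5 rad,
with jitter-and-retry if the contour passes within 1e−8 of a zero. It is
restricted to `a < 0 ≤ b`, where no real unstable roots exist and the zero
count is twice the pair count.

Because branches accrue one per `2π/ω` of delay, the analytic *dimension
line* has slope `ω/2π` (dimension per unit delay). Its offset is not
predicted — comparisons against measured correlation dimensions fit the
offset and test only the slope.

## Numerical integration

Fixed-step explicit Euler with `dt = 1e−3` time units is the production
scheme; the delayed value is read `round(τ/dt)` nodes back on the solution
grid, and constant history (default `1.1·x*`, optionally with seeded uniform
jitter clamped at zero to break symmetry in chaotic regimes) fills the grid
for `t ≤ 0`. Classical RK4 with linear interpolation of the past at
half-steps provides the step-size adequacy check (`validate_step` reports
the max pointwise Euler-vs-RK4 gap); at the default `dt` the gap on the
oscillatory reference models is ~1e−3 of the unit concentration, and halving
`dt` changes measured periods by well under 0.1%. Trajectories from
non-negative history remain non-negative (degradation vanishes at 0 or is
linear); a non-finite state aborts with the offending step. The transient
discarded before any metric defaults to `max(50τ, 200)` time units, clamped
to 80% of a short run.

## Period and amplitude

A cycle is delimited by down-crossings of the calibrated equilibrium level,
refined by linear interpolation between the bracketing samples; tangential
grazes do not count. The period is the mean of the last K = 10 crossing
intervals, the amplitude the max − min over the final cycle (the one-cycle
window is our reading of the protocol; a whole-run window differs only in
chaotic regimes). A coefficient of variation of the intervals above 0.1
flags an irregular rhythm; a residual amplitude below 1e−6 (rounding-level
wiggle around a stable equilibrium) is reported as "no oscillation".
Sweeps over `(n, τ)` proceed row by row, seeding each run's history with the
final state of the previous grid point (re-perturbing if that state has
settled onto the equilibrium, so the continuation can pick up oscillations
past onset).

## Correlation dimension

The estimator follows the Grassberger–Procaccia/TISEAN pipeline. A
trajectory is downsampled to ~20–24 samples per dominant period (mean
down-crossing interval about the series mean; autocorrelation fallback),
then truncated to at most `max_points` samples. Delay vectors with lag
`min(first autocorrelation minimum, period/4)` are compared in max-norm for
all embedding dimensions `m` up to `m_max` in a single pass; pairs closer
than one dominant period in time are excluded (Theiler window). The
correlation sums on a 48-point log-spaced radius grid are smoothed by the
Gaussian-kernel correlation integral, computed by 200-node Gauss–Legendre
quadrature after substituting `s = 2εu`, with the measured curve continued
beyond its grid as power laws fitted to its end slopes — the transform is
exact on power laws, which is the property relied on.

D2 is extracted from local slopes `d log T / d log ε` restricted to
`10⁻³ ≤ C ≤ 0.9` (below, the sum is dominated by dynamically correlated
near-returns; above, by attractor-size saturation): for each embedding
dimension in the top half of the m-range, the widest ε-window on which the
slope is flat to 15% gives a plateau level, and D2 is the median of those
levels, with their relative spread as the plateau-quality figure. When no
plateaus exist the median of the per-m slope maxima is returned flagged
poor — a lower bound, which is what remains measurable when the true
dimension approaches the embedding range. Validation on signals of known
dimension (sampled sinusoid, two- and three-frequency quasiperiodic sums,
uniform planar noise) reproduces 1, 2, 3 and 2 within ±0.1–0.2; on the
calibrated chaotic member the estimates match the classic published values
at scaled delays 1.7–2.3 and progressively under-read above D2 ≈ 3 at the
series lengths used here (12,000 embedded points), consistent with the
known failure of numerical dimension estimates at high dimension. The lag
cap at a quarter period matters: autocorrelation minima of these broadband
signals exceed half a period and the resulting long embedding windows make
slopes creep upward with `m` without converging.

Dimension-line comparisons therefore scan delays from just below the onset
of complexity (limit cycle, D2 ≈ 1) through developed chaos (D2 ≈ 2.5) —
`τ ∈ {1.0, 1.6, 2.2, 2.8, 3.2}` at `n = 10` for the Mackey–Glass member —
where the estimator operates inside its validated range. At `τ ≈ 3.4` this
model is multistable: depending on the initial history the trajectory lands
on either the high-dimensional chaotic attractor or a coexisting
lower-dimensional one, so that delay is excluded from the default scan
grid. Slopes of D2 vs τ regressions over this grid agree with the analytic
`ω/2π` to within ~10–25% across history seeds.

## Reductions of the monotonic models

For large `n` the repressor is nearly a binary switch between `F_max = β`
and `F_min = 0`. Rewriting the DDE as the chain `u_k' = f(u_{k+1}) − g(u_k)`
over successively delayed coordinates and truncating it with a switch
variable `s` gives:

- **First order:** `x' = s − g(x)`. The switch emulates the delayed
  repressor: after `x` crosses `x*` the synthesis keeps its old state for
  one delay, so the turning points are the one-delay images of `x*` under
  the two extreme flows, `X_A = Φ(s_high, x*, τ)` and
  `X_B = Φ(s_low, x*, τ)`, equivalently the roots of
  `∫ dz/(s − g(z)) = τ`. Both routes are implemented (closed-form flow time
  inverted by Brent vs. adaptive quadrature inside a root search) and agree
  to 1e−8. The orbit is exactly periodic after the first event with a
  closed-form period — manifestly independent of `n`, which is precisely
  the first-order reduction's deficiency.

- **Second order:** `u1' = f(u2) − g(u1)`, `u2' = s − g(u2)`, with `u1`
  playing `x(t)` and `u2` playing `x(t−τ)`. Every DDE trajectory projected
  onto `(x(t), x(t−τ))` is pinned between the one-delay images of the two
  bounding flows — the lower curve `u1 = Φ(s_low, u2, τ)` and upper curve
  `u1 = Φ(s_high, u2, τ)` — which therefore serve as switching curves,
  stored as 2,000-point polylines with monotone cubic (PCHIP)
  interpolation. One curve guards each switch direction: with `s` low the
  phase point drifts toward its lower-right rest state and flips on
  crossing the upper curve outward; with `s` high it drifts upper-left and
  flips at the lower curve. (Watching both curves in both states, the other
  reading of the switching rule, deadlocks: immediately after a flip `u1`'s
  motion reverses only after `u2` responds, so the point grazes the curve
  it just crossed, flips straight back, and escapes the bounded region.
  The one-curve-per-direction rule is the relaxation-oscillator convention
  and is immune to the graze.) Events are located by the ODE solver's
  sign-change root finding on each step; after a flip the event is held off
  for `2·dt` because the state starts exactly on the curve. More than ~10
  events per mean period flags a degenerate (chattering) configuration.

Switch levels default to the synthesis extremes. For the non-saturable
model the second-order reduction instead uses the self-consistent pair — the
two-cycle of the decreasing one-delay return map `ρ → f(ρ/γ)`,
`ρ1 = f(ρ2/γ)`, `ρ2 = f(ρ1/γ)` — solved by damped fixed-point iteration
with a Brent solve on `h(h(ρ)) = ρ` as fallback (residual < 1e−10). A
genuine two-cycle exists exactly when `|h'| > 1` at the fixed point, which
for the calibrated model means `n > 2` — the same threshold as the Hopf
condition; below it the constructor raises rather than returning a
collapsed pair. As `n → ∞` the pair approaches the extremes `(0, β)`.

At `n = 20, τ = 5` the first-order reduction underestimates the DDE period
by ~0.2% (and by construction cannot depend on `n`), while the second-order
reduction is accurate to ~0.01% and reproduces the period's dependence on
`τ` — the qualitative improvement the second order exists for. The
boundary curves bound the actual DDE projections to better than ~1e−4 in
simulation.

## Default sizes and runtimes

Defaults are chosen so the full test suite and the acceptance script each
run in minutes on one CPU: reference trajectories 350–500 time units at
`dt = 1e−3`, chaos-scan trajectories 12,200 time units with 12,000 embedded
points, 100 randomized instances for the root-count comparison. These are
the sizes at which all reported numbers were computed; they are
configuration, not hard limits.

## Known limitations

- The correlation-dimension estimator under-reads above D2 ≈ 3 at these
  series lengths and flags (rather than resolves) higher-dimensional
  attractors.
- The reduction machinery applies only to monotonic synthesis; the
  mixed-feedback models are not reducible this way (their synthesis is not
  step-like in the delayed coordinate).
- Stability analysis of the non-calibrated equilibria of the
  mixed-feedback + saturable model is out of scope; its extra equilibria
  are returned by the generic scan without classification.
- No normal-form computation: super- vs subcritical character of the Hopf
  points is observed in simulation, not derived.
- Dimension-line offsets are free parameters; only slopes are predicted.
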