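# Methods

## The microscopic model

The subject alternates between two states.  In the post-reward state it
chooses a leisure duration `τ` from `[0, τ_max]`, enjoying an innate
microscopic utility `U_L(τ)`; in the pre-reward state it pre-commits to
working for the entire price `P` and then collects a reward of
subjective intensity `R_I` (utility units are arbitrary).  Policies are
densities `π(τ)` scored by the long-run average reward rate

    ρ(π) = (R_I + E_π[U_L]) / (P + E_π[τ]),

and choice maximizes the entropy-regularized objective
`E_π[Q] + H(π)/β`, where `Q(τ) = U_L(τ) − ρτ + V_pre` is the
differential value of leisure and `ρτ` the average foregone reward
(the opportunity cost of committing to leisure for `τ` seconds).  The
maximizer is the softmax `π(τ) ∝ exp(βQ(τ))`, and the model is the
joint fixed point of the softmax and the rate.  `β = 0` gives the
uniform density over `[0, τ_max]`; `β = ∞` gives the deterministic
optimum, which maximizes `(R_I + U_L(τ))/(P + τ)` and, for concave
`U_L`, satisfies `U_L'(τ*) = ρ*` at an interior optimum.

Assumptions worth keeping in view: the work bout is always exactly one
price (no free work-bout lengths, no leisure inserted before the price
is met); `U_L` depends on bout duration only — no fatigue, satiation,
or coupling to the amount of work already done; the reward is
non-satiating; and the cycle repeats indefinitely (trials are windows
onto a stationary process).  There is no explicit "quit" action: when
leisure dominates (linear utility with `C_L > R_I/P`), the
deterministic policy sits at `τ_max` rather than leaving the task.

### Closed-form policies

* linear `U_L = C_L τ`: truncated exponential, rate `β(ρ − C_L)`
  (negative rate = density rising toward `τ_max`, the leisure-dominant
  regime);
* logarithmic `U_L = C_L ln τ`: truncated gamma, shape `βC_L + 1`,
  rate `βρ` (mode `C_L/ρ`, untruncated mean `(C_L + 1/β)/ρ`);
* `log1p` (`C_L ln(1+τ)`, the default concave form because it is finite
  at `τ = 0`): no closed form is exposed; callers fall back to the
  numeric density.

The gap `mean − mode = 1/(βρ)` for the gamma policy is what makes the
typical (modal) leisure bout stagnate while the mean grows as the rate
`ρ` falls at long prices — the mechanism behind time allocation rising
with price for concave utility.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `R_I` | subjective reward intensity (utility) | 10 | mid-range payoff with `P = 5` |
| `P` | price (s) | 5 | short-to-medium price |
| `τ_max` | leisure-duration range (s) | `20·P` | wide enough to dominate the no-truncation mean at the lowest payoffs explored; the admissible range scales with the trial |
| `T` | trial duration (s) | `25·P` | trials are normalized to a fixed multiple of the price |
| `C_L` | marginal-utility coefficient | 1 (linear), 5 (log forms) | places the linear payoff threshold at `P = R_I/C_L = 10 s` and the concave interior optimum at ~1–2 s leisure per cycle |
| `β` | inverse temperature (1/utility) | 1 | visibly stochastic but far from uniform |
| `a` | matching exponent | 2 | over-matching |
| `P_e`, `R_max` | matching anchor | 10 s, 10 | TA = 1/2 at the anchor |

These defaults are fixed study conditions, not tuning knobs; sweeps use
geometric grids `R_I ∈ [1, 100]`, `P ∈ [1, 50]` (20×20) and the
price-reversal scan uses `P ∈ [2, 100]` (20 points) at `R_I = 10`.

## Numerical choices

* Durations live on a uniform grid (`grid_n = 2001` by default) with
  trapezoidal quadrature; densities are normalized by the trapezoid
  rule **on their own grid**, which is the package-wide contract (the
  closed-form `pdf` uses the same rule, so solver-vs-closed-form
  comparisons are pure shape comparisons).
* Fixed point: damped iteration `ρ ← (1−η)ρ + η·rate(ρ)` with
  `η = 0.5`, stopping when the residual `|rate(ρ) − ρ| ≤ 1e-10`, capped
  at 10,000 iterations; on failure (or on request) a bracketing
  root-finder on `rate(ρ) − ρ` over an expanding bracket from
  `[0, R_I/P + C_L + …]`.  Initial `ρ = R_I/(P + τ_max/2)`.
  Non-convergence is flagged on the result, never silent.
* Softmax is computed with max-subtraction; `V_post` is anchored at 0
  (differential values are defined up to a constant; the softmax is
  shift-invariant), giving `V_pre = R_I − ρP`.
* Deterministic optimum: grid argmax (first index on ties — smallest
  `τ`) refined by bounded scalar minimization in the bracketing cell.
* Pure-log utility is `−∞` at `τ = 0`; the solver assigns zero density
  there and masks the node in expectations.  Public evaluation raises
  instead.  Under `β = 0` (uniform) the masked node slightly truncates
  the integrable singularity of `E[ln τ]`.
* Inverse-CDF sampling interpolates the trapezoid CDF linearly;
  duplicate CDF values are dropped to keep it strictly increasing.

## The derived macroscopic utility

With `K` (fractional) cycles and cumulative leisure `L`, the per-cycle
policy is constrained by `K·E_π[τ] = L`.  Enforcing this with a
multiplier `λ` and optimizing the per-cycle utilities plus entropy
gives the constrained softmax `π_λ(τ) ∝ exp(β(U_L(τ) − λτ))` with `λ`
root-found so `E[τ] = L/K` (the mean is strictly decreasing in `λ`;
brackets expand geometrically).  The derived utility is

    W(K, L) = K·(R_I + E_{π_λ}[U_L] + H(π_λ)/β + f(L/K)),

homogeneous of degree 1 in `(K, L)`.  The correction `f` enforces the
average-foregone-reward accounting: it is constructed numerically as
the solution of the linear ODE

    f(ℓ) − (ℓ + P)·f'(ℓ) = −H(π_{λ(ℓ)})/β,

integrated by cubic-spline quadrature on a 257-point per-cycle-leisure
table over `[1e-3, 0.995]·τ_max`.  This is exactly the condition making
the budget-line optimum of `W` coincide with the micro fixed point when
the reward rate contains only microscopic utilities (the default).  `f`
is defined up to a multiple of `(ℓ + P)` — i.e. of `L + K·P`, constant
on every budget line — so the anchor of the quadrature is immaterial to
optima; it is set at the low end of the table.  If the entropy bonus is
instead included in the rate (`include_entropy_in_rate=True`, the
"soft-optimal" reading of the objective), the construction is exactly
consistent with `f ≡ 0`; both variants are exposed because the
entropy-free rate and the entropy-regularized objective are two
defensible conventions that differ at small `β`.

`macro_optimum` parameterizes the budget line by `ℓ = L/K` and solves
the stationarity condition of the evaluator,
`λ(ℓ)P = R_I + ln Z(λ)/β − H/β`, by bracketing (falling back to a dense
scan of the evaluator when no interior stationary point exists, e.g.
at `β = ∞` corners).  At the optimum the stored multiplier satisfies
the shadow-price identity `λ = ρ`.  Limits: `β = ∞` gives
`W = K(R_I + U_L(L/K))`, which for linear `U_L` is the affine
perfect-substitutes labor-supply utility `R_I K + C_L L`; the finite-β
evaluator converges to it pointwise at rate `1/β`.

`derive` requires `β > 0`: the `β = 0` policy is uniform regardless of
`(K, L)`, so no macroscopic utility over allocations can be induced
from it.  The evaluator is finite on the tabulated per-cycle-leisure
range; truncation at `τ_max` keeps every constrained policy proper, so
no further finiteness condition is needed.

## What the simulator emulates — and what it does not

`ethogram_sim` generates the model's own behavior: trials start in the
post-reward state (leisure first; a flag starts with work), alternate
sampled leisure bouts with price-long work bouts, truncate the final
bout at `T`, and log a reward after each completed price.  Consecutive
work bouts separated by zero-length leisure are merged.  This emulates
fixed-length trials of a cumulative-handling-time schedule *after* the
contingency is known; it does not emulate the pre-certainty period at
trial start, within-price leisure interruptions, session-level
nonstationarity (warm-up, satiety), or measurement noise in real
ethograms.  Tests that pass on these synthetic ethograms therefore
validate the sampling and bookkeeping machinery and the model's
internal consistency — not the model's fit to any animal's data.

Finite trials bias empirical TA slightly below the per-cycle value
`P/(P + E[τ])` (the trial ends mid-cycle); at `T = 25·P` the bias is
well inside the 3-standard-error band used by the checks.

## Problem sizes used by the checks

Test-suite and acceptance-script computations use the 2001-point
duration grid (200,001 points for the one closed-form root-finder
comparison, where quadrature error would otherwise dominate), 20×20
sweeps, 100 simulated trials for TA recovery and 10⁴ draws for
distributional tests.  The whole suite runs in well under a minute.

## Known limitations

* The factor by which mode and mean of the pure-log gamma policy move
  between prices is identical (both scale as `1/ρ`); mode stagnation is
  a statement about *absolute* change (coefficients `C_L` vs
  `C_L + 1/β`), and is reported as such.
* Contours and indifference curves are marching-squares polylines on
  the solved grid, deliberately unsmoothed; at coarse grids they are
  angular.
* The damped iteration's convergence constant depends on the payoff;
  near-degenerate regimes (e.g. linear utility at `P = R_I/C_L`, where
  every policy has the same rate) converge in one step but sit exactly
  on the uniform-policy knife edge.
* `λ`-vs-`ρ` and micro-vs-macro agreement are exact properties of the
  *discretized* model; both routes share the duration grid, so grid
  refinement moves both answers together.
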