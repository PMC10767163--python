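# Methods

## The model

A parent enters breeding period `t ∈ {1, …, T}` with reserves
`r ∈ [0, R_max = 1]` and chooses an allocation `(r_i, r_o)` with
`r_i + r_o ≤ r`: `r_i` buys immune defence, `r_o` buys offspring, and any
remainder is carried forward. The components are

- `Φ(r_o) = Φ_max · r_o^α` offspring (concave, `0 < α < 1`; `0^α` is
  defined as exactly 0, the continuous limit);
- `S_current(r_i) = exp(−M·f / (1 + γ·r_i))`, survival through the
  brooding fraction `f ∈ [0, 1]` of the current period;
- `S_future(r_i) = exp(−M / (1 + γ·r_i))`, survival to the next season.

Offspring survive only if the brooding parent survives the current
period, so the per-period reproductive payoff is `Φ(r_o)·S_current(r_i)`.
All per-period quantities are expected values; stochastic realisation
happens only in the forward simulation.

Interpretation of the parameters, with defaults:

| parameter | meaning | default |
|---|---|---|
| `M` | background mortality per breeding period | 1.0 |
| `γ` | survival efficacy of immune investment | 2.0 |
| `f` | brooding/pregnancy fraction of a period | 0.5 |
| `α` | concavity of offspring production | 0.5 |
| `Φ_max` | offspring at full allocation | 100 |
| `T` | reproductive senescence horizon | 20 periods |
| `K` | simulated population size | 200 (2000 for mortality fits) |

`T = 20` and the population sizes are the package's standard study
conditions: `K = 200` is the size at which population-average allocation
trajectories are reported, and mortality-rate fits use `K = 2000` so the
log-linear fit has usable counts over many periods. All sizes are
configurable.

## Semelparous closed form

With one season, fitness is `W(r_i) = Φ_max (r−r_i)^α e^{−Mf/(1+γ r_i)}`.
The stationarity condition is quadratic in `r_i`; the positive branch

`r_i* = [−(2+k) + √((2+k)² − 4(1 − r k γ))]/(2γ)`, `k = M f/α`,

is the maximiser whenever the feasibility condition `r·M·f·γ/α ≥ 1`
holds (the negative branch is always negative there and is discarded).
Below the threshold the fitness is decreasing in `r_i` at 0, so the
boundary `r_i* = 0` is returned rather than "no solution" — the
constrained maximiser exists for every parameter combination even where
the *interior* solution does not. `γ = 0` (investment without effect)
likewise returns the boundary answer. The unconstrained root can exceed
`r` for extreme `(Mf, γ)`; it is clipped to `[0, r]` and flagged.
A grid-search maximiser (`brute_force_optimum`) serves as the
independent oracle throughout the tests.

## Backward induction

`W(r, t) = max_{r_i+r_o≤r} [Φ(r_o)S_current(r_i) + S_future(r_i)·W(r', t+1)]`
with `r' = clip(r − r_i − r_o + g, 0, 1)` and `W(·, T) = 0`. Numerical
choices:

- **Grid.** Reserves on a uniform grid of 101 points on [0, 1];
  allocations restricted to grid multiples. On a uniform grid
  `r − r_i − r_o` lands exactly on a grid point, so only the added gain
  needs interpolation.
- **Interpolation.** Continuation values are linearly interpolated, which
  preserves the monotonicity of `W` in `r`. Refining 51 → 201 points
  moves `W(R_max, 1)` by under 1%.
- **Full triangle.** The solver searches all `r_i + r_o ≤ r`, not just
  exhausting allocations — banking reserves is part of the transition
  rule and is occasionally optimal.
- **Tie-break.** Exact ties in the maximum resolve to the smallest `r_i`,
  then the smallest `r_o` (prefer not investing when indifferent), making
  policies deterministic.
- **Gain cap.** Post-gain reserves are clipped at `R_max = 1`; excess
  gain is wasted.

The deterministic gain schedule defaults to `g(t) = 0.32 + 4e^{−0.5t}`.
This literal form *decreases* with `t`; a saturating variant
`0.32 + 4e^{−0.5/t}` (rising toward an asymptote, matching the verbal
description of growth toward asymptotic size) and a constant schedule are
provided as swappable alternatives, and the discrepancy is deliberately
left visible rather than silently "corrected".

In the stochastic variant the gain is drawn from a discrete Gaussian,
`p(g_n) ∝ exp(−(g_n − ḡ)²/2σ²)` on `g_n = g_min + (n/N)(g_max − g_min)`,
`n = 0..N`. Defaults: `g_min = 0`, `g_max = 1`, `N = 20`, `ḡ = 0.5`,
`σ = 0.4`. σ matches the reported study condition for the
population-average experiments; the support equals the reserve range and
`ḡ` sits at its midpoint, neutral choices where no values are stated.
The parent observes the period's gain *before* allocating, so the policy
is indexed `(r, t, g_n)` and `W(r, t)` is the `p(g_n)`-weighted average
of per-level maxima. A single-point support collapses the stochastic
solver onto the deterministic one exactly (tested to machine precision).
The alternative timing — committing the allocation before observing the
gain — is out of scope.

## Forward Monte Carlo

Per period and per alive individual: draw the gain level through the
inverse CDF (uniform ρ), look up `(r_i*, r_o*)` at the nearest reserve
grid point for `(t, g_n)`, accumulate reproductive credit
`Φ(r_o*)·S_current(r_i*)`, survive with probability `S_future(r_i*)`
(uniform χ), update reserves with clipping. The order is
gain → allocate → survive. Within-season brood loss affects offspring
credit only, never the parent's own death, which is governed solely by
`S_future` — the literal reading of the simulation flowchart this
follows. Initial reserves are drawn from the gain distribution itself
(its support lies inside the reserve range by default). `survivors[t]`
counts individuals alive at the *start* of period `t`, so under a pinned
`r_i ≡ 0` policy the expected fraction after `n` mortality draws is
`e^{−Mn}`. Runs are bit-reproducible from `(policy, K, seed)`.

## Emergent mortality

`M_emergent` is the absolute slope of `log survivors[t]` against `t`,
fitted by least squares *weighted by the survivor count*: the variance of
`log n` for a count `n` is ≈ `1/n`, so equal weights would let the
near-extinct tail (a handful of lingering individuals) dominate and bias
the rate — with `K = 2000` and `M = 1.5` the unweighted slope misses a
known planted rate by ~15%, the weighted one by ~2%. Periods with zero
survivors are dropped (log undefined) and at least three usable periods
are required; faster extinction raises an error rather than returning a
two-point "fit". Analytic bounds `M/(1 + γ·R_max) ≤ M_emergent ≤ M`
hold up to fit noise and are asserted in the tests.

## What the simulations do and do not show

The synthetic populations are exactly the model's own data-generating
process: independent individuals, a stationary gain distribution shared
by all sites, no density dependence, no heritability (offspring are
counted, never instantiated), and a hard senescence cut-off. Passing
tests therefore demonstrate internal consistency of solver + simulator
and the model's qualitative predictions — *not* that real brooding
species obey the fitted rates. γ compresses all host–pathogen dynamics
into one efficacy constant; systems where pathogen pressure feeds back on
behaviour are outside the model.

Directional findings under the standard conditions:

- mean immune investment rises with the brooding fraction `f`, in both
  policy tables and simulated populations;
- emergent mortality stays below the background rate whenever γ makes
  investment worthwhile, and the shortfall grows with `f`;
- short-lived populations (`M = 3.5`) out-invest long-lived ones
  (`M = 1`) at `γ = 4` for intermediate and long brooding
  (`f = 0.5, 0.9`). At `f = 0.1` the ordering *reverses*: with almost no
  brooding exposure and very high background mortality the optimal policy
  abandons immune investment in favour of current reproduction — the
  same high-`M` dip the deterministic policy analysis shows most
  strongly at low `f`. The short-vs-long-lived comparison is therefore
  only asserted where the brooding mechanism operates.

## Known limitations

- Allocations are restricted to reserve-grid multiples; policies inherit
  the grid's 0.01 resolution.
- The discrete Gaussian's realised mean/variance deviate from `(ḡ, σ²)`
  when σ is comparable to the support range (σ = 0.4 on [0, 1] is
  noticeably truncated); this is a property of the stated distribution,
  not a fitting target.
- The emergent-mortality fit assumes a single exponential decay; early
  transients (before allocations settle) are averaged into the slope.
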