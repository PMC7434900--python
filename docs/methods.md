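# Methods

## Model

The package composes two ingredients of deterministic cell-size control:

1. **Division timing.** Newborn sizes follow
   `V_{n+1} = (a·V_n + (2−a)·V̄)/2` with `a ∈ [0, 2]` and fixed point `V̄`.
   The mother divides symmetrically at size `a·V_n + (2−a)·V̄`. Deviations
   from `V̄` decay exactly as `(a/2)^n`, so `a = 0` (sizer) corrects in one
   generation, `a = 1` (adder) halves the deviation per generation, and
   `a = 2` (timer) never corrects (neutrally stable).
2. **Growth.** Within a cycle, `dv/dt = f(v)` with a positive rate law
   `f`. The cycle duration is the inverse-rate integral from birth size to
   division size, floored at a minimum cycle time `T_min`. The floor also
   resolves the degenerate case of a cell born *above* its division size
   (possible for `a < 1` and very large newborns): the signed integral is
   then ≤ 0 and the cell divides after exactly `T_min`, still at the
   mapped division size. This reading is what produces the late recovery
   of the capacity for very large newborns in sizer-adder mixtures.

Proliferation capacity over a horizon `T_f` is `2^(D + r)` where `D` counts
completed cycles (`Σ_{n<D} T(V_n) ≤ T_f < Σ_{n<D+1} T(V_n)`) and
`r = (T_f − Σ_{n<D}T(V_n))/T(V_D)` is the elapsed fraction of the cycle in
progress. Indexing `D` as a *count of completed cycles* (the sum runs
`n = 0…D−1`) is the only convention under which the closed-form cycle sums
below equal their own per-cycle summation and the capacity reaches 2
exactly when the first division completes; with `r`'s denominator taken as
the in-progress cycle's duration the capacity is continuous and
non-decreasing in `T_f`. For `D = 0` the same interpolator gives a capacity
in `[1, 2)`. Note that an alternative convention counting one fewer
division would rescale every capacity by exactly 2; since plotted profiles
are normalized by the capacity at a reference size, the two conventions
produce identical curves (a property the tests assert).

## Parameters

| parameter | meaning | default / preset value | units |
|---|---|---|---|
| `a` | division-timing parameter (0 sizer, 1 adder, 2 timer) | scenario-specific: 1, 0.6 or 1.5 | — |
| `V̄` | homeostatic newborn size | 30 | size (μm-like) |
| `T_min` | minimum cycle duration | 20 | h |
| `T_f` | culture horizon | 72 | h |
| `α` | growth-rate coefficient | 1/48 | 1/h (or size/h for linear) |
| `V_th` | growth-law size scale | 25 (saturating), 20 (Hill) | size |
| `k` | Hill exponent | 3 | — |

Sizes and times are treated as abstract units; nothing converts them. The
Hill-type (`power_saturating`) law is validated for `k > 0` and reduces
exactly to the saturating law at `k = 1`; the rate is non-monotone in size
only for `k > 1`, peaking at `v = V_th·(k−1)^(−1/k)`.

The decreasing-growth scenario (`fig2c`) uses the reciprocal law
`f(v) = α·V_th²/v` as the simplest strictly decreasing positive rate with a
closed-form integral; its `V_th` is set to `V̄ = 30` so the rate matches the
exponential law's `α·V̄` at the fixed point. Any strictly decreasing law
gives the same shape conclusion.

Whether the bell-shape scenarios (`fig3a–c`) share `V̄ = 30`, `α = 1/48`,
`T_min = 20 h`, `T_f = 72 h` with the monotone scenarios is a preset
convention here; only the growth law and `a` differ between presets.

## Numerical choices

* Inverse-rate integrals use closed forms for every built-in law
  (logarithms, polynomials); adaptive quadrature (`scipy.integrate.quad`,
  relative 1e-10, absolute 1e-12) is the generic route for custom laws and
  an independent cross-check everywhere else. Integrals are **signed** so
  that "born above division size" is detectable by the caller.
* Lineages abort with a divergence error after 10,000 generations; this can
  only trigger when `T_min = 0` allows durations to collapse toward zero.
* Shape classification thresholds neighbour differences at a relative
  tolerance of 1e-9, collapses runs, ignores flat stretches, and maps the
  resulting sign pattern (`+` increasing, `−` decreasing, `+−` unimodal,
  `+−+` unimodal-then-increasing, anything else "other"). Shape labels and
  analytically derivable boundary locations are the contract; exact peak
  positions on normalized axes are not asserted anywhere.
* Profile grids default to 200 geometrically spaced founder sizes over
  `[V̄/10, 3V̄]`, wide enough to contain every preset's interior extremum.
* Profile CSVs are written with `%.17g` and read back with round-trip float
  parsing, so a re-read profile is bit-identical.

## The sizer-adder mixture's late rise

For `a < 1` the division size falls below the newborn size at
`V0 = (2−a)·V̄/(1−a)` (105 for the `fig3b` preset). The capacity profile is
bell-shaped for small sizes, reaches a local minimum where the first-cycle
duration is maximal (`V0 ≈ 61` under the preset parameters), then **rises**
as `V0` approaches the boundary — the first-cycle integral shrinks to zero
there and the duration hits the `T_min` floor. The capacity is maximal
essentially at the boundary itself; just past it the profile declines
slowly again, because the first cycle is pinned at `T_min` while the
*second* cycle's duration keeps growing with `V0`, until (far outside the
default grid) the second cycle hits the floor too and the pattern repeats
as a damped staircase. The default `[V̄/10, 3V̄]` grid therefore shows the
clean `+−+` (unimodal-then-increasing) signature; a grid extended past the
boundary picks up the small post-boundary decline and classifies as
"other". This is a real feature of the model, not a numerical artifact.

## Synthetic sorting experiment

`synthetic_population` emulates a size-sorting assay: a lognormal newborn
population (default mean `V̄`, CV 0.25 — positive and right-skewed, chosen
to resemble forward-scatter histograms; the CV is illustrative, not
measured), quantile-sorted into 8 equal-count bins, each bin's fold change
computed as the mean model capacity over the bin's cells at their own
founder sizes (so binning artifacts stay visible). A truncated-normal
distribution and equal-width binning are available as options. What this
does *not* emulate: sorting impurity, apoptosis, FSC calibration, age
structure within a bin, or growth-rate noise — so a passing assay shows the
binning pipeline faithfully transmits the deterministic profile, not that
the model fits any particular measured dataset. Note the bin fold-change
pattern reflects where the population sits relative to the profile: a
population centred right of a capacity peak yields monotone decreasing bin
fold changes even for a bell-shaped profile.

The division-noise check adds i.i.d. Gaussian noise to newborn sizes after
each division (additive by default; multiplicative optional; sizes floored
at `V̄/100`). The map then becomes AR(1) with coefficient `a/2`: newborn
variance converges to `sd²/(1 − a²/4)` for `a < 2` and grows like
`g·sd²` per generation for the timer — the quantitative sense in which
`a = 2` is non-homeostatic.

## Problem sizes

Profiles use 200 grid points; the sorting assay 10,000 cells in 8 bins;
variance checks 1,000 lineages over 50–60 generations; analytic-vs-numeric
equivalence tests 200 random parameter draws per law; the brute-force
ODE oracle (fixed-step RK4, `dt = 1e-3 h`) covers 50 random initial sizes
across the five built-in laws.

## Known limitations

* Deterministic core: no stochastic division timing, no mother/daughter
  asymmetry, no cell death, symmetric division only.
* Capacity is per-founder fold change; no population age structure.
* The sizer's behaviour for founders at or above the division threshold
  (divide after exactly `T_min`) is a modelling choice; the model itself is
  silent there.
* Dimensional reading of "size" (length-like units vs volume) is left
  abstract.
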