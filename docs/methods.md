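# Methods

## Model structure

The package implements continuous-time, two-sex, stage-classified matrix
population models in which mating, birth, and life-cycle transitions are
three simultaneous processes, each described by its own rate matrix on a
common stage space. For maximum harem size `h` the stages are juvenile
males `m1`, single adult males `m2`, juvenile females `f1`, single adult
females `f2`, and union stages `u_1 … u_h`, where `u_i` is one adult male
plus `i` adult females. Monogamy is the `h = 1` special case — there is a
single code path, and a dedicated test confirms the 5-stage matrices are
the `h = 1` instances of the general builders.

The projection matrix is the *average* of the process matrices,
`A = (T + B + U)/3`; the divisor is tied to the number of processes and is
hard-coded at three. Growth rates are therefore expressed on the
averaged-rate time scale; all comparisons made by the package (Δλ between
scenarios) are on the same scale and hence internally consistent.

Assumptions worth stating explicitly:

- New unions always form at the maximum size `u_h`; harems can shrink
  (one female at a time, or total dissolution when the leader dies) but
  never grow.
- Single males re-enter `m2` only when a union dissolves entirely (from
  `u_1`, or by leader death which is itself a dissolution); they never
  leave a standing harem.
- Female mortality inside a union is **one death event per union per unit
  time** (rate `μ_f2` in every union column), not one per female. This is
  the convention of the printed model this package reproduces, and it is
  the entire source of the slight female bias in the polygynous adult sex
  ratio: because harem females share one death event, their per-capita
  mortality is below that of males, and the equilibrium adult sex ratio
  settles just below ½ (≈ 0.490–0.496 across the harem-size/divorce
  grid). Switching on the `per_female_union_mortality` variant
  (`i·μ_f2` in `u_i`) makes both sexes' per-capita schedules identical
  and restores an exactly unbiased ratio — a useful diagnostic, off by
  default.
- Only adults are harvested: `E·s_h` adds to `μ_m2` and `E·(1 − s_h)` to
  `μ_f2`. `apply_harvest` folds this in and zeroes `E` in the returned
  parameter set so the substitution cannot be applied twice.

## Mating functions

All families are generalized weighted (Hölder) means
`M = scale·[β f^α + (1−β) m^α]^{1/α}` with `α < 0`: degree-1 homogeneous,
zero when either sex is absent, monotone in both densities. With
`β = 1/2, α = −1` the mean is exactly `2mf/(m+f)`, the harmonic form used
in every worked model, so the default `scale = 1` needs no correction
factor. The exponent `α → −∞` limit is `min(m, f)`; at finite `α` the
deviation from the minimum is bounded by the factor `β^{1/α}` (≈ 1.4 % at
`α = −50`), which is what the property test asserts.

Numerical care: the Hölder bracket is evaluated in units of the smaller
density so both ratio terms lie in (0, 1] — no overflow at very negative
exponents; underflow of the larger-density term is benign because that
term also vanishes from the exact mean. Degenerate inputs: `M = 0` and
both per-capita rates 0 when `m + f = 0`; when only the own sex is absent
the per-capita rate takes its finite algebraic limit (harmonic:
`U_m → 2`), which multiplies a zero density and so moves no flux.

For polygyny the female argument is the number of prospective harems
`f2/h`, and the female column of U drains at `h·U_f` (a new union absorbs
one male and `h` females). Multiplicity-weighted accounting confirms
union formation conserves individuals exactly.

## Equilibration and growth rate

Because all entries of `A` are degree-0 homogeneous, the composition
`p = n/‖n‖₁` obeys the simplex-projected dynamics
`dp/dt = (I − p1ᵀ)A[p]p`. The equilibrium `p̂` is found by adaptive
Runge–Kutta 4(5) integration (`scipy.integrate.solve_ivp`, RK45) in
checkpoint windows of 10 time units; at each checkpoint round-off
negatives are clipped and `p` renormalized (never inside the right-hand
side, which would distort the integrator's error model). Convergence
requires **both** the windowed change `max|Δp|` and the instantaneous
residual `‖dp/dt‖∞` to fall below `tol` — the dual criterion guards
against slow transients masquerading as equilibria. Defaults:
`tol = 1e−10`, `t_max = 1e4`, uniform initial composition (configurable;
equilibria are verified independent of the start).

Step tolerances default to `rtol = 1e−10`, `atol = 1e−12`, two decades
below the convergence tolerance: with looser steps the per-window
integrator noise floor (~2e−10) sits above `tol` and convergence is never
declared even though the composition is correct to nine digits. The
system is small (≤ 14 stages here), smooth and non-stiff, so the tight
tolerances cost only a few hundredths of a second per equilibration;
typical runs converge within 40–60 time units.

λ is then the eigenvalue of `A[p̂]` with **largest real part** (the
continuous-time Malthusian convention, `e^{λt}` growth — not largest
modulus), guaranteed real here because `A` has nonnegative off-diagonals.
The associated right eigenvector, rescaled nonnegative with unit sum,
must and does coincide with `p̂`; a complex or sign-indefinite dominant
pair raises with diagnostics, and a tie in real part (e.g. the all-zero
matrix) warns that the structure is ambiguous. Two independent routes to
λ — the eigenvalue, and the late-time log-slope of total density from
integrating `dn/dt = A[n]n` directly — agree to better than 1e−4 across
the tested parameter grid. Non-convergence by `t_max` is reported via a
flag with the residual, never an exception: pathological parameter sets
(limit cycles cannot be ruled out in general) are flagged, not resolved.

## Sweeps and summaries

`run_sweep` evaluates the Cartesian product of a parameter grid, records
λ, the secondary sex ratio `s2`, and the mated fraction at each
equilibrium, and differences λ and `s2` against the matched `E = 0`
baseline (same parameter vector with harvest off) — the construction
behind the harvest-response analyses. Everything is deterministic: fixed
integrator settings and initial composition, no randomness, so no seeds.
`s2` counts individuals *inside* unions via the stage-content vectors
(union `u_i` holds 1 male and `i` females); this definition reproduces
both the exact ½ of symmetric monogamy and the ≈ 0.494 female bias of
polygyny, which adjudicates it over counting singles only.

## Scope of the test evidence

There is no synthetic-data generator: the models themselves are the study
system, and all inputs are the printed parameterizations (baseline
symmetric vital rates `μ_juv = 0.5`, `μ_adult = 0.1`, maturation 0.5,
`s1 = 0.5`, `k = 20`; divorce rates 0–2; harem sizes 1–10; harvest
`E ≤ 1`). Passing tests show the implementation is internally consistent
(conservation to 1e−12, dual-route λ to 1e−4, printed matrices
transcribed cell-for-cell) and reproduces the documented equilibrium
behavior *of this model family*; they say nothing about the fit of these
models to any real population, where age-within-stage effects, stochastic
environments, density dependence, and behavioral responses to harvest are
all outside the model class. Known limitations: a single interbreeding
adult class per sex (no stage-specific mating preferences), no polyandry,
no couple-duration structure, no juvenile harvest, and convergence of the
frequency dynamics is checked numerically per run rather than proven.
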