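# bmmr — two-sex matrix population models with explicit mating

`bmmr` builds and analyses continuous-time, stage-structured population
models in which both sexes, and the mated unions they form, are explicit
stages. It is aimed at evolutionary demographers and wildlife managers who
need population-level predictions — long-term growth rate, stable stage
structure, adult sex ratio — for mating systems ranging from persistent
monogamous pair bonds to transient polygynous harems, including the
response to sex-biased harvest.

## The model

A population with stages `(m1, m2, f1, f2, u_1, …, u_h)` — juvenile and
single adult males and females, plus unions `u_i` of one male and a harem
of `i` females (`h = 1` is monogamy) — evolves as

    dn/dt = A[n] n,     A[n] = (T + B + U[n]) / 3,

the average of three simultaneous process rate matrices:

- **U[n]** — union formation. Singles pair at rates set by a mating
  function from the generalized weighted (Hölder) mean family; the default
  harmonic mean gives a total union-formation rate
  `M = 2 m2 (f2/h) / (m2 + f2/h)`, where `f2/h` counts *prospective
  harems*. New unions always form at the maximum size `u_h`.
- **B** — births. A union with `i` females reproduces at rate `i·k`, split
  `s1` male : `1 − s1` female.
- **T** — transitions. Juvenile mortality and maturation, adult mortality,
  and union dynamics: leader death (rate `μ_m2`) dissolves the union and
  frees its `i` females; a female death (`μ_f2`, one event per union per
  unit time) or departure (divorce rate `d`) shrinks `u_i` to `u_{i−1}`,
  and `u_1` dissolves entirely.

Because every entry of `A` depends on `n` only through the composition
`p = n/‖n‖₁`, the dynamics are frequency-dependent and close on the
simplex:

    dp/dt = (I − p 1ᵀ) A[p] p.

Integrating this to its equilibrium `p̂` (the stable stage distribution)
gives the long-term Malthusian growth rate λ as the dominant eigenvalue of
`A[p̂]`. Harvest at total rate `E` with male bias `s_h` adds `E·s_h` to
adult male and `E·(1 − s_h)` to adult female mortality.

## Worked example

```python
import bmmr

space = bmmr.make_stage_space(1)                      # 5-stage monogamy
params = bmmr.ModelParams(h=1, d=0.1, E=0.0)          # baseline rates
res = bmmr.equilibrate(space, params, bmmr.MatingSpec())

print(f"lambda = {res.lam:.4f}")
print(f"s2     = {bmmr.secondary_sex_ratio(space, res.p_hat):.4f}")
print(f"mated  = {bmmr.proportion_mated(space, res.p_hat):.4f}")
```

prints

```
lambda = 0.3312
s2     = 0.5000
mated  = 0.4360
```

The population grows at λ ≈ 0.33 per unit time on the averaged-rate time
scale; with identical male and female vital rates the adult sex ratio is
exactly ½; and at divorce rate 0.1, about 44 % of adults are inside a pair
bond at equilibrium. Sweeping harvest scenarios:

```python
table = bmmr.run_sweep(
    bmmr.ModelParams(h=2, d=0.5, E=1.0),
    {"s_h": [0.0, 0.5, 1.0]},
)
print(table[["s_h", "lam", "s2", "delta_lam", "delta_s2"]])
```

```
   s_h       lam        s2  delta_lam  delta_s2
0  0.0  0.212423  0.675071  -0.151023  0.179507
1  0.5  0.237843  0.479908  -0.125603 -0.015655
2  1.0  0.249546  0.311304  -0.113901 -0.184260
```

Female-biased harvest (`s_h = 0`) costs this small-harem population the
most growth (Δλ = −0.151) and leaves the surviving adults strongly
male-biased, while male-biased harvest depletes adult males (`s2` falls
to 0.31).

The same operations are available from the shell:

```sh
bmmr equilibrate --fixture monogamy_baseline --out eq.json --trajectory traj.csv
bmmr sweep --fixture polygyny_grid --out grid.csv
bmmr matrices --fixture monogamy_baseline --out mats/
bmmr fixtures                     # list named parameterizations
```

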