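# Methods

## Model and scope

The package simulates and analyses the scalar stochastic difference
equation `X_{t+1} = f(X_t, ξ_t) X_t` on the non-negative half line, where
the environment states `ξ_t` are i.i.d. and fitness `f` is continuous,
non-negative, and monotone or unimodal in density for every supported
model. Zero is absorbing. Two standing restrictions follow the theory the
package implements: environments are temporally uncorrelated (no
autocorrelated noise), and the environment space is a finite-dimensional
real vector (each random parameter is one coordinate, coordinates are
independent). Structured populations, demographic stochasticity and
continuous-time analogues are out of scope.

## Geometric-mean fitness

All persistence criteria are expressed through `G(x) = exp(E[log f(x, ξ)])`.
The expectation engine offers three routes:

- **closed form** — registered per (model, noise-family) pair; e.g. the
  Ricker mean log fitness `E r − E a · x` needs only coordinate means, mate
  limitation needs `E log λ` (exact for point-mass, lognormal, gamma and
  positive uniform noise). Requesting an unregistered closed form is an
  error, never a silent fallback.
- **quadrature** — Gauss–Legendre on bounded supports, Gauss–Hermite for
  normal coordinates, and Gauss–Legendre on the [1e−10, 1−1e−10] quantile
  truncation for lognormal/gamma (weights renormalized). Default 128 nodes
  (capped at 64 per coordinate in tensor products); the reported error is
  the half-node refinement difference.
- **Monte Carlo** — seeded i.i.d. draws with the standard error reported.

`log f = −∞` on a positive-probability set (mate limitation at `x = 0`)
yields `E[log f] = −∞` and `G = 0` rather than an error; unbounded limits
propagate as `G = +∞`. Boundary verdicts treat `|log G| ≤ max(3·error,
10⁻⁶)` as "critical": regime classification refuses to call a side there
and returns INDETERMINATE, because classification within numerical error of
`G = 1` is not meaningful.

`G(∞)` uses each model's declared high-density limit; a model without one
is evaluated at densities 10⁶ and 10⁸ and must agree to relative 10⁻³,
else the report is INDETERMINATE.

## Regime classification

`classify_regime` implements the decision trees stated in the README, in
this order: monotone-decreasing models use the (extinction / unbounded
growth / stochastic persistence) trichotomy; monotone-increasing models the
(extinction / unbounded growth / conditional persistence) trichotomy; mixed
models with `G(0) > 1` use the sufficient tail condition — a grid-detected
`x_c` past the maximizer of the mean log fitness with `f` decreasing beyond
it and `G(x_c) < 1`. The general integral form of that condition is not
implemented; the decreasing-tail form is sufficient for every catalogue
model.

For mixed models with `G(0) < 1` the noise decides:

- **large noise** — if some random coordinate makes `log f(x, ·)` unbounded
  below (normal growth-rate noise; lognormal or gamma multiplicative
  factors; flagged per model from its family metadata) *and* the one-step
  growth `x·f(x, ξ̄)` is bounded on the probe grid with its maximum away
  from the right edge, the extinction state is reachable from every density
  and the verdict is unconditional extinction. Both checks are grid-based
  heuristics and are reported as such in the evidence.
- **small (compactly supported) noise** — the verdict defers to the
  deterministic skeleton (below) and carries the skeleton report as
  evidence.

## Deterministic skeleton

`F₀(x) = x f(x, ξ̄)` freezes the environment at its coordinatewise mean —
for the uniform noise families used in the experiments this is the natural
center, and alternative reference environments can be supplied by
evaluating a user-defined model. Numerics:

- smallest positive fixed point `M`: sign-change bracketing of `F₀(x) − x`
  on a 4096-point log grid over [10⁻¹², x_max], refined by Brent's method
  to relative 10⁻¹²; requires `F₀(x_max) < x_max` (default `x_max = 50`,
  far beyond every catalogue skeleton's range).
- critical point `C`: the probe grid must show exactly one interior local
  maximum (unimodality is an explicit assumption; violations raise, they
  are never silently resolved), then bounded scalar maximization.
- verdicts: skeleton fitness above one at zero density ⇒ no Allee effect,
  positive attractor with a global positive basin; fitness below one
  everywhere ⇒ global extinction; otherwise `F₀(F₀(C))` versus `M`, with a
  BOUNDARY verdict inside a 10⁻⁸ relative band where the dichotomy is
  numerically meaningless. The attractor hull is the min/max of a 4096-step
  orbit from `C` after a 1000-step burn-in.

**Invariant-interval certificates.** For a positive-attractor skeleton and
bounded noise support, the certificate iterates worst-case one-step image
bounds `F_lo/F_hi` — evaluated at the corners of the noise support box,
valid because every catalogue fitness is coordinatewise monotone in its
random parameters — from the attractor hull until the interval is a fixed
point of the expansion. Extremes are located on a 4096-point grid and
sharpened by bounded scalar optimization; the final interval satisfies
`F([α, β] × support) ⊆ [α, β]` up to a recorded relative tolerance of
10⁻⁹. Absence of a certificate is reported as `None`, never as a claim of
non-existence. The small-noise extinction check combines an
essential/global-extinction skeleton verdict with bounded noise, the two
low-density Allee assumptions (`G(0) < 1`; fitness increasing near zero,
probed by finite differences over sampled environments), and a numeric
dissipativity check (100 skeleton iterations of a spread of starts settle
below `x_max`).

## Simulation conventions

Densities evolve in linear scale. Values below 10⁻³⁰⁰ clamp to zero;
values above 10³⁰⁰ are capped so that saturating terms like `x/(h + x)`
remain well defined on diverging runs (the cap only affects runs already
twenty decades beyond the explosion threshold). Runs are classified by
final density only — extinct below 10⁻⁸, exploded above 10⁸, interior
otherwise — mirroring the final-density persistence protocol; path minima
are available separately through the minimum-density probe, which estimates
`P[min_{t≤T} X_t ≤ γ]` as a finite-horizon proxy for accessibility of the
extinction state. All finite-horizon verdicts are proxies for limits and
the thresholds are always reported alongside results.

All randomness flows through `numpy.random.Generator`. Every public
operation takes an explicit seed; replicate and grid sub-streams are
spawned with `SeedSequence.spawn`, so results are bit-reproducible and
streams never collide across operations. Common-random-number comparisons
replay a recorded environment sequence through the same iteration code.

## Experiment protocols and defaults

- **Persistence curves** (mate limitation, `λ` lognormal with log-mean 0.1,
  `h = 10`): persistence is final density above 100. The full protocol uses
  10,000 replicates per initial density; the test suite and acceptance
  script run 1,000–2,000, which resolves the curve shape to ±2–3 points.
  The horizon is not part of the protocol statement; the default `T = 1000`
  is insensitive to doubling (verified in the suite). The σ grid
  {0, 0.25, 0.5, 1} and the x₀ grid are package choices recorded in every
  output's metadata.
- **Long-run scatters**: 10,000 steps with the final 1,000 points kept, per
  parameter value and initial density. The mate-limitation–Ricker sweep
  varies the half-width ε of `r ~ U[4.5−ε, 4.5+ε]` (`a = 1`, `h = 10` — the
  same half-saturation as the persistence-curve model, since the protocol
  leaves it open); the predator-saturation–Ricker sweep uses
  `exp(4 − 4x − P/(1/12 + x))` with `P ~ U[P̄(1−ε), P̄(1+ε)]`. The default
  initial-density set is a geometric 8-point grid on [10⁻², 10], recorded
  in metadata. The scaled predation sweep uses P̄ ∈ {0.15 … 1.0}, ε = 0.2,
  and starts up to 1.0: for this strongly overcompensating map, densities
  much above 1 are thrown to near zero in one step, so "high" initial
  densities meaningfully means the top of the attractor's basin.
- **Regime maps** classify each grid cell (regime + skeleton verdict) and
  attach a small corroborating ensemble; per-cell errors are logged in the
  table, never raised.

Scaled problem sizes throughout (hundreds of replicates, 10³–10⁴ steps)
were chosen so the full suite exercises every protocol end-to-end in well
under a minute per experiment while keeping Monte-Carlo standard errors
small relative to the effects asserted.

## What the synthetic experiments do and do not show

All data are generated by the models themselves; there is no observational
input. The experiments therefore validate the implementation against the
theory's predictions (trichotomies, skeleton dichotomy, noise-induced
threshold shifts) under exactly the stated noise families. They do not
establish anything about real populations: real environments are
autocorrelated, vital-rate distributions are rarely lognormal/uniform, and
demographic stochasticity — absent here — dominates at the very low
densities where Allee effects matter most.

## Known limitations

- The Liebhold–Bascompte fitness `exp(γ(x − C) + ξ)` is a reconstruction
  from the qualitative properties of the original (log-linear density
  dependence, additive zero-mean normal noise, `f(0) < 1 < f(∞)`); use it
  for qualitative experiments only.
- Accessibility and invariance are certified numerically (grid + corner
  bounds), not by interval arithmetic; certificates carry their tolerance.
- The unstable positive periodic orbits that coexist with essential
  extinction are not detected; only the attractor/essential-extinction
  dichotomy is computed.
- The noise threshold at which a positive attractor loses its invariant
  interval is reported by sweeping ε, not computed in closed form.
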