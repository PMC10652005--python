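# Methods

## The model

`youthprev` implements a linear four-compartment stock-flow model of
mental-disorder onset and progression in a youth population (ages 12–24).
The stocks are:

- **N** — asymptomatic, not vulnerable (low onset risk);
- **V** — asymptomatic but exposed to one or more risk factors that raise
  onset risk (vulnerable);
- **S** — experiencing subthreshold symptoms (mild, non-specific, clinical
  stages 1a–b);
- **D** — full-threshold mental disorder (stages 2–4).

The flows are

```
dN/dt = (1 − φ)·g − u·N − (λ + μ)·N
dV/dt = φ·g − θ_eff·u·V − (λ + α·μ)·V
dS/dt = u·N + θ_eff·u·V − i·S − (λ + β·μ)·S
dD/dt = i·S − (λ + γ·μ)·D
```

with `θ_eff = 1 + h·(θ − 1)`. Adolescents turning 12 enter at `g` persons
per year, a fraction `φ` of them vulnerable; there are no flows between N
and V (risk of becoming vulnerable is assumed stable through youth) and no
migration. `u` is the per capita symptom-onset rate of the non-vulnerable
population and `θ ≥ 1` the onset hazard ratio of the at-risk vulnerable
population; `h ∈ [0, 1]` is the fraction of the vulnerable stock still at
increased risk (1 before selective prevention). `i` is the per capita
progression rate from subthreshold symptoms to disorder. Everyone ages out
at `λ` per year and dies at `μ` per year scaled by the stock-specific
mortality hazard ratios `1 ≤ α < β < γ`.

Assumptions worth keeping in mind: the model is aggregate (no individual
heterogeneity in risk, comorbidity, age or intervention response), rates
are constant in time, and recovery flows out of S and D are not modelled —
the equilibrium prevalences absorb whatever recovery occurs empirically
through the calibrated rates.

### Equilibrium and stability

The coupling is strictly feed-forward (N, V → S → D), so setting the
derivatives to zero solves sequentially:

```
N* = (1 − φ)·g / (u + λ + μ)
V* = φ·g / (θ_eff·u + λ + α·μ)
S* = (u·N* + θ_eff·u·V*) / (i + λ + β·μ)
D* = i·S* / (λ + γ·μ)
```

Correctness is enforced by property tests (the flow field must vanish at
the closed-form stocks, to 1e−10 relative, over randomized parameter
draws, and the stocks must agree with a dense linear solve of `J·y = −b`)
rather than by transcription of any particular algebraic form.

The Jacobian is lower-triangular in the ordering (N, V, S, D), so its
eigenvalues are the negated per capita removal rates of the four stocks:
`−(u+λ+μ)`, `−(θ_eff·u+λ+αμ)`, `−(i+λ+βμ)`, `−(λ+γμ)`. All are strictly
negative whenever rates are positive: the equilibrium is always stable,
and the slowest eigenvalue — `−(λ+γμ) ≈ −0.0775`/yr at the default rates —
sets a relaxation timescale of ≈13 years. Covering 90% of a prevalence
change therefore takes ≈ ln(10)/0.0775 ≈ 30 years, which is why the full
population-level effect of a permanently maintained intervention is only
realised over decades.

Useful identity: at any equilibrium `D*/S* = i/(λ+γμ)` exactly; the
calibration exploits it.

## Parameters and defaults

| symbol | meaning | default | unit | origin |
| --- | --- | --- | --- | --- |
| φ, θ | vulnerability structure | scenario inputs | —, hazard ratio | varied per analysis |
| u | onset rate, non-vulnerable | calibrated | /person-yr | root-found to baseline target |
| h | vulnerable fraction at risk | 1 pre-intervention | — | reduced by selective prevention |
| i | progression rate | 0.03251 | /person-yr | Australian prevalence estimates |
| λ | ageing-out rate | 0.07692 | /person-yr | 1/13 years in the 12–24 window |
| μ | mortality, non-vulnerable | 0.0003343 | /person-yr | Australian youth mortality |
| α, β, γ | mortality hazard ratios | 1, 1.2, 1.673 | — | V, S, D stocks respectively |
| P0 | population | 1,000,000 | persons | calibration target |

Prevalences are proportions in [0, 1] internally; percent formatting
(two decimals) happens only in reporting.

## Calibration

`PreventionModel.fit()` calibrates in a fixed order, each step independent
of the later ones:

1. **i** (closed form, optional): `i = (λ+γμ)·target_prev_D/target_prev_S`
   from the D*/S* identity — independent of φ, θ, u, g. With the default
   targets this gives 0.0324913; the published table prints 0.03251, a
   0.057% difference attributable to rounding of the printed inputs (the
   unrounded prevalence estimates behind the published value are not
   recoverable). The package documents the discrepancy rather than hiding
   it; passing `i=0.03251` reproduces the published configuration, in
   which case the equilibrium subthreshold prevalence matches its 18.6%
   target only to that same rounding (18.59%).
2. **u** (root-finding): equilibrium disorder prevalence is strictly
   increasing in u, from 0 toward an analytic supremum (the two-compartment
   S/D limit as u → ∞, computed up front to pre-validate feasibility), so
   the root is unique. A bracketed Brent solve on an auto-expanded interval
   is used, with an absolute residual check at 1e−12 on the prevalence.
   Infeasible targets fail loudly, naming the supremum.
3. **g** (linear scaling): all stocks are linear in g, so a single
   evaluation at g = 1 gives `g* = P0 / total_at_g1` exactly.

This convention — recalibrating u at h = 1 for every (φ, θ) — makes all
scenarios share the identical pre-intervention prevalence, so
post-intervention prevalences are directly comparable across scenarios.

## Interventions

Each prevention type reduces exactly one parameter: universal scales
`u` by `(1 − effect)`, indicated scales `i` by `(1 − effect)`, selective
decrements `h` by `effect` (absolute = proportional when the
pre-intervention h is 1; a decrement beyond the remaining h clamps to 0
with a logged warning). Effects touch disjoint parameters, so stacked
portfolios compose order-independently. All population-level effects are
evaluated at the new equilibrium, i.e. they are long-run effects of
permanently maintained interventions.

Two structural consequences the tests pin down: universal and indicated
interventions of equal individual-level effect are nearly equally
effective (within 0.2 percentage points of prevalence for effects ≤ 0.4
at φ=0.4, θ=2 — a conservative quantification chosen here, verified
against the closed form, not an external constant), and selective
prevention is bounded: at θ = 1 it does nothing, and even full coverage
(h → 0) leaves the non-vulnerable onset flow untouched.

## Dynamics

Transients are integrated with a hand-rolled fixed-step classical
Runge–Kutta scheme (default step 0.1 yr). The system is linear and
non-stiff at these rates (all removal rates ≲ 0.12/yr), so RK4 at this
step is converged far below reporting precision (halving the step moves
prevalences by < 1e−8, asserted in tests) and the scheme is exactly
deterministic — simpler to reproduce than an adaptive solver, which is why
`scipy.integrate` was not used here. An intervention switch is forced onto
the time grid and applied exactly once. Trajectories start at the
pre-intervention analytic equilibrium rather than burning in: the
pre-switch segment is flat by construction, with identical results.

`time_to_equilibrium` reports the first time after the switch at which the
prevalence enters an ε-band around the target *and stays there*; it is
monotone in ε and returns NaN when the band is never held.

Numerical details: tiny negative stocks from round-off are clipped to zero
after integration; a zero-inflow model equilibrates to the empty
population, whose prevalence is reported as NaN and flagged rather than
raised, keeping sweeps robust; a model with all removal rates zero has no
equilibrium and raises.

## Sensitivity surfaces

`phi_theta_grid` recalibrates u in every cell and evaluates the
equilibrium at a post-intervention h (default 0.5, a halving of the
at-risk fraction); infeasible cells (targets above the supremum) are
reported as NaN, never clamped. `effect_curves` sweeps all three
intervention types over a common calibrated baseline. Default resolutions
(φ step 0.05, θ step 0.25, effect step 0.02) are fine enough that the
monotone structure is visible and coarse enough that a full reproduction
run takes ~2 s on one core.

## Synthetic risk-factor catalogues

Real risk-factor estimates (childhood trauma, parental mental disorder,
socioeconomic disadvantage, …) are summarised by two robust features: most
onset hazard ratios are modest (the generator's default target is that
74.42% fall below 2) and φ and θ are inversely related — common exposures
carry small relative risks, rare exposures the large ones (θ > 3 pairs
with φ ≲ 0.1). The generator draws log θ from a normal truncated to the
configured range, with its location solved by root-finding so the expected
fraction below 2 hits the target exactly; log φ is linear in −log θ with
Gaussian noise (defaults: slope 1, intercept −1.2 so that θ ≈ 3 maps to
φ ≈ 0.1, noise SD 0.5), with out-of-range draws redrawn. The catalogue is
deterministic under a fixed seed.

What the synthetic catalogues do **not** emulate: the identity of real
risk factors, their estimate uncertainties, correlations between factors,
or any per-factor fidelity — only the marginal θ constraint and the
inverse φ–θ association. Tests passing on these catalogues therefore show
that the *portfolio-level conclusion* (selective prevention against any
single empirically plausible risk factor reduces prevalence less than a
moderately effective universal intervention) follows from that coarse
structure alone; they say nothing about any specific real factor.

## Problem sizes and runtimes

The package's own test suite runs in a few seconds: equilibrium and
calibration are closed-form-plus-scalar-root-find (microseconds to
milliseconds), a 1,300-year trajectory at step 0.1 is 13,000 RK4 steps
(~0.2 s), the default φ×θ grid is 399 calibrated cells (~1 s), and the
distributional checks on the generator use n = 10,000 draws. These sizes
were chosen as the smallest at which each qualitative claim is sharply
testable.

## Known limitations

- Aggregate dynamics only; no age structure, no individual heterogeneity,
  no stochasticity (demographic noise matters at small populations).
- Rates are time-invariant; time-limited or waning interventions, coverage
  and uptake, and cost-effectiveness are out of scope.
- The calibrated u and i are tied to the Australian prevalence estimates;
  alternative targets are accepted as configuration but no other
  population's values ship with the package.
- Selective-intervention stacking composes decrements on the remaining h;
  empirical evidence on stacked selective programmes is not modelled.
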