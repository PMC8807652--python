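# Methods

## Model

The drilled tooth is a one-degree-of-freedom oscillator in the axial
direction with three ingredients:

1. **Strongly nonlinear elasticity.** The restoring force is
   `F_e = k u|u|^(α−1)` with a non-integer order α ≥ 1; for real teeth α is
   measured in (1, 1.1]. The odd signed-power form keeps the force law
   well-defined for negative deflection and non-integer α.
2. **Linear mass loss.** The drill removes material at a constant volumetric
   rate, so `m(t) = m0 − c t` with `c = ρ D² π n f_r / 4` (density ρ, drill
   diameter D, spindle speed n in rev/s, feed f_r in mm/rev). The schedule
   refuses evaluation past the depletion time m0/c.
3. **Forces of drilling.** The steady axial drilling force `F_f = K_f D f_r`
   (the short entry transient is out of scope), and the reactive
   (Meshchersky) force `(dM/dt) u̇` that any body with time-varying mass
   experiences. Moved to the right-hand side of the equation of motion the
   reactive term is `+c u̇`: for decreasing mass it pumps energy into the
   oscillation.

Full equation of motion, in g/mm/s units throughout:

```
m(t) ü + k u|u|^(α−1) = c u̇ + F_f .
```

Initial conditions are a small deflection u0 and an impact velocity v0; the
heuristic `v0 = F_f / n` (momentum transferred per revolution) is available
when v0 is not given directly.

The feed rate (mm/rev, order 10⁻²) is the natural small parameter: the mass
lost per oscillation cycle is tiny, which is the adiabatic regime the
averaging below requires. The implementation works in physical time with
physical coefficients and never manipulates a slow-time variable explicitly —
the averaged laws end up algebraic in m(t), so none is needed.

## Generalized trigonometric (Ateb) functions

The unperturbed oscillator `ẍ + K x|x|^(α−1) = 0` is solved exactly by
`x = A sin_{2,α+1}(ωt + θ)` with `ω = A^((α−1)/2) √(2K/(α+1))`. On the first
quarter-period the sine is the inverse of the phase integral
`ψ(s) = ∫₀^s dw/√(1−w^(α+1))`, which the substitution `z = w^(α+1)` turns
into a regularized incomplete beta function; the evaluator therefore calls
`scipy.special.betaincinv` and is accurate to machine precision (no ODE
drift). The full period is `2Π_α = (4/(α+1)) B(1/(α+1), 1/2)`.

Beyond the first quarter-period the function is extended by the symmetries
forced by the symmetric potential: reflection about the half-period,
oddness, and 2Π_α-periodicity. The cosine is the phase derivative of the
sine, computed as `±√(1 − |sin|^(α+1))`, positive on the half-period
centered on ψ = 0 (so cos(0) = 1). The derivative rule
`d cos/dψ = −((α+1)/2) sin|sin|^(α−1)` uses the odd signed power, which is
the only reading that stays real for non-integer α.

An optional `QuarterPeriodTable` fast path (monotone PCHIP on 2048
sine-spaced nodes, clustered toward the quarter-period where the inverse has
a square-root branch) evaluates to ~1e-10 of the exact route; the exact
inversion is the default everywhere.

Period averages used by the averaging method: the odd combinations vanish
and `⟨cos²_{2,α+1}⟩ = (α+1)/(α+3)`.

## Averaged solution

Writing the perturbed solution as `x = A(t) sin_{2,α+1}ψ(t)` with
`ψ̇ = ω + θ̇` and averaging the amplitude/phase equations over one GTF period
gives `θ̇ = 0` and closed-form power laws in the instantaneous mass. Three
regimes are exposed:

| regime | amplitude | frequency exponent of (m0/m) |
|---|---|---|
| with_reactive | `A0 (m0/m)^{1/(α+3)}` | `(α+1)/(α+3)` |
| no_reactive | `A0 (m/m0)^{1/(α+3)}` | see below |
| constant_mass | `A0` | 0 |

The with-reactive amplitude does not depend on k, and both of its laws rise
as m falls; at α = 1 the frequency reduces exactly to `√(k/m)` and the
amplitude to `A0 (m0/m)^{1/4}`.

**No-reactive frequency ambiguity.** The published relation for the
no-reactive regime has frequency proportional to `(m/m0)^{(α+1)/(α+3)}`
(falling with m), but substituting that regime's amplitude into
`ω = A^((α−1)/2) √(2k/((α+1)m))` instead yields exponent `−2/(α+3)` of
(m/m0) (slightly rising). The two conflict; both are implemented
(`freq_mode="printed"` default, `"consistent"` alternative), neither is
endorsed, and nothing downstream depends on the choice. All three regimes
coincide at m = m0.

**Phase.** `ψ(t) = θ0 + ∫₀^t ω(m(t')) dt'`, computed by composite Simpson
quadrature on the caller's grid (`scipy.integrate.cumulative_simpson`). For
the linear schedule the exact antiderivative of `C (m0 − c t)^p` is also
provided (`phase_closed_form`) and is the quadrature's oracle in the tests
(agreement ~1e-9 on the worked example's grids).

**Waveform.** The displacement is reconstructed through the inverse of the
variable substitution that removed the constant drive:

```
u = ( A(t)^α sinψ|sinψ|^(α−1) + F_f/k )^{1/α},
```

with the outer 1/α root taken as a signed power `y ↦ sign(y)|y|^{1/α}` so
the expression stays real and continuous when the bracket goes negative
(the published expression is silent on that case). For α = 1 this is
exactly `A sinψ + F_f/k`. The per-cycle positive peak is then
`(A(m)^α + F_f/k)^{1/α}`, the envelope against which numeric peaks are
compared. Note that with this composition the reported worked-example
offset constant (0.0194) is not an independent additive term; the waveform
uses the composition, not a re-derived offset.

The frequency law collapses algebraically (no fitting) to `ω(m) = C m^p`
with `C = ω(m0) m0^{-p}` and `p = −(α+1)/(α+3)` in the reactive regime
(`power_law_coefficients`).

## Numeric oracle

The full equation of motion is integrated by `scipy.integrate.solve_ivp`
with the DOP853 adaptive 8th-order pair at rtol 1e-10 / atol 1e-12
(defaults), dense output sampled on a uniform grid; a fixed-step classical
RK4 integrator (20 substeps per output interval by default) is the second,
independent route and agrees to <1e-6 on the worked example. Tolerance
refinement by 10 changes extracted peak amplitudes by <1e-5 relative;
constant-mass unforced runs conserve energy to better than 1e-7 relative
over 50 cycles for α ∈ {1, 1.03, 1.1}.

**Envelope extraction.** Peaks are located by a 3-point local-maximum test
refined with parabolic interpolation (the trajectory must carry ≥ ~40
samples per cycle). Periods come from successive upward zero crossings of
the signal minus a one-cycle running mean — the detrending neutralizes the
constant drive offset F_f/k — with linear interpolation between samples.
Crossings within half a detrending window of either end of the trajectory
are discarded (the running mean is edge-biased there and distorts the
first/last period estimate). Instantaneous frequency is reported both as
2π/period and as 2Π_α/period (the GTF phase units the averaged law
predicts).

**Comparison.** `compare` reports the pointwise max |u| difference (phase
drift makes this grow long before the envelopes disagree — it is
informational), the per-cycle relative envelope error between independently
extracted envelopes matched in time by interpolation, the per-cycle relative
period error, and the first time the envelope error exceeds a threshold
(default 5%, this package's own quantification of "negligible difference",
applied over a 200 s window in which the worked example's mass falls
1.32 → 0.92 g, m0/m ≤ 1.43 — still well inside the adiabatic regime; the
measured per-cycle error there is ≈0.1%).

## Problem sizes and defaults

The standard comparison runs 200 s of the worked example at output spacing
0.02 s (≈ 30 cycles, ≥ 300 samples per cycle); energy-conservation checks
run 50 cycles; GTF oracle integrations run a few periods at rtol 1e-12.
These sizes keep every property well resolved while the whole suite runs in
seconds.

## Known limitations

- One axial degree of freedom; no drill-tooth contact events, thermal or
  surface-roughness effects, and no transient entry-force phase.
- The linear mass schedule and constant drilling force idealize a steady
  cut; real feeds vary.
- `v0 = F_f/n` is a heuristic; a published variant of it
  (`πDF_f/v` with an undefined v) is dimensionally unclear and not
  implemented.
- The averaging laws assume slow mass loss; as m0/m grows large the
  envelope error grows (the comparison window deliberately stays within
  m0/m ≤ 1.43).
- The worked example's mass slope 0.002 g/s is an input, not recomputed
  from density (the example's ρ and n are not part of the preset).
- The first-order averaged laws carry no O(ε²) corrections; stiff behavior
  for α outside [1, 3] is unsupported.
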