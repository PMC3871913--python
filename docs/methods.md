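# Methods

## Model and assumptions

The system couples one predator to two prey through bilinear
Lotka–Volterra interaction terms with logistic self-limitation in every
species. The predator declines exponentially (rate `a30`) without food
and gains from both prey; there is no prey switching, spatial structure,
stochastic demography, or delay. Prey die-offs are idealized as
instantaneous proportional removals: the fraction removed (`alpha`,
`beta`) and the period `T` are fixed, which models synchronized
semelparous flowering as a deterministic, periodic disturbance. The phase
offset `l` is restricted to the open interval `(0, 1)` so that one prey-1
pulse falls strictly inside every `(nT, (n+1)T)` window: the admissible
range is not forced by the dynamics, but the open interval guarantees the
two reset maps act at distinct instants, which the monodromy construction
assumes. Should a caller ever force coincident pulses, the two maps
commute (they act on disjoint components), so the order is immaterial.

Pulses act on the left limit, `x(t+) = (1−θ) x(t)`, and trajectories are
recorded with the pre-pulse value in the sample array and the post-pulse
value in the event log; integration resumes from the post-pulse value.

## Closed forms and their verification

Three closed forms carry the analysis, none of which is taken on faith;
each has an independent numeric oracle in the test suite:

* **Logistic flow** `x(dt) = a x0 e^{a dt} / (a + b x0 (e^{a dt} − 1))` —
  checked against high-order ODE integration (DOP853, rtol 1e−13) to
  relative 1e−9.
* **Stroboscopic fixed point**
  `x0+ = a((1−θ)e^{aT} − 1)/(b(e^{aT} − 1))` — checked against
  brute-force iteration of the flow-then-pulse map to 1e−12. The fixed
  point exists iff the per-cycle net log-growth `ln(1−θ) + aT` is
  positive; nonexistence is a result value (`None`), not an exception, so
  scans can tabulate it.
* **Orbit integral** `∫₀ᵀ x*(t) dt = (ln(1−θ) + aT)/b` — checked against
  adaptive quadrature of the sampled orbit to relative 1e−6.

The derivative of the stroboscopic map at its fixed point is
`e^{−aT}/(1−θ)`, which is therefore the prey Floquet multiplier. Some
printed treatments simplify this multiplier to `e^{−aT}` (dropping a
`1/(1−θ)` factor); the numerically integrated monodromy matrix resolves
the discrepancy in favor of `e^{−aT}/(1−θ)`, and `FloquetReport` carries
both values (`lambda1` vs `lambda1_printed`) with a flag recording which
one the monodromy matches. The stability conclusion is identical either
way, because the orbit-existence condition makes both expressions < 1.

The predator multiplier `λ₃` follows from integrating the decoupled third
variational row along the orbit, using the exact orbit integrals. The
numeric monodromy integrates the full variational matrix along the
closed-form orbit (DOP853, rtol 1e−12) with the two diagonal reset
matrices applied at their scheduled instants, starting just after the
prey-2 pulse; agreement with the analytic `λ₃` is required to 1e−6
relative and observed at ~1e−11 over hundreds of random sets.

## Boundedness

The weighted population `V = (a31/a13) x1 + (a32/a23) x2 + x3` does not
increase at pulses and satisfies `dV/dt + a30 V ≤ D` between them, where
`D` is the sum of the maxima of the two concave quadratics
`(a3i/ai3) xi (ai0 + a30 − aii xi)`. Note the conversion weight
multiplies the *entire* bracket, including the `a30` contribution from
`a30·V`; an alternative grouping that leaves `a30` unweighted fails to
bound `dV/dt + a30 V` whenever `a3i > ai3` (a seeded random simulation
exhibits `limsup V` above that smaller constant, and the test suite
retains the envelope check that would catch such an error). Integrating
the differential inequality gives the exact pointwise envelope
`V(t) ≤ V(0+) e^{−a30 t} + D(1 − e^{−a30 t})/a30`, which is what the
boundedness tests assert on every random trajectory (with 0.1% numerical
slack), plus the asymptotic bound `D/a30` after the transient on
long runs. The componentwise bound `M = max_i (ai3/a3i) D/a30` feeds the
permanence side conditions.

## Classification

The regime label is decided in this order: failure of either prey orbit's
existence condition (`no_bamboo_orbit`); `λ₃ < 1` (`panda_free_stable` —
by the global-stability result this is predator extinction, not merely
local stability); the full permanence certificate, requiring `λ₃ > 1`
and both side conditions `ln(1−α) + (a10 − a13 M) T > 0`,
`ln(1−β) + (a20 − a23 M) T > 0` (`permanent_certified`); then either
single-prey certificate `−a30 T + (a3i/aii)(ln(1−θi) + ai0 T) > 0`,
prey 1 checked first (`subsystem1_permanent`, `subsystem2_permanent`);
otherwise `unstable_uncertified`. All conditions are sufficient
certificates only: `unstable_uncertified` means the predator invades but
no analytic permanence certificate applies, and simulation is the only
remaining evidence — it is never read as non-permanence. The side
conditions are evaluated with the `M` above because the certificate's
statement only requires "an upper bound of the solution"; the symmetric
`(a20 − a23 M)` form is used for prey 2.

## Simulation

Pulse times are known a priori, so the simulator integrates the smooth
vector field between consecutive scheduled pulses (LSODA, adaptive,
stiff-capable) and applies the reset map exactly at each instant — no
event detection, no accumulation of event-location error. Defaults are
rtol 1e−9 / atol 1e−12 where trajectories feed quantitative checks, and
1e−6 / 1e−9 for regime scans, where only tail-level behavior matters.
No positivity floor is imposed: nonnegativity must emerge from the
dynamics and is asserted (to −atol) over seeded random draws.
Numerical extinction is declared at a tail maximum below 1e−6 and
numerical permanence at a tail minimum above `1e−3 × D/a30`; both
thresholds are arguments, not constants baked into the library.

## Fixture generation

`generate_fixture(regime, seed)` rejection-samples parameter sets from
regime-specific proposal boxes until the classifier returns the requested
label *and* the defining exponent clears a margin (default 0.1). The
margin places fixtures in the interior of their regime: a stability
exponent of −0.1 contracts the predator by e^{−0.1} per period, so a
200-period run resolves extinction (≈ e^{−20}) well below the 1e−6
threshold, and symmetric reasoning applies to invasion. The prey
existence margins are similarly required to exceed 0.2 so stroboscopic
convergence is briskly geometric. Draws are deterministic given
`(regime, seed)`; `unstable_uncertified` cannot be requested because it
is defined by the absence of a certificate. Fixtures emulate the
analytically tractable disturbance (fixed fraction, fixed period); real
bamboo die-offs vary in severity and timing, stands are spatially
patchy, and regeneration takes a decade or more, so passing tests
demonstrate the internal consistency of model and analysis, not a
calibrated forecast for any real panda habitat.

## Problem sizes

The default verification runs use: 50 random pulsed-logistic subsystems
for the integral identity; 200 random parameter sets for the monodromy
oracle (100 in the standalone script); 10 extinction and 10 persistence
fixtures simulated for 200 pulse periods each; and 1000 random
trajectories over 15 time units (300 in the script) for positivity and
the boundedness envelope, with five 300-time-unit runs from large initial
states for the asymptotic bound. These sizes complete in a few minutes on
one core while leaving the statistical checks comfortably redundant.

## Known limitations

* The permanence certificates are conservative: for the canonical
  parameter set they fail for every `T` even where simulation shows
  robust persistence, because `M` is a crude solution bound.
* `T*` is reported only when its defining ratio is positive (numerator
  and denominator both negative); otherwise classification falls back to
  the sign of `ln λ₃` directly, since the rewriting divides by a quantity
  of unknown sign.
* Near the existence boundary (`ln(1−θ) + aT → 0+`) the periodic orbit
  and the multipliers degenerate continuously to zero; fixtures avoid
  this neighborhood, and analyses there should reduce tolerances.
* No bifurcation continuation is attempted beyond parameter scans, and
  basins of attraction are not estimated.
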