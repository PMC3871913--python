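# pulseprey

Simulation and stability analysis of an impulsive one-predator/two-prey
system, motivated by the giant panda and its two staple bamboo species.
Many bamboos reproduce by synchronized semelparity — whole stands flower,
seed, and die at once — so the panda's food supply is periodically and
abruptly reduced. `pulseprey` models each die-off as a proportional
removal pulse on top of Lotka–Volterra dynamics and answers the central
question analytically: **for which pulse periods does the predator
survive?**

## Model

Between pulses the bamboo densities `x1`, `x2` and the panda density `x3`
follow

```
dx1/dt = x1 (a10 − a11 x1 − a13 x3)
dx2/dt = x2 (a20 − a22 x2 − a23 x3)
dx3/dt = x3 (−a30 − a33 x3 + a31 x1 + a32 x2)
```

and at the pulse instants a fixed fraction of a bamboo stand is removed:

```
x1(t+) = (1 − α) x1(t)   at  t = (n + l − 1) T
x2(t+) = (1 − β) x2(t)   at  t = n T
```

with pulse period `T` and phase offset `l ∈ (0, 1)` interleaving the two
die-off trains.

With the panda absent, each bamboo is an exactly solvable pulsed logistic
system: a positive `T`-periodic orbit `x*(t)` exists iff
`ln(1−θ) + aT > 0`, its post-pulse density is
`x₀⁺ = a((1−θ)e^{aT} − 1)/(b(e^{aT} − 1))`, and its one-period mean
satisfies `∫₀ᵀ x*(t) dt = (ln(1−θ) + aT)/b`. Linearizing about the
panda-free periodic solution `(x1*, x2*, 0)` gives the Floquet multipliers;
the predator's invasion multiplier is

```
λ₃ = exp( −a30 T + (a31/a11)(ln(1−α) + a10 T) + (a32/a22)(ln(1−β) + a20 T) )
```

`λ₃ < 1` makes the panda-free solution globally stable (the panda starves);
`λ₃ = 1` defines the extinction threshold

```
T* = [ (a31/a11) ln(1−α) + (a32/a22) ln(1−β) ] / [ a30 − (a31/a11) a10 − (a32/a22) a20 ]
```

when that ratio is positive: bamboo flowering periods shorter than `T*`
drive the panda extinct. Sign conditions on the same per-period exponents
certify permanence of the full system and of the two single-prey
subsystems. The package computes all of this in closed form, verifies it
against a numerically integrated monodromy matrix, and confirms the
predicted dynamics with an event-driven simulator.

## Worked example

The canonical parameter set (`pulseprey.example_parameters()`, also in the
docstrings) has `a10=1, a11=0.5, a13=0.2, a20=1.2, a22=0.4, a23=0.25,
a30=0.3, a31=a32=0.1, a33=0.05, α=0.4, β=0.5, T=1, l=0.5`:

```python
>>> import pulseprey as pp
>>> p = pp.example_parameters()
>>> pp.analytic_multipliers(p)
(0.6131324019524039, 0.6023884238244043, 0.9273243153143027)
>>> pp.extinction_threshold(p).value
1.3772595994659222
>>> pp.classify_regime(p).label
'panda_free_stable'
>>> traj = pp.simulate(p, [1.0, 1.0, 0.5], 200.0)
>>> float(traj.x[-1, 2])          # panda density after 200 periods
7.002602572814832e-08
>>> pp.classify_regime(p.replace(T=2.0)).label
'unstable_uncertified'
```

At `T = 1 < T* ≈ 1.377` the predator multiplier is `λ₃ ≈ 0.927 < 1`: the
panda-free solution is stable and the simulated panda density decays to
`~7e-8` by `t = 200` while the bamboos lock onto their periodic orbits. At
`T = 2 > T*`, `λ₃ ≈ 1.133 > 1` and the panda invades (a 400-time-unit
simulation keeps its tail minimum at `≈ 0.406`); the label is
`unstable_uncertified` because the sufficient permanence certificate —
which needs weak predation relative to the solution bound `M ≈ 8.21` —
does not apply to this set.

The same analyses are exposed on the command line:

```
pulseprey classify --config p0.json
pulseprey floquet  --config p0.json
pulseprey scan     --config p0.json --param T --from 0.5 --to 2.5 --steps 21 --out scan.csv
pulseprey simulate --config p0.json --x0 1,1,0.5 --t-end 200 --out traj.csv
pulseprey fixture  --regime permanent_certified --seed 1
```

where `p0.json` is a flat JSON object with exactly the fields listed above.

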