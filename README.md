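# mrpepa

Reagent-centric mass-action reaction networks with two exact semantics — a
deterministic ODE engine and a stochastic Gillespie (CTMC) engine — built
around Rosen's (M,R) metabolism-replacement system.

## The scientific problem

Relational biology asks whether a network that is *closed to efficient
causation* — one in which every catalyst is itself produced by the network —
can be realised and simulated at all. The smallest such network is Rosen's
(M,R) system: metabolism converts a nutrient A into B using catalyst f,
replacement rebuilds f from B using catalyst p (Rosen's Φ), and p in turn is
made from f using B itself as the catalyst. Only A is supplied from outside;
f, p and B all entail each other.

`mrpepa` expresses this loop as ordinary enzyme kinetics. Each catalysed
step S + E → P is the standard triple of elementary mass-action reactions
(binding, unbinding, turnover):

    A + f → fA (k1)    fA → f (k2)      fA → f + B (k3)
    B + p → pB (l1)    pB → p + B (l2)  pB → p + f (l3)
    f + B → Bf (m1)    Bf → B + f (m2)  Bf → B + p (m3)

with first-order degradation of B, f and p (rate constants d1, d2, d3). The
nutrient A is an environment-held reservoir: it multiplies the binding rate
of the first step but its quantity never changes (the unbinding step returns
no A; the environment absorbs the difference).

Models are written species-by-species (the reagent-centric style of the
Bio-PEPA process algebra): each species lists its role per reaction —
product `>>`, reactant `<<`, activator `(+)`, inhibitor `(-)` — with a
stoichiometric coefficient. The reaction-centric stoichiometric form is
derived from this and drives both engines:

* **ODE semantics** — dx/dt = N·v(x) with N the net stoichiometry matrix
  and v(x) the mass-action law values; integrated with LSODA.
* **CTMC semantics** — Gillespie's direct method: exponential waiting times
  at the total propensity, the next reaction drawn proportionally to its
  propensity. A state where every propensity is zero is an absorbing
  deadlock: the network has "died".

The interesting biology is the interplay of the two: regimes exist where
the ODE converges to a live steady state while individual stochastic
trajectories, with identical inputs, either live or die.

## Worked example

```python
from mrpepa import get_preset, find_steady_state, extinction_probability

# baseline regime: k1=l1=m1=0.01, k2=l2=m2=100, k3=l3=m3=1,
#                  d1=0, d2=0.05, d3=0.02426, A(0)=f(0)=1000
model = get_preset("fig3").build()

steady = find_steady_state(model)
print(steady.converged, steady.rounded_counts)
```

prints

```
True {'A': 1000, 'B': 495, 'f': 286, 'p': 577, 'fA': 28, 'pB': 28, 'Bf': 14}
```

i.e. from 1000 molecules of A and f the network settles into a live steady
state with ~577 molecules of p, 495 of B, 286 of f and small populations of
the three enzyme-substrate complexes — while A stays pinned at 1000 by the
environment.

The fragile regime shows the life/death dichotomy:

```python
fragile = get_preset("fig7").build()
print(find_steady_state(fragile, t_max=1000).rounded_counts)
# {'A': 1000, 'B': 340, 'f': 33, 'p': 53, 'fA': 298, 'pB': 149, 'Bf': 101}
summary = extinction_probability(fragile, n_reps=100, t_end=1000, base_seed=1)
print(summary.fraction)   # 0.86 — most, but not all, stochastic runs die
```

The deterministic analysis says "alive"; 86 of 100 exact stochastic
replicates nevertheless deadlock before t = 1000 (the remaining 14
survive). The same model, same parameters — only the sampling differs.

The same functionality is available from the shell:

```sh
mrpepa steady-state --preset fig3
mrpepa simulate --preset fig3 --engine ssa --reps 10 --seed 1 --out runs/fig3
mrpepa extinction --preset fig7 --reps 100 --t-end 1000 --seed 1
mrpepa scale --preset fig3 --factor 1e4     # 10^7-molecule version
mrpepa convert --preset fig3                # reaction-centric listing
```

Models can also be written as text files (see `examples/mr.biopepa`) and
passed with `--model FILE`.

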