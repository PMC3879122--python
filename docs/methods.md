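# Methods

## Model representation

A model is a set of *species behaviours* (per species: the reactions it
takes part in, with role and integer stoichiometry), one kinetic law per
reaction, parameter values, initial quantities, and a set of
environment-held (constant) species. Validation enforces the structural
invariants: exactly one law per used reaction and vice versa, initial
counts exactly for the declared species, constant species drawn from the
declared set, and law expressions resolving over declared names. A species
may appear on both sides of a reaction (a catalyst written explicitly);
it may not repeat the same role within one reaction.

Kinetic laws are either the mass-action shorthand `fMA(c)` or an explicit
arithmetic expression over parameters and species. `fMA(c)` expands to
`c × Π(rate factors)`, where the rate factors are the reaction's reactants
and activators with multiplicity; explicitly written products of exactly
that shape are recognised back into mass-action form, so both spellings
produce identical models and volume scaling works on either. Inhibitor
roles are stored but carry no built-in rate semantics: a law involving an
inhibitor must be written explicitly.

Constant species are a model-level annotation, not a role: a constant
reactant multiplies the rate but its net stoichiometry is pinned to zero in
every reaction. In the (M,R) instantiation this realises the boundary
condition on the nutrient A, including the asymmetry that the unbinding
step fA → f returns no A.

## The (M,R) instantiation

Seven species (A, B, f, p and the complexes fA, pB, Bf), twelve reactions:
three binding/unbinding/turnover triples with constants (k1,k2,k3),
(l1,l2,l3), (m1,m2,m3) and three degradations d1 (B), d2 (f), d3 (p).
Bimolecular constants have units 1/(molecule·time unit); all others
1/time unit. B and its catalytic form are the same entity (the model
describes a single pathway), so no conversion step between them exists.

Three named regimes are built in:

| preset | constants | behaviour |
|---|---|---|
| fig3 | k1=l1=m1=0.01, k2=l2=m2=100, k3=l3=m3=1, d1=0, d2=0.05, d3=0.02426 | live steady state |
| fig6 | as fig3 but d2=0.07 | leaves the live attractor (collapse) |
| fig7 | k1=l1=m1=1, k2=l2=m2=100, k3=m3=10, l3=20, d1=0, d2=60, d3=19.2666666 | ODE alive, stochastic runs may die |

all starting from A(0)=f(0)=1000, everything else 0. These presets *are*
the study conditions; there is no separate synthetic-data layer.

## Deterministic engine

dx/dt = N·v(x). Constant species are excluded from the integrated state
vector altogether, so their series are exactly constant by construction
rather than to integrator tolerance. Default integrator LSODA with
rtol 1e-8, atol 1e-10 (the unbinding constants of 100 against binding
constants of 0.01 make the system moderately stiff; LSODA switches to BDF
as needed). Reported series clamp undershoots to zero; an undershoot below
−atol raises a metadata flag.

### Steady-state detection and a degeneracy worth knowing about

`find_steady_state` integrates in checkpoints and declares convergence when
max |dx/dt| over non-constant species falls below `abs_tol`, default
**1e-4 molecules per time unit** (about 3·10⁻⁸ of the gross one-way fluxes
of ~2900 in the baseline regime). Once the residual is below a coarse
threshold, the endpoint is additionally polished by a Newton solve of
dx/dt = 0; the polished point is accepted only if it stays non-negative and
within the endpoint's neighbourhood, because an adaptive integrator alone
stalls at a residual set by its relative tolerance rather than reaching the
exact fixed point.

The default tolerance is deliberately not tighter. Eliminating the complex
species from the fixed-point equations of the baseline regime gives, with
d1 = 0 and the shorthand c = k1·k3/(k2+k3) = m1·m3/(m2+m3):

* B* = A − d2/c  (from the f balance) = 495 exactly,
* an interior fixed point exists only if d3 = c·B*²/A = 0.0242599…

The regime's d3 = 0.02426 is a rounding of that value, so the *exact*
interior fixed point does not exist: the dynamics reach a quasi-steady
slow manifold whose residual plateaus at ≈2.5e-5 (unchanged between
t = 1000 and t = 10000; an unconstrained Newton step from there falls onto
the degenerate dead manifold f = p = 0, which the closeness guard rejects).
A tolerance of 1e-4 treats this physically-steady plateau as converged; at
the accepted state the counts round exactly to (B, f, p, fA, pB, Bf) =
(495, 286, 577, 28, 28, 14). Regimes with a true interior fixed point
(e.g. the fast-binding one) converge at much tighter tolerances if asked.

### Volume scaling

`scale_model` multiplies initial quantities by V and each mass-action
constant by V^(1−order), where the order counts all rate-contributing
factors including constant species — so bimolecular constants divide by V
and unimolecular ones are untouched. Mass-action ODEs are exactly
equivariant under this map (trajectory scales pointwise by V); models with
unrecognised laws are refused since the order cannot be inferred. The
10⁷-molecule variant of the baseline regime is `scale_model(fig3, 1e4)`.

## Stochastic engine

Gillespie's direct method, exact: waiting time exponential in the total
propensity, next reaction proportional to its propensity, state updated by
the net stoichiometric change (constant species never move). Mass-action
propensities use the falling-factorial count product for reactants
(`n·(n−1)` for a doubled reactant) and the plain power for constant
species and activators; with all-unit stoichiometries the two coincide.

Implementation notes, chosen for exactness-per-second rather than elegance:

* the inner loop is numba-compiled for pure mass-action networks
  (~10⁷ events/s on one core); symbolic laws fall back to a Python loop
  with an explicit guard that a positive symbolic rate cannot drive a
  count negative;
* propensities are updated incrementally through a reaction dependency
  graph, with a full exact recomputation every 2¹⁶ events (bounding float
  drift) and whenever the running total approaches zero — a deadlock is
  therefore always confirmed against exactly recomputed propensities;
* each replicate r draws from its own numpy PCG64 generator seeded
  `base_seed + r`, making every trajectory bit-reproducible from
  (model, t_end, seed);
* trajectories are recorded onto a uniform grid by last-value-carried-
  forward; extinction freezes the state, which then fills the rest of the
  grid.

Extinction is *defined* operationally as total propensity zero — the halt
itself — rather than any particular pattern of empty species.
`extinction_probability` runs consecutive-seed replicates and reports the
extinct fraction with a 95% Wilson interval.

## Exact CTMC oracle

For small instances the reachable state space (dynamic species only) is
enumerated breadth-first; transitions leaving a `state_cap` truncation are
routed to one absorbing overflow state so the leaked probability mass is
tracked exactly, and the transient distribution is exp(tQᵀ)·p₀ via sparse
`expm_multiply`. The oracle exists to check the sampler, never to replace
it: the tests compare 3·10⁴ sampled endpoints of a small-count (M,R)
instance (A = 2 constant, one f, unit rates, no degradation, t = 1) against
the exact distribution by chi-squared over all states with expected count
≥ 5 (tail lumped), α = 0.01, and the one-molecule decay model against the
closed form P(extinct by t) = 1 − e^{−ct}.

## Problem sizes used in the checks

The end-to-end suite and `scripts/acceptance.py` use: the full t = 1000
horizon and 100 replicates for the fragile-regime extinction fraction;
50 replicates at system sizes 1000 and 10⁴ over t = 300 for the
law-of-large-numbers comparison (t = 300 is well past the ~100-time-unit
transient, and the deviation metric is a relative Frobenius norm against
the ODE curve); 3·10⁴ samples for the goodness-of-fit test; scaling factors
10 and 10⁴ for equivariance. These sizes are the package's own choices for
a desk-scale reproduction.

## Limitations

* No approximate accelerations (tau-leaping, hybrid switching): exactness
  is the point at these molecule counts.
* No bifurcation machinery; the d2 = 0.07 regime change is shown by direct
  simulation only, and no claim is made about the full attractor structure.
* The text format is a pragmatic subset (no compartments, events, or
  built-in functional rates beyond `fMA`); SBML export is not included.
* The quasi-steady degeneracy analysis above is specific to d1 = 0; with
  nonzero B degradation the algebra changes.
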