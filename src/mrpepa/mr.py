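"""Rosen's (M,R) metabolism-replacement system as a mass-action network.

The network closes the catalytic loop of relational biology with ordinary
enzyme kinetics: metabolism (A -> B, catalysed by f), replacement of the
catalyst (B -> f, catalysed by p) and replacement of the replacer
(f -> p, catalysed by B). Each catalysed step is the usual three-reaction
binding / unbinding / turnover triple, so every catalyst in the model is
itself a product of the model; only the nutrient A is held constant by the
environment. B, f and p additionally degrade at first-order rates d1, d2
and d3.

Note the boundary condition on A: it enters the binding rate of r_k1 but is
never consumed, and the unbinding r_k2 (fA -> f) returns no A — the
environment reservoir absorbs the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .model import KineticLaw, Model, ModelError, Role, SpeciesBehaviour

# species in reporting order; reactions in the order of the three enzymatic
# triples (k: A->B by f, l: B->f by p, m: f->p by B) plus the degradations
MR_SPECIES = ("A", "B", "f", "p", "fA", "pB", "Bf")
MR_REACTIONS = (
    "r_k1", "r_k2", "r_k3",
    "r_l1", "r_l2", "r_l3",
    "r_m1", "r_m2", "r_m3",
    "r_d1", "r_d2", "r_d3",
)


@dataclass(frozen=True)
class MRParams:
    """Rate constants and initial molecule counts of the (M,R) instantiation.

    Bimolecular constants (k1, l1, m1) are per molecule per time unit; the
    unbinding/turnover and degradation constants are per time unit. Defaults
    are the baseline steady-state regime.
    """

    k1: float = 0.01
    k2: float = 100.0
    k3: float = 1.0
    l1: float = 0.01
    l2: float = 100.0
    l3: float = 1.0
    m1: float = 0.01
    m2: float = 100.0
    m3: float = 1.0
    d1: float = 0.0
    d2: float = 0.05
    d3: float = 0.02426
    A_init: float = 1000.0
    B_init: float = 0.0
    f_init: float = 1000.0
    p_init: float = 0.0
    fA_init: float = 0.0
    pB_init: float = 0.0
    Bf_init: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            if value < 0:
                kind = "initial count" if f.name.endswith("_init") else "rate constant"
                raise ModelError(f"negative {kind} {f.name} = {value}")

    def replace(self, **updates) -> "MRParams":
        from dataclasses import replace as _replace

        return _replace(self, **updates)


R, P = Role.REACTANT, Role.PRODUCT

# reagent-centric behaviour table: species -> [(reaction, coeff, role), ...]
_MR_BEHAVIOURS = {
    "A": [("r_k1", 1, R)],
    "B": [
        ("r_k3", 1, P),
        ("r_l1", 1, R), ("r_l2", 1, P),
        ("r_m1", 1, R), ("r_m2", 1, P), ("r_m3", 1, P),
        ("r_d1", 1, R),
    ],
    "f": [
        ("r_k1", 1, R), ("r_k2", 1, P), ("r_k3", 1, P),
        ("r_l3", 1, P),
        ("r_m1", 1, R), ("r_m2", 1, P),
        ("r_d2", 1, R),
    ],
    "p": [
        ("r_l1", 1, R), ("r_l2", 1, P), ("r_l3", 1, P),
        ("r_m3", 1, P),
        ("r_d3", 1, R),
    ],
    "fA": [("r_k1", 1, P), ("r_k2", 1, R), ("r_k3", 1, R)],
    "pB": [("r_l1", 1, P), ("r_l2", 1, R), ("r_l3", 1, R)],
    "Bf": [("r_m1", 1, P), ("r_m2", 1, R), ("r_m3", 1, R)],
}

_MR_RATE_CONSTANTS = {
    "r_k1": "k1", "r_k2": "k2", "r_k3": "k3",
    "r_l1": "l1", "r_l2": "l2", "r_l3": "l3",
    "r_m1": "m1", "r_m2": "m2", "r_m3": "m3",
    "r_d1": "d1", "r_d2": "d2", "r_d3": "d3",
}


def build_mr_model(params: MRParams | None = None) -> Model:
    """Build the 7-species, 12-reaction (M,R) model.

    All kinetic laws are pure mass action over each reaction's reactants
    (constant A included as a rate factor of r_k1); A is environment-held.
    """
    from . import expressions as ex
    from .model import expand_mass_action

    params = MRParams() if params is None else params
    parameters = {
        name: getattr(params, name)
        for name in ("k1", "k2", "k3", "l1", "l2", "l3", "m1", "m2", "m3", "d1", "d2", "d3")
    }
    behaviours = [SpeciesBehaviour(s, _MR_BEHAVIOURS[s]) for s in MR_SPECIES]
    # seed each law with its bare constant, then expand to the full
    # mass-action product so validation always sees a concrete expression
    laws = [
        KineticLaw(r, ex.Sym(_MR_RATE_CONSTANTS[r]), _MR_RATE_CONSTANTS[r])
        for r in MR_REACTIONS
    ]
    initial = {s: getattr(params, f"{s}_init") for s in MR_SPECIES}
    model = Model(parameters, behaviours, laws, initial, constant_species={"A"})
    return expand_mass_action(model)
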