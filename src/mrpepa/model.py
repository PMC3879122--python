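"""Reagent-centric reaction networks.

A model is defined species-by-species: each species declares, for every
reaction it takes part in, its role (product ``>>``, reactant ``<<``,
activator ``(+)``, inhibitor ``(-)``) and a positive integer stoichiometric
coefficient. The reaction-centric view (reactants / products / modifiers /
net stoichiometric change, one kinetic law per reaction) is derived, and it
is what both the deterministic and the stochastic engine consume.

Environment-held species (``constant_species``) contribute to reaction rates
but never change: their net stoichiometry is pinned to zero in every
reaction, modelling a reservoir replenished from outside the system.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from . import expressions as ex
from .expressions import Expr


class ModelError(ValueError):
    """A model that violates a structural invariant."""


class Role(enum.Enum):
    """Role of a species in one reaction, with its surface syntax."""

    PRODUCT = ">>"
    REACTANT = "<<"
    ACTIVATOR = "(+)"
    INHIBITOR = "(-)"

    @classmethod
    def from_symbol(cls, symbol: str) -> "Role":
        for role in cls:
            if role.value == symbol:
                return role
        raise ValueError(f"unknown role symbol {symbol!r}")


@dataclass(frozen=True)
class BehaviourTerm:
    """One (reaction, stoichiometry, role) capability of a species."""

    reaction: str
    coeff: int
    role: Role

    def __post_init__(self):
        if self.coeff < 1 or int(self.coeff) != self.coeff:
            raise ModelError(
                f"stoichiometric coefficient must be a positive integer, got {self.coeff!r}"
            )


@dataclass(frozen=True)
class SpeciesBehaviour:
    """A species together with its per-reaction roles (the reagent-centric view)."""

    name: str
    terms: tuple[BehaviourTerm, ...]

    def __init__(self, name: str, terms: Iterable[BehaviourTerm | tuple]):
        object.__setattr__(self, "name", name)
        norm = tuple(
            t if isinstance(t, BehaviourTerm) else BehaviourTerm(*t) for t in terms
        )
        object.__setattr__(self, "terms", norm)
        # one term per (reaction, role): a species may be both reactant and
        # product of the same reaction (a catalyst written on both sides)
        seen = set()
        for t in norm:
            key = (t.reaction, t.role)
            if key in seen:
                raise ModelError(
                    f"species {name!r} repeats role {t.role.value} in reaction {t.reaction!r}"
                )
            seen.add(key)


@dataclass(frozen=True)
class KineticLaw:
    """Rate law of one reaction.

    ``mass_action_constant`` names the rate-constant parameter when the law is
    pure mass action (rate = constant x product of rate-contributing
    quantities); the expanded ``expression`` is kept alongside so every law
    can be evaluated uniformly.
    """

    reaction: str
    expression: Expr
    mass_action_constant: str | None = None


@dataclass(frozen=True)
class Model:
    parameters: dict[str, float]
    behaviours: tuple[SpeciesBehaviour, ...]
    laws: tuple[KineticLaw, ...]
    initial_counts: dict[str, float]
    constant_species: frozenset[str] = field(default_factory=frozenset)

    def __init__(self, parameters, behaviours, laws, initial_counts, constant_species=()):
        object.__setattr__(self, "parameters", dict(parameters))
        object.__setattr__(self, "behaviours", tuple(behaviours))
        object.__setattr__(self, "laws", tuple(laws))
        object.__setattr__(self, "initial_counts", dict(initial_counts))
        object.__setattr__(self, "constant_species", frozenset(constant_species))
        self._validate()

    # -- structural accessors ------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Species names in declaration order."""
        return [b.name for b in self.behaviours]

    @property
    def reactions(self) -> list[str]:
        """Reaction names in kinetic-law declaration order."""
        return [law.reaction for law in self.laws]

    def behaviour(self, name: str) -> SpeciesBehaviour:
        for b in self.behaviours:
            if b.name == name:
                return b
        raise KeyError(name)

    def law(self, reaction: str) -> KineticLaw:
        for l in self.laws:
            if l.reaction == reaction:
                return l
        raise KeyError(reaction)

    # -- validation ----------------------------------------------------------

    def _validate(self) -> None:
        species = self.species
        if len(set(species)) != len(species):
            dup = sorted({s for s in species if species.count(s) > 1})
            raise ModelError(f"duplicate species declaration: {', '.join(dup)}")

        law_reactions = [l.reaction for l in self.laws]
        if len(set(law_reactions)) != len(law_reactions):
            dup = sorted({r for r in law_reactions if law_reactions.count(r) > 1})
            raise ModelError(f"duplicate kinetic law for reaction: {', '.join(dup)}")

        used_reactions = {t.reaction for b in self.behaviours for t in b.terms}
        missing_laws = sorted(used_reactions - set(law_reactions))
        if missing_laws:
            raise ModelError(f"missing kinetic law for reaction: {', '.join(missing_laws)}")
        orphan_laws = sorted(set(law_reactions) - used_reactions)
        if orphan_laws:
            raise ModelError(
                f"kinetic law for reaction not used by any species: {', '.join(orphan_laws)}"
            )

        sset = set(species)
        missing_counts = sorted(sset - set(self.initial_counts))
        if missing_counts:
            raise ModelError(f"missing initial count for species: {', '.join(missing_counts)}")
        orphan_counts = sorted(set(self.initial_counts) - sset)
        if orphan_counts:
            raise ModelError(f"initial count for undeclared species: {', '.join(orphan_counts)}")
        for name, value in self.initial_counts.items():
            if value < 0:
                raise ModelError(f"negative initial count for species {name!r}: {value}")

        rogue_const = sorted(self.constant_species - sset)
        if rogue_const:
            raise ModelError(f"constant species not declared: {', '.join(rogue_const)}")

        known = sset | set(self.parameters)
        for law in self.laws:
            unknown = sorted(set(ex.identifiers(law.expression)) - known)
            if unknown:
                raise ModelError(
                    f"kinetic law of {law.reaction!r} references undeclared "
                    f"identifier: {', '.join(unknown)}"
                )
            if law.mass_action_constant is not None and law.mass_action_constant not in self.parameters:
                raise ModelError(
                    f"mass-action constant {law.mass_action_constant!r} of "
                    f"{law.reaction!r} is not a declared parameter"
                )

    # -- convenience ---------------------------------------------------------

    def with_parameters(self, **updates: float) -> "Model":
        unknown = sorted(set(updates) - set(self.parameters))
        if unknown:
            raise KeyError(f"unknown parameter: {', '.join(unknown)}")
        return Model(
            {**self.parameters, **updates},
            self.behaviours,
            self.laws,
            self.initial_counts,
            self.constant_species,
        )


@dataclass(frozen=True)
class ReactionView:
    """Reaction-centric derived view of one reaction."""

    reaction: str
    reactants: dict[str, int]
    products: dict[str, int]
    modifiers: frozenset[str]
    net_change: dict[str, int]
    law: KineticLaw


def reaction_views(model: Model) -> list[ReactionView]:
    """Switch from the reagent-centric to the reaction-centric notation.

    Net change of a constant species is pinned to zero; its quantity still
    enters the rate of any reaction that lists it as reactant or activator.
    """
    views: list[ReactionView] = []
    for law in model.laws:
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        modifiers: set[str] = set()
        for b in model.behaviours:
            for t in b.terms:
                if t.reaction != law.reaction:
                    continue
                if t.role is Role.REACTANT:
                    reactants[b.name] = t.coeff
                elif t.role is Role.PRODUCT:
                    products[b.name] = t.coeff
                else:
                    modifiers.add(b.name)
        net = {}
        for s in set(reactants) | set(products):
            if s in model.constant_species:
                net[s] = 0
            else:
                delta = products.get(s, 0) - reactants.get(s, 0)
                if delta:
                    net[s] = delta
        views.append(
            ReactionView(law.reaction, reactants, products, frozenset(modifiers), net, law)
        )
    return views


def net_stoichiometry(model: Model) -> np.ndarray:
    """Signed species-by-reactions matrix of net molecule changes.

    Rows follow species declaration order, columns follow kinetic-law order;
    rows of constant species are identically zero.
    """
    species_index = {s: i for i, s in enumerate(model.species)}
    mat = np.zeros((len(species_index), len(model.laws)), dtype=np.int64)
    for j, view in enumerate(reaction_views(model)):
        for s, delta in view.net_change.items():
            mat[species_index[s], j] = delta
    return mat


# ---------------------------------------------------------------------------
# mass-action handling


def mass_action_expression(model_species_roles: Mapping[str, int], constant: str) -> Expr:
    """Expand ``fMA(constant)``: constant x product of rate factors with multiplicity."""
    factors: list[Expr] = [ex.Sym(constant)]
    for name, power in model_species_roles.items():
        factors.extend([ex.Sym(name)] * power)
    return ex.build_product(factors)


def _activator_factors(model: Model, view: ReactionView) -> dict[str, int]:
    """Rate-contributing quantities of a mass-action reaction: reactants plus
    activators, with multiplicity. Inhibitors never enter a built-in law."""
    factors = dict(view.reactants)
    for b in model.behaviours:
        for t in b.terms:
            if t.reaction == view.reaction and t.role is Role.ACTIVATOR:
                factors[b.name] = factors.get(b.name, 0) + t.coeff
    return factors


def expand_mass_action(model: Model) -> Model:
    """Return a model in which every mass-action law's expression is the
    expanded product; laws already carrying an expression are left alone."""
    views = {v.reaction: v for v in reaction_views(model)}
    new_laws = []
    for law in model.laws:
        if law.mass_action_constant is not None:
            factors = _activator_factors(model, views[law.reaction])
            expr = mass_action_expression(factors, law.mass_action_constant)
            new_laws.append(replace(law, expression=expr))
        else:
            new_laws.append(law)
    return Model(
        model.parameters, model.behaviours, new_laws, model.initial_counts, model.constant_species
    )


def canonicalise_mass_action(model: Model) -> Model:
    """Expand declared mass-action laws and recognise explicitly written ones,
    so that structurally equivalent sources yield equal models."""
    views = {v.reaction: v for v in reaction_views(model)}
    new_laws = []
    for law in model.laws:
        const = recognise_mass_action(model, law)
        if const is not None:
            factors = _activator_factors(model, views[law.reaction])
            expr = mass_action_expression(factors, const)
            new_laws.append(KineticLaw(law.reaction, expr, const))
        else:
            new_laws.append(law)
    return Model(
        model.parameters, model.behaviours, new_laws, model.initial_counts, model.constant_species
    )


def recognise_mass_action(model: Model, law: KineticLaw) -> str | None:
    """If ``law``'s expression is ``c * (rate factors with multiplicity)`` for a
    single parameter ``c``, return that parameter's name, else None."""
    if law.mass_action_constant is not None:
        return law.mass_action_constant
    factors = ex.product_factors(law.expression)
    if factors is None:
        return None
    params: list[str] = []
    counts: dict[str, int] = {}
    for f in factors:
        if isinstance(f, ex.Sym) and f.name in model.parameters:
            params.append(f.name)
        elif isinstance(f, ex.Sym):
            counts[f.name] = counts.get(f.name, 0) + 1
        else:
            return None
    if len(params) != 1:
        return None
    view = next(v for v in reaction_views(model) if v.reaction == law.reaction)
    if counts == _activator_factors(model, view):
        return params[0]
    return None


# ---------------------------------------------------------------------------
# compiled form consumed by the engines


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat arrays describing a network, shared by the ODE and SSA engines.

    For mass-action reactions the rate is ``const x prod(factors)``; species
    with ``factor_kind`` 0 use the falling-factorial (combinatorial) count
    product in the stochastic semantics and the plain power in the
    deterministic one; kind 1 (constant species, activators) always uses the
    plain power. Reactions without a recognised mass-action form carry their
    expression and are evaluated symbolically.
    """

    species: tuple[str, ...]
    reactions: tuple[str, ...]
    dynamic_mask: np.ndarray  # bool per species; False = environment-held
    initial_state: np.ndarray  # float per species
    net_matrix: np.ndarray  # species x reactions, int
    ma_consts: np.ndarray  # float per reaction; NaN where not mass action
    factor_offsets: np.ndarray  # reactions+1, into factor_* arrays
    factor_species: np.ndarray
    factor_power: np.ndarray
    factor_kind: np.ndarray  # 0 combinatorial, 1 plain
    exprs: tuple  # per reaction: Expr or None (mass action)
    param_env: dict[str, float]

    @property
    def all_mass_action(self) -> bool:
        return all(e is None for e in self.exprs)

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def propensity_vector(self, counts: np.ndarray) -> np.ndarray:
        """Stochastic propensities at integer ``counts`` (combinatorial form)."""
        return _rates(self, counts, combinatorial=True)

    def rate_vector(self, state: np.ndarray) -> np.ndarray:
        """Deterministic law values at continuous ``state`` (plain powers)."""
        return _rates(self, state, combinatorial=False)


def _rates(net: CompiledNetwork, state: np.ndarray, combinatorial: bool) -> np.ndarray:
    out = np.empty(len(net.reactions))
    for j in range(len(net.reactions)):
        if net.exprs[j] is not None:
            env = dict(net.param_env)
            env.update(zip(net.species, state.tolist()))
            out[j] = ex.evaluate(net.exprs[j], env)
            continue
        v = net.ma_consts[j]
        for k in range(net.factor_offsets[j], net.factor_offsets[j + 1]):
            s = net.factor_species[k]
            p = net.factor_power[k]
            if combinatorial and net.factor_kind[k] == 0:
                for i in range(p):
                    v *= max(state[s] - i, 0.0)
            else:
                v *= state[s] ** p
        out[j] = v
    return out


def compile_network(model: Model) -> CompiledNetwork:
    """Lower a validated model to the flat-array form used by both engines."""
    species = tuple(model.species)
    sidx = {s: i for i, s in enumerate(species)}
    views = reaction_views(model)
    reactions = tuple(v.reaction for v in views)
    net_matrix = net_stoichiometry(model)

    ma_consts = np.full(len(views), np.nan)
    offsets = [0]
    f_species: list[int] = []
    f_power: list[int] = []
    f_kind: list[int] = []
    exprs: list = []
    for j, view in enumerate(views):
        const = recognise_mass_action(model, view.law)
        if const is None:
            exprs.append(view.law.expression)
        else:
            exprs.append(None)
            ma_consts[j] = model.parameters[const]
            factors = _activator_factors(model, view)
            for name in sorted(factors, key=lambda n: sidx[n]):
                f_species.append(sidx[name])
                f_power.append(factors[name])
                is_plain = name in model.constant_species or name not in view.reactants
                f_kind.append(1 if is_plain else 0)
        offsets.append(len(f_species))

    dynamic = np.array([s not in model.constant_species for s in species], dtype=bool)
    x0 = np.array([float(model.initial_counts[s]) for s in species])
    return CompiledNetwork(
        species=species,
        reactions=reactions,
        dynamic_mask=dynamic,
        initial_state=x0,
        net_matrix=net_matrix,
        ma_consts=ma_consts,
        factor_offsets=np.array(offsets, dtype=np.int64),
        factor_species=np.array(f_species, dtype=np.int64),
        factor_power=np.array(f_power, dtype=np.int64),
        factor_kind=np.array(f_kind, dtype=np.int64),
        exprs=tuple(exprs),
        param_env=dict(model.parameters),
    )
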