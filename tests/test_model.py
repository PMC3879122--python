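"""Reagent-centric model representation and the derived reaction-centric view."""

import numpy as np
import pytest

from mrpepa import (
    KineticLaw,
    Model,
    ModelError,
    MRParams,
    Role,
    SpeciesBehaviour,
    build_mr_model,
    net_stoichiometry,
    reaction_views,
)
from mrpepa import expressions as ex
from mrpepa.model import canonicalise_mass_action, recognise_mass_action
from mrpepa.mr import MR_REACTIONS, MR_SPECIES

R, P = Role.REACTANT, Role.PRODUCT


def view_of(model, reaction):
    return next(v for v in reaction_views(model) if v.reaction == reaction)


class TestMRModel:
    def test_structure(self, fig3_model):
        assert fig3_model.species == list(MR_SPECIES)
        assert fig3_model.reactions == list(MR_REACTIONS)
        assert fig3_model.constant_species == {"A"}
        for law in fig3_model.laws:
            assert recognise_mass_action(fig3_model, law) is not None

    def test_product_step_of_replacement_reaction(self, fig3_model):
        # pB -> p + f: the enzyme p is freed and new catalyst f is made
        v = view_of(fig3_model, "r_l3")
        assert v.reactants == {"pB": 1}
        assert v.products == {"p": 1, "f": 1}
        assert v.net_change == {"pB": -1, "p": 1, "f": 1}

    def test_nutrient_has_zero_net_change_everywhere(self, fig3_model):
        for v in reaction_views(fig3_model):
            assert v.net_change.get("A", 0) == 0

    def test_binding_step_consumes_catalyst_but_not_nutrient(self, fig3_model):
        v = view_of(fig3_model, "r_k1")
        assert v.reactants == {"A": 1, "f": 1}
        assert v.net_change == {"A": 0, "f": -1, "fA": 1}
        # A still multiplies the rate
        factors = [f.name for f in ex.product_factors(v.law.expression) if isinstance(f, ex.Sym)]
        assert "A" in factors

    def test_degradation_views(self, fig3_model):
        v = view_of(fig3_model, "r_d2")
        assert v.reactants == {"f": 1}
        assert v.products == {}
        assert v.law.mass_action_constant == "d2"

    def test_full_net_stoichiometry_matrix(self, fig3_model):
        # enumerated by hand from the twelve reactions
        expected = np.array(
            # k1  k2  k3  l1  l2  l3  m1  m2  m3  d1  d2  d3
            [
                [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # A
                [0, 0, 1, -1, 1, 0, -1, 1, 1, -1, 0, 0],  # B
                [-1, 1, 1, 0, 0, 1, -1, 1, 0, 0, -1, 0],  # f
                [0, 0, 0, -1, 1, 1, 0, 0, 1, 0, 0, -1],  # p
                [1, -1, -1, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # fA
                [0, 0, 0, 1, -1, -1, 0, 0, 0, 0, 0, 0],  # pB
                [0, 0, 0, 0, 0, 0, 1, -1, -1, 0, 0, 0],  # Bf
            ]
        )
        assert np.array_equal(net_stoichiometry(fig3_model), expected)

    def test_views_and_matrix_agree_column_by_column(self, fig3_model):
        mat = net_stoichiometry(fig3_model)
        sidx = {s: i for i, s in enumerate(fig3_model.species)}
        for j, v in enumerate(reaction_views(fig3_model)):
            col = np.zeros(len(sidx), dtype=int)
            for s, d in v.net_change.items():
                col[sidx[s]] = d
            assert np.array_equal(mat[:, j], col), v.reaction

    def test_zero_degradation_rates_keep_reactions(self, fig3_network):
        model = build_mr_model(MRParams(d1=0, d2=0, d3=0))
        assert len(model.reactions) == 12
        from mrpepa.model import compile_network

        net = compile_network(model)
        state = np.array([1000.0, 50.0, 20.0, 30.0, 5.0, 5.0, 5.0])
        rates = dict(zip(net.reactions, net.rate_vector(state)))
        assert rates["r_d1"] == rates["r_d2"] == rates["r_d3"] == 0.0

    def test_negative_parameter_rejected_with_name(self):
        with pytest.raises(ModelError, match="d2"):
            MRParams(d2=-0.05)
        with pytest.raises(ModelError, match="f_init"):
            MRParams(f_init=-1)


class TestModelValidation:
    def make(self, **overrides):
        kwargs = dict(
            parameters={"c": 1.0},
            behaviours=[
                SpeciesBehaviour("X", [("r1", 1, R)]),
                SpeciesBehaviour("Y", [("r1", 1, P)]),
            ],
            laws=[KineticLaw("r1", ex.Sym("c"), "c")],
            initial_counts={"X": 5, "Y": 0},
            constant_species=(),
        )
        kwargs.update(overrides)
        return Model(**kwargs)

    def test_valid_model_builds(self):
        assert self.make().species == ["X", "Y"]

    def test_missing_law_names_reaction(self):
        with pytest.raises(ModelError, match="r1"):
            self.make(laws=[])

    def test_orphan_law_rejected(self):
        with pytest.raises(ModelError, match="r2"):
            self.make(
                laws=[
                    KineticLaw("r1", ex.Sym("c"), "c"),
                    KineticLaw("r2", ex.Sym("c"), "c"),
                ]
            )

    def test_duplicate_law_rejected(self):
        with pytest.raises(ModelError, match="duplicate"):
            self.make(
                laws=[KineticLaw("r1", ex.Sym("c"), "c"), KineticLaw("r1", ex.Sym("c"), "c")]
            )

    def test_missing_initial_count_rejected(self):
        with pytest.raises(ModelError, match="Y"):
            self.make(initial_counts={"X": 5})

    def test_negative_initial_count_rejected(self):
        with pytest.raises(ModelError, match="X"):
            self.make(initial_counts={"X": -1, "Y": 0})

    def test_undeclared_identifier_in_law(self):
        with pytest.raises(ModelError, match="zz"):
            self.make(laws=[KineticLaw("r1", ex.Sym("zz"))])

    def test_constant_species_must_be_declared(self):
        with pytest.raises(ModelError, match="Z"):
            self.make(constant_species={"Z"})

    def test_duplicate_role_per_reaction_rejected(self):
        # both sides of the same reaction is fine (catalyst); the same role
        # twice is not
        with pytest.raises(ModelError, match="X"):
            SpeciesBehaviour("X", [("r1", 1, R), ("r1", 2, R)])
        SpeciesBehaviour("X", [("r1", 1, R), ("r1", 1, P)])  # allowed

    def test_zero_stoichiometry_rejected(self):
        with pytest.raises(ModelError, match="positive integer"):
            SpeciesBehaviour("X", [("r1", 0, R)])

    def test_empty_model_has_0x0_stoichiometry(self):
        empty = Model({}, [], [], {})
        assert net_stoichiometry(empty).shape == (0, 0)
        assert reaction_views(empty) == []


class TestCancellationAndRecognition:
    def test_catalyst_on_both_sides_has_zero_net_change(self):
        # X + E -> Y + E: E written as both reactant and product cancels
        model = Model(
            {"c": 2.0},
            [
                SpeciesBehaviour("X", [("r1", 1, R)]),
                SpeciesBehaviour("E", [("r1", 1, R), ("r1", 1, P)]),
                SpeciesBehaviour("Y", [("r1", 1, P)]),
            ],
            [KineticLaw("r1", ex.Sym("c"), "c")],
            {"X": 1, "E": 1, "Y": 0},
        )
        v = view_of(model, "r1")
        assert v.reactants["E"] == 1 and v.products["E"] == 1
        assert v.net_change.get("E", 0) == 0
        assert v.net_change == {"X": -1, "Y": 1}

    def test_constant_reactant_net_change_pinned_to_zero(self):
        model = Model(
            {"c": 1.0},
            [
                SpeciesBehaviour("C", [("r1", 1, R)]),
                SpeciesBehaviour("D", [("r1", 1, P)]),
            ],
            [KineticLaw("r1", ex.BinOp("*", ex.Sym("c"), ex.Sym("C")))],
            {"C": 3, "D": 0},
            constant_species={"C"},
        )
        v = view_of(model, "r1")
        assert v.net_change["C"] == 0

    def test_explicit_product_recognised_as_mass_action(self):
        model = Model(
            {"k": 0.5},
            [
                SpeciesBehaviour("X", [("r1", 1, R)]),
                SpeciesBehaviour("Y", [("r1", 2, R)]),
                SpeciesBehaviour("Z", [("r1", 1, P)]),
            ],
            [
                KineticLaw(
                    "r1",
                    ex.build_product([ex.Sym("k"), ex.Sym("X"), ex.Sym("Y"), ex.Sym("Y")]),
                )
            ],
            {"X": 1, "Y": 2, "Z": 0},
        )
        assert recognise_mass_action(model, model.laws[0]) == "k"
        canon = canonicalise_mass_action(model)
        assert canon.laws[0].mass_action_constant == "k"

    def test_sum_expression_not_mass_action(self):
        model = Model(
            {"k": 0.5},
            [SpeciesBehaviour("X", [("r1", 1, R)])],
            [KineticLaw("r1", ex.BinOp("+", ex.Sym("k"), ex.Sym("X")))],
            {"X": 1},
        )
        assert recognise_mass_action(model, model.laws[0]) is None


def test_with_parameters_returns_updated_copy(fig3_model):
    bumped = fig3_model.with_parameters(d2=0.07)
    assert bumped.parameters["d2"] == 0.07
    assert fig3_model.parameters["d2"] == 0.05
    with pytest.raises(KeyError):
        fig3_model.with_parameters(nope=1.0)
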