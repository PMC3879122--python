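"""Stochastic semantics: propensities, exact sampling, averaging, extinction."""

import math

import numpy as np
import pytest

from mrpepa import (
    Model,
    Trajectory,
    average_trajectories,
    compile_network,
    extinction_probability,
    find_steady_state,
    propensities,
    sample_final_counts,
    ssa_simulate,
)
from mrpepa.model import KineticLaw, Role, SpeciesBehaviour
from mrpepa import expressions as ex


class TestPropensities:
    def test_initial_state_of_baseline(self, fig3_model):
        props = propensities(fig3_model, {"A": 1000, "f": 1000})
        assert props["r_k1"] == pytest.approx(10_000.0)
        assert props["r_d2"] == pytest.approx(0.05 * 1000)
        for r, v in props.items():
            if r not in ("r_k1", "r_d2"):
                assert v == 0.0

    def test_dead_state_has_all_zero_propensities(self, fig3_model):
        props = propensities(fig3_model, {"A": 1000})
        assert all(v == 0.0 for v in props.values())

    def test_matches_deterministic_law_values_at_integer_state(self, fig3_network):
        # all stoichiometries are one, so the combinatorial and plain
        # products coincide at any integer state
        counts = {"A": 1000, "B": 495, "f": 286, "p": 577, "fA": 28, "pB": 28, "Bf": 14}
        props = propensities(fig3_network, counts)
        x = np.array([float(counts[s]) for s in fig3_network.species])
        rates = dict(zip(fig3_network.reactions, fig3_network.rate_vector(x)))
        for r in props:
            assert props[r] == pytest.approx(rates[r], rel=1e-12)

    def test_doubled_reactant_uses_falling_factorial(self):
        # dimerisation 2X -> Y: propensity c * x(x-1), not c * x^2
        model = Model(
            {"c": 0.5},
            [
                SpeciesBehaviour("X", [("dim", 2, Role.REACTANT)]),
                SpeciesBehaviour("Y", [("dim", 1, Role.PRODUCT)]),
            ],
            [KineticLaw("dim", ex.Sym("c"), "c")],
            {"X": 4, "Y": 0},
        )
        props = propensities(model, {"X": 4, "Y": 0})
        assert props["dim"] == pytest.approx(0.5 * 4 * 3)
        assert propensities(model, {"X": 1, "Y": 0})["dim"] == 0.0

    def test_negative_counts_rejected(self, fig3_model):
        with pytest.raises(ValueError):
            propensities(fig3_model, {"A": 1000, "f": -1})


class TestSimulate:
    def test_seed_determinism_is_bit_identical(self, fig3_model):
        t1, r1 = ssa_simulate(fig3_model, 50.0, seed=7, n_points=50)
        t2, r2 = ssa_simulate(fig3_model, 50.0, seed=7, n_points=50)
        assert np.array_equal(t1.values, t2.values)
        assert r1.extinct == r2.extinct

    def test_different_seeds_differ(self, fig3_model):
        t1, _ = ssa_simulate(fig3_model, 50.0, seed=1, n_points=50)
        t2, _ = ssa_simulate(fig3_model, 50.0, seed=2, n_points=50)
        assert not np.array_equal(t1.values, t2.values)

    def test_counts_are_nonnegative_integers(self, fig3_model):
        traj, _ = ssa_simulate(fig3_model, 100.0, seed=3, n_points=100)
        assert np.all(traj.values >= 0)
        assert np.all(traj.values == np.round(traj.values))

    def test_nutrient_never_decremented(self, fig3_model):
        traj, _ = ssa_simulate(fig3_model, 100.0, seed=4, n_points=100)
        assert np.all(traj.series("A") == 1000.0)

    def test_immediate_extinction_with_no_mobile_molecules(self):
        from mrpepa import MRParams, build_mr_model

        model = build_mr_model(MRParams(A_init=1000, f_init=0))
        traj, report = ssa_simulate(model, 10.0, seed=1, n_points=10)
        assert report.extinct and report.t_extinct == 0.0
        assert np.all(traj.values == traj.values[0])

    def test_extinction_is_absorbing(self, fig7_model):
        # seed chosen to exhibit an early death at this horizon
        traj, report = ssa_simulate(fig7_model, 200.0, seed=12, n_points=200)
        assert report.extinct
        frozen = traj.values[traj.times >= report.t_extinct]
        assert np.all(frozen == frozen[0])

    def test_non_integer_initial_counts_rejected(self):
        from mrpepa import MRParams, build_mr_model

        model = build_mr_model(MRParams(f_init=10.5))
        with pytest.raises(ValueError, match="integer"):
            ssa_simulate(model, 1.0, seed=1)

    def test_decay_extinction_matches_closed_form(self, decay_model):
        # X -> 0 at rate c with one molecule: P(dead by t) = 1 - exp(-ct)
        c, t = 0.3, 2.0
        summary = extinction_probability(decay_model(c=c), n_reps=1000, t_end=t, base_seed=11)
        p_true = 1.0 - math.exp(-c * t)
        assert summary.ci_low <= p_true <= summary.ci_high

    def test_symbolic_law_falls_back_to_python_loop(self):
        from mrpepa import parse_model

        model = parse_model(
            """
            c = 0.5;
            kineticLawOf r : c * X + 0.1;
            X = (r) <<;
            X[5]
            """
        )
        traj, report = ssa_simulate(model, 500.0, seed=5, n_points=10)
        assert report.extinct  # constant floor keeps firing until X hits 0
        assert traj.values[-1, 0] == 0.0


class TestAveraging:
    def grid(self, t_end=10.0, n=10):
        return np.linspace(0.0, t_end, n + 1)

    def test_average_of_trajectory_with_itself(self, fig3_model):
        traj, _ = ssa_simulate(fig3_model, 10.0, seed=1, n_points=10)
        mean = average_trajectories([traj, traj], self.grid())
        np.testing.assert_array_equal(mean.values, traj.values)

    def test_average_of_constant_trajectories(self):
        grid = self.grid()
        trajs = [
            Trajectory(grid, ("X",), np.full((len(grid), 1), float(v))) for v in (1, 2, 6)
        ]
        mean = average_trajectories(trajs, grid)
        assert np.all(mean.values == 3.0)
        assert mean.meta["n_averaged"] == 3

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_trajectories([], self.grid())

    def test_mismatched_species_rejected(self):
        grid = self.grid()
        a = Trajectory(grid, ("X",), np.zeros((len(grid), 1)))
        b = Trajectory(grid, ("Y",), np.zeros((len(grid), 1)))
        with pytest.raises(ValueError, match="species"):
            average_trajectories([a, b], grid)

    def test_lvcf_resampling(self):
        traj = Trajectory(
            np.array([0.0, 1.0, 3.0]), ("X",), np.array([[1.0], [5.0], [2.0]])
        )
        res = traj.resample(np.array([0.0, 0.5, 1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(res.values[:, 0], [1.0, 1.0, 5.0, 5.0, 2.0, 2.0])

    def test_ten_run_average_near_ode_steady_state(self, fig3_model):
        t_end, n = 1000.0, 100
        grid = np.linspace(0.0, t_end, n + 1)
        runs = [ssa_simulate(fig3_model, t_end, seed=s, n_points=n)[0] for s in range(10)]
        mean = average_trajectories(runs, grid)
        steady = find_steady_state(fig3_model)
        finals = np.stack([t.values[-1] for t in runs])
        sem = finals.std(axis=0, ddof=1) / math.sqrt(len(runs))
        for i, s in enumerate(mean.species):
            if s == "A":
                continue
            assert abs(mean.values[-1, i] - steady.counts[s]) <= 3 * sem[i] + 1e-9, s


class TestExtinctionProbability:
    def test_no_reaction_model_is_dead_at_t0(self):
        model = Model({}, [SpeciesBehaviour("X", [])], [], {"X": 3})
        # a species with no capabilities cannot react at all
        summary = extinction_probability(model, n_reps=5, t_end=1.0, base_seed=1)
        assert summary.fraction == 1.0

    def test_baseline_regime_rarely_dies(self, fig3_model):
        summary = extinction_probability(fig3_model, n_reps=5, t_end=100.0, base_seed=1)
        assert summary.fraction == 0.0

    def test_wilson_interval_bounds(self, decay_model):
        summary = extinction_probability(decay_model(), n_reps=50, t_end=1.0, base_seed=3)
        assert 0.0 <= summary.ci_low <= summary.fraction <= summary.ci_high <= 1.0

    def test_replicates_use_consecutive_seeds(self, decay_model):
        model = decay_model()
        s1 = extinction_probability(model, n_reps=20, t_end=1.0, base_seed=5)
        s2 = extinction_probability(model, n_reps=20, t_end=1.0, base_seed=5)
        assert s1.fraction == s2.fraction


def test_sample_final_counts_matches_single_runs(fig3_model):
    finals = sample_final_counts(fig3_model, 20.0, n_reps=3, base_seed=9)
    net = compile_network(fig3_model)
    for r in range(3):
        traj, _ = ssa_simulate(fig3_model, 20.0, seed=9 + r, n_points=1)
        np.testing.assert_array_equal(finals[r], traj.values[-1])
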