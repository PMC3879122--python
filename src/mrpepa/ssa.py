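"""Stochastic (CTMC) semantics: Gillespie's direct method.

Each trajectory is one exact sample of the continuous-time Markov chain:
waiting times are exponential with rate equal to the total propensity, the
next reaction is chosen with probability proportional to its propensity, and
the state moves by the reaction's net stoichiometric change. Under mass
action the propensity of a reaction is its rate constant times the falling-
factorial product of its reactant counts (the plain product for constant
species and activators, which are not consumed).

A state with total propensity zero is absorbing: the network has deadlocked
("died") and the trajectory is frozen from that time on. With the nutrient A
held constant this can only happen when every mobile species combination
feeding a reaction is exhausted.

Trajectories are recorded onto a uniform time grid by last-value-carried-
forward. The inner loop for pure mass-action networks is numba-compiled;
networks with symbolic rate expressions use a pure-Python loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from statsmodels.stats.proportion import proportion_confint

from .model import CompiledNetwork, Model, compile_network
from .trajectory import Trajectory


@dataclass
class ExtinctionReport:
    """Whether (and when) a single run reached the dead, zero-propensity state."""

    extinct: bool
    t_extinct: float | None
    final_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "extinct": self.extinct,
            "t_extinct": self.t_extinct,
            "final_counts": self.final_counts,
        }


@dataclass
class ExtinctionSummary:
    """Replicate-level extinction estimate with a 95% Wilson interval."""

    fraction: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_extinct: int
    t_end: float
    base_seed: int

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def propensities(model_or_net: Model | CompiledNetwork, counts: dict[str, int]) -> dict[str, float]:
    """Propensity of every reaction at integer ``counts``."""
    net = model_or_net if isinstance(model_or_net, CompiledNetwork) else compile_network(model_or_net)
    x = _validated_counts(net, [counts.get(s, 0) for s in net.species])
    return dict(zip(net.reactions, net.propensity_vector(x).astype(float)))


def _validated_counts(net: CompiledNetwork, values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise ValueError("molecule counts must be non-negative")
    if np.any(x != np.round(x)):
        raise ValueError("molecule counts must be integers for the stochastic semantics")
    return x


# ---------------------------------------------------------------------------
# numba core (pure mass-action networks)


@njit(cache=False, fastmath=False)
def _ssa_core_ma(
    gen,
    x0,
    t_end,
    grid,
    consts,
    f_off,
    f_sp,
    f_pw,
    f_kind,
    fast_s1,
    fast_s2,
    u_off,
    u_sp,
    u_delta,
    dep_off,
    dep_list,
    out,
):
    # fast_s1[j] >= -1 marks the fast path (all rate factors have power 1,
    # at most two of them); the generic branch handles higher powers with
    # the falling-factorial (kind 0) or plain-power (kind 1) product.
    x = x0.copy()
    n_r = consts.shape[0]
    props = np.empty(n_r)
    total = 0.0
    for j in range(n_r):
        v = consts[j]
        s1 = fast_s1[j]
        if s1 >= -1:
            if s1 >= 0:
                v *= x[s1]
            s2 = fast_s2[j]
            if s2 >= 0:
                v *= x[s2]
        else:
            for k in range(f_off[j], f_off[j + 1]):
                s = f_sp[k]
                if f_kind[k] == 0:
                    for i in range(f_pw[k]):
                        v *= x[s] - i
                    if v < 0.0:
                        v = 0.0
                else:
                    for i in range(f_pw[k]):
                        v *= x[s]
        props[j] = v
        total += v
    t = 0.0
    g = 0
    n_grid = grid.shape[0]
    since_refresh = 0
    while True:
        if total <= 1e-10 or since_refresh >= 65536:
            # exact refresh: rules out both float drift and false deadlock
            total = 0.0
            for j in range(n_r):
                v = consts[j]
                s1 = fast_s1[j]
                if s1 >= -1:
                    if s1 >= 0:
                        v *= x[s1]
                    s2 = fast_s2[j]
                    if s2 >= 0:
                        v *= x[s2]
                else:
                    for k in range(f_off[j], f_off[j + 1]):
                        s = f_sp[k]
                        if f_kind[k] == 0:
                            for i in range(f_pw[k]):
                                v *= x[s] - i
                            if v < 0.0:
                                v = 0.0
                        else:
                            for i in range(f_pw[k]):
                                v *= x[s]
                props[j] = v
                total += v
            since_refresh = 0
            if total <= 0.0:
                while g < n_grid:
                    out[g] = x
                    g += 1
                return t  # deadlock time
        t_next = t + (-math.log(gen.random()) / total)
        while g < n_grid and grid[g] < t_next:
            out[g] = x
            g += 1
        if t_next > t_end:
            while g < n_grid:
                out[g] = x
                g += 1
            return -1.0  # survived to t_end
        t = t_next
        u = gen.random() * total
        acc = 0.0
        chosen = n_r - 1
        for j in range(n_r):
            acc += props[j]
            if u < acc:
                chosen = j
                break
        for k in range(u_off[chosen], u_off[chosen + 1]):
            x[u_sp[k]] += u_delta[k]
        for k in range(dep_off[chosen], dep_off[chosen + 1]):
            j = dep_list[k]
            v = consts[j]
            s1 = fast_s1[j]
            if s1 >= -1:
                if s1 >= 0:
                    v *= x[s1]
                s2 = fast_s2[j]
                if s2 >= 0:
                    v *= x[s2]
            else:
                for k2 in range(f_off[j], f_off[j + 1]):
                    s = f_sp[k2]
                    if f_kind[k2] == 0:
                        for i in range(f_pw[k2]):
                            v *= x[s] - i
                        if v < 0.0:
                            v = 0.0
                    else:
                        for i in range(f_pw[k2]):
                            v *= x[s]
            total += v - props[j]
            props[j] = v
        since_refresh += 1


def _kernel_arrays(net: CompiledNetwork):
    """Precompute the flat arrays the jitted kernel needs: sparse updates,
    the power-1 fast path, and the reaction dependency graph."""
    u_off, u_sp, u_delta = _update_arrays(net)
    n_r = len(net.reactions)

    # fast path: reactions whose rate factors are all power 1, at most two
    fast_s1 = np.full(n_r, -2, dtype=np.int64)  # -2 = generic path
    fast_s2 = np.full(n_r, -1, dtype=np.int64)
    factor_sets: list[set[int]] = []
    for j in range(n_r):
        lo, hi = net.factor_offsets[j], net.factor_offsets[j + 1]
        sp = net.factor_species[lo:hi]
        pw = net.factor_power[lo:hi]
        factor_sets.append(set(int(s) for s in sp))
        if len(sp) <= 2 and np.all(pw == 1):
            fast_s1[j] = sp[0] if len(sp) >= 1 else -1
            if len(sp) == 2:
                fast_s2[j] = sp[1]

    # dependency graph: reaction j firing invalidates reaction i iff a species
    # changed by j enters i's rate
    dep_off = [0]
    dep_list: list[int] = []
    for j in range(n_r):
        changed = {int(s) for s in u_sp[u_off[j]:u_off[j + 1]]}
        for i in range(n_r):
            if factor_sets[i] & changed:
                dep_list.append(i)
        dep_off.append(len(dep_list))
    return (
        fast_s1,
        fast_s2,
        u_off,
        u_sp,
        u_delta,
        np.array(dep_off, dtype=np.int64),
        np.array(dep_list, dtype=np.int64),
    )


def _update_arrays(net: CompiledNetwork):
    """Per-reaction sparse net-change updates (constant species rows are zero)."""
    offsets = [0]
    species: list[int] = []
    deltas: list[float] = []
    for j in range(len(net.reactions)):
        col = net.net_matrix[:, j]
        for i in np.flatnonzero(col):
            species.append(int(i))
            deltas.append(float(col[i]))
        offsets.append(len(species))
    return (
        np.array(offsets, dtype=np.int64),
        np.array(species, dtype=np.int64),
        np.array(deltas, dtype=np.float64),
    )


def _ssa_core_python(seed, x0, t_end, grid, net: CompiledNetwork, out):
    rng = np.random.default_rng(seed)
    x = x0.copy()
    t, g, n_grid = 0.0, 0, len(grid)
    u_off, u_sp, u_delta = _update_arrays(net)
    while True:
        props = net.propensity_vector(x)
        if np.any(props < 0):
            raise ValueError("negative propensity from a symbolic kinetic law")
        # guard: a symbolic law may be positive without enough reactants left
        for j in range(len(props)):
            if props[j] > 0:
                for k in range(u_off[j], u_off[j + 1]):
                    if x[u_sp[k]] + u_delta[k] < 0:
                        props[j] = 0.0
                        break
        total = float(props.sum())
        if total <= 0.0:
            out[g:] = x
            return t
        t_next = t - math.log(rng.random()) / total
        while g < n_grid and grid[g] < t_next:
            out[g] = x
            g += 1
        if t_next > t_end:
            out[g:] = x
            return -1.0
        t = t_next
        j = int(np.searchsorted(np.cumsum(props), rng.random() * total, side="right"))
        j = min(j, len(props) - 1)
        for k in range(u_off[j], u_off[j + 1]):
            x[u_sp[k]] += u_delta[k]


def _cached_kernel_arrays(net: CompiledNetwork):
    cached = getattr(net, "_kernel_arrays_cache", None)
    if cached is None:
        cached = _kernel_arrays(net)
        object.__setattr__(net, "_kernel_arrays_cache", cached)
    return cached


def sample_final_counts(
    model: Model | CompiledNetwork,
    t: float,
    n_reps: int,
    base_seed: int,
) -> np.ndarray:
    """Final molecule counts of ``n_reps`` independent runs at time ``t``.

    Returns an (n_reps, n_species) integer array; replicate r uses seed
    ``base_seed + r``. This is the cheap bulk interface used to compare the
    sampler's empirical transient distribution with exact CTMC analysis.
    """
    net = model if isinstance(model, CompiledNetwork) else compile_network(model)
    x0 = _validated_counts(net, net.initial_state)
    grid = np.array([0.0, float(t)])
    out = np.empty((2, len(net.species)))
    finals = np.empty((n_reps, len(net.species)), dtype=np.int64)
    if net.all_mass_action:
        fast_s1, fast_s2, u_off, u_sp, u_delta, dep_off, dep_list = _cached_kernel_arrays(net)
        for r in range(n_reps):
            _ssa_core_ma(
                np.random.default_rng(int(base_seed) + r),
                x0,
                float(t),
                grid,
                net.ma_consts,
                net.factor_offsets,
                net.factor_species,
                net.factor_power,
                net.factor_kind,
                fast_s1,
                fast_s2,
                u_off,
                u_sp,
                u_delta,
                dep_off,
                dep_list,
                out,
            )
            finals[r] = out[-1]
    else:
        for r in range(n_reps):
            _ssa_core_python(int(base_seed) + r, x0, float(t), grid, net, out)
            finals[r] = out[-1]
    return finals


def ssa_simulate(
    model: Model | CompiledNetwork,
    t_end: float,
    seed: int,
    n_points: int = 1000,
) -> tuple[Trajectory, ExtinctionReport]:
    """One exact stochastic trajectory, recorded on a uniform grid.

    Identical (model, t_end, seed) always reproduce the same trajectory.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    net = model if isinstance(model, CompiledNetwork) else compile_network(model)
    x0 = _validated_counts(net, net.initial_state)
    grid = np.linspace(0.0, t_end, n_points + 1)
    out = np.empty((len(grid), len(net.species)))
    if net.all_mass_action:
        fast_s1, fast_s2, u_off, u_sp, u_delta, dep_off, dep_list = _cached_kernel_arrays(net)
        t_dead = _ssa_core_ma(
            np.random.default_rng(int(seed)),
            x0,
            float(t_end),
            grid,
            net.ma_consts,
            net.factor_offsets,
            net.factor_species,
            net.factor_power,
            net.factor_kind,
            fast_s1,
            fast_s2,
            u_off,
            u_sp,
            u_delta,
            dep_off,
            dep_list,
            out,
        )
    else:
        t_dead = _ssa_core_python(int(seed), x0, float(t_end), grid, net, out)

    extinct = t_dead >= 0.0
    final = {s: int(out[-1, i]) for i, s in enumerate(net.species)}
    meta = {
        "engine": "ssa",
        "seed": int(seed),
        "parameters": dict(net.param_env),
        "extinct": bool(extinct),
    }
    traj = Trajectory(grid, net.species, out, meta)
    report = ExtinctionReport(bool(extinct), float(t_dead) if extinct else None, final)
    return traj, report


def average_trajectories(trajectories: list[Trajectory], grid: np.ndarray) -> Trajectory:
    """Pointwise mean of replicate trajectories on ``grid`` (LVCF resampling)."""
    if not trajectories:
        raise ValueError("cannot average an empty list of trajectories")
    species = trajectories[0].species
    for traj in trajectories[1:]:
        if traj.species != species:
            raise ValueError(
                f"species sets differ: {species} vs {traj.species}"
            )
    grid = np.asarray(grid, dtype=float)
    stacked = np.stack([t.resample(grid).values for t in trajectories])
    meta = {"engine": "ssa", "n_averaged": len(trajectories)}
    return Trajectory(grid, species, stacked.mean(axis=0), meta)


def extinction_probability(
    model: Model,
    n_reps: int,
    t_end: float,
    base_seed: int,
    n_points: int = 1,
) -> ExtinctionSummary:
    """Fraction of replicates dead by ``t_end``, with a 95% Wilson interval.

    Replicate r uses seed ``base_seed + r``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    net = compile_network(model)
    n_extinct = 0
    for r in range(n_reps):
        _, report = ssa_simulate(net, t_end, base_seed + r, n_points=n_points)
        n_extinct += report.extinct
    low, high = proportion_confint(n_extinct, n_reps, alpha=0.05, method="wilson")
    return ExtinctionSummary(
        fraction=n_extinct / n_reps,
        ci_low=float(low),
        ci_high=float(high),
        n_reps=n_reps,
        n_extinct=n_extinct,
        t_end=t_end,
        base_seed=base_seed,
    )
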