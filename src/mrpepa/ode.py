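"""Deterministic (ODE) semantics of a reaction network.

The network's continuous dynamics are dx/dt = N v(x), where N is the net
stoichiometry matrix and v(x) the vector of kinetic-law values at state x.
Environment-held species are excluded from the integrated state vector
altogether (their rows of N are zero by construction), so their series are
exactly constant rather than constant to integrator tolerance.

The (M,R) instantiation is moderately stiff (unbinding constants of 100
against binding constants of 0.01), so the default integrator is LSODA with
tight tolerances.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import CompiledNetwork, Model, ModelError, compile_network, recognise_mass_action
from .trajectory import SteadyStateResult, Trajectory

DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10
STEADY_STATE_TOL = 1e-4  # molecules per time unit


class IntegrationError(RuntimeError):
    """Adaptive integration failed (stiffness or step underflow)."""

    def __init__(self, message: str, t_failed: float):
        super().__init__(f"{message} (at t = {t_failed:g})")
        self.t_failed = t_failed


def ode_rhs(model_or_net: Model | CompiledNetwork, state: dict[str, float]) -> dict[str, float]:
    """Rate of change of every species at ``state``.

    Derivatives are the stoichiometry-weighted sums of the kinetic-law
    values; every constant species has derivative exactly 0.
    """
    net = _as_network(model_or_net)
    missing = [s for s in net.species if s not in state]
    if missing:
        raise KeyError(f"state is missing species: {', '.join(missing)}")
    x = np.array([float(state[s]) for s in net.species])
    if np.any(x < 0):
        raise ValueError("state quantities must be non-negative")
    dx = net.net_matrix @ net.rate_vector(x)
    return dict(zip(net.species, dx.astype(float)))


def _as_network(model_or_net) -> CompiledNetwork:
    if isinstance(model_or_net, CompiledNetwork):
        return model_or_net
    return compile_network(model_or_net)


def _dynamic_rhs(net: CompiledNetwork):
    """RHS over dynamic species only; constant species pinned to x0."""
    dyn = np.flatnonzero(net.dynamic_mask)
    n_dyn = net.net_matrix[dyn, :]
    full = net.initial_state.copy()

    def rhs(t, y):
        full[dyn] = y
        return n_dyn @ net.rate_vector(full)

    return rhs, dyn


def _embed(net: CompiledNetwork, y_dyn: np.ndarray, dyn: np.ndarray) -> np.ndarray:
    x = net.initial_state.copy()
    x[dyn] = y_dyn
    return x


def simulate_ode(
    model: Model,
    t_end: float,
    n_points: int = 1000,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network on a uniform grid of ``n_points + 1`` times.

    Small negative undershoots (above ``-abs_tol``) are clamped to zero in
    the reported series; an undershoot below ``-abs_tol`` sets the
    ``negative_undershoot`` flag in the trajectory metadata.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    net = compile_network(model)
    rhs, dyn = _dynamic_rhs(net)
    grid = np.linspace(0.0, t_end, n_points + 1)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        net.initial_state[dyn],
        method=method,
        t_eval=grid,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        t_failed = sol.t[-1] if len(sol.t) else 0.0
        raise IntegrationError(f"integration failed: {sol.message}", t_failed)

    values = np.tile(net.initial_state, (len(grid), 1))
    values[:, dyn] = sol.y.T
    undershoot = float(values.min())
    values = np.clip(values, 0.0, None)
    meta = {
        "engine": "ode",
        "method": method,
        "rel_tol": rel_tol,
        "abs_tol": abs_tol,
        "parameters": dict(model.parameters),
        "negative_undershoot": bool(undershoot < -abs_tol),
    }
    return Trajectory(grid, net.species, values, meta)


def find_steady_state(
    model: Model,
    t_max: float = 10_000.0,
    abs_tol: float = STEADY_STATE_TOL,
    rel_tol: float = DEFAULT_REL_TOL,
    int_abs_tol: float = DEFAULT_ABS_TOL,
    method: str = "LSODA",
    n_checkpoints: int = 200,
) -> SteadyStateResult:
    """Integrate until every non-constant derivative is below ``abs_tol``.

    The criterion max |dx/dt| <= abs_tol is checked on a checkpoint schedule
    up to ``t_max``. Once the integrator has entered the attractor's basin
    (residual below a coarse threshold) the endpoint is polished by a Newton
    solve of dx/dt = 0, since an adaptive integrator alone stalls at a
    residual set by its relative tolerance rather than reaching the exact
    fixed point. A polished state is only accepted if it stays non-negative
    and close to the integration endpoint. Failing to converge by ``t_max``
    is reported (``converged=False``), not raised.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if abs_tol <= 0:
        raise ValueError("abs_tol must be positive")
    net = compile_network(model)
    rhs, dyn = _dynamic_rhs(net)

    def residual(y_dyn: np.ndarray) -> float:
        return float(np.max(np.abs(rhs(0.0, y_dyn)))) if len(y_dyn) else 0.0

    y = net.initial_state[dyn].copy()
    res = residual(y)
    if res <= abs_tol:
        return SteadyStateResult(dict(zip(net.species, net.initial_state)), res, True, 0.0)

    def polish(y_end: np.ndarray) -> np.ndarray | None:
        sol = root(lambda v: rhs(0.0, v), y_end, method="hybr")
        y_fix = sol.x
        close = np.allclose(y_fix, y_end, rtol=1e-3, atol=1.0)
        if sol.success and close and np.all(y_fix >= -int_abs_tol):
            return np.clip(y_fix, 0.0, None)
        return None

    polish_threshold = max(1e3 * abs_tol, 1e-3)
    checkpoints = np.linspace(0.0, t_max, n_checkpoints + 1)[1:]
    t_prev = 0.0
    for t_next in checkpoints:
        sol = solve_ivp(
            rhs, (t_prev, t_next), y, method=method, rtol=rel_tol, atol=int_abs_tol
        )
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}", sol.t[-1])
        y = sol.y[:, -1]
        t_prev = t_next
        res = residual(y)
        if res <= abs_tol:
            state = np.clip(_embed(net, y, dyn), 0.0, None)
            return SteadyStateResult(dict(zip(net.species, state)), res, True, float(t_next))
        if res <= polish_threshold:
            y_fix = polish(y)
            if y_fix is not None and residual(y_fix) <= abs_tol:
                state = _embed(net, y_fix, dyn)
                return SteadyStateResult(
                    dict(zip(net.species, state)), residual(y_fix), True, float(t_next)
                )
    state = np.clip(_embed(net, y, dyn), 0.0, None)
    return SteadyStateResult(dict(zip(net.species, state)), res, False, float(t_max))


def scale_model(model: Model, factor: float) -> Model:
    """Volume-scale a pure mass-action model.

    Initial quantities are multiplied by ``factor`` and each rate constant
    by ``factor**(1 - order)``, where the order counts every
    rate-contributing quantity factor (constant species included). The
    resulting deterministic trajectory is the original one scaled pointwise
    by ``factor`` on the same time grid.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    net = compile_network(model)
    scale_of: dict[str, float] = {}
    for law in model.laws:
        const = recognise_mass_action(model, law)
        if const is None:
            raise ModelError(
                f"cannot scale: kinetic law of {law.reaction!r} is not mass action"
            )
        j = net.reactions.index(law.reaction)
        order = int(net.factor_power[net.factor_offsets[j]:net.factor_offsets[j + 1]].sum())
        scale = factor ** (1 - order)
        if const in scale_of and not math.isclose(scale_of[const], scale):
            raise ModelError(
                f"cannot scale: parameter {const!r} is shared by reactions of different order"
            )
        scale_of[const] = scale
    parameters = {
        name: value * scale_of.get(name, 1.0) for name, value in model.parameters.items()
    }
    initial = {s: v * factor for s, v in model.initial_counts.items()}
    return Model(parameters, model.behaviours, model.laws, initial, model.constant_species)
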