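"""Brute-force transient analysis of the reaction network's CTMC.

The reachable state space is enumerated breadth-first from the initial
state (constant species are part of the rate environment, not the state).
Transitions out of the truncation are routed to a single absorbing overflow
pseudo-state, so the probability mass lost to truncation is tracked exactly.
The transient distribution at time t is computed with a matrix exponential
on the truncated generator; it serves as the independent oracle against
which the Gillespie sampler is checked on small instances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .model import CompiledNetwork, Model, compile_network


class TruncationError(RuntimeError):
    """Probability mass beyond the state cap exceeded the allowed bound."""


@dataclass
class TransientDistribution:
    """State probabilities at one time, over dynamic-species count vectors."""

    species: tuple[str, ...]  # dynamic species only, model order
    probabilities: dict[tuple[int, ...], float]
    leaked_mass: float  # mass absorbed by the truncation boundary
    t: float
    n_states: int

    def probability(self, counts: dict[str, int]) -> float:
        key = tuple(int(counts[s]) for s in self.species)
        return self.probabilities.get(key, 0.0)


def ctmc_transient_oracle(
    model: Model | CompiledNetwork,
    t: float,
    state_cap: int = 20_000,
    leak_tol: float = 1e-6,
) -> TransientDistribution:
    """Exact transient distribution at time ``t`` on a truncated state space.

    Raises :class:`TruncationError` when the enumeration hits ``state_cap``
    and more than ``leak_tol`` probability escapes into the truncated region.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    net = model if isinstance(model, CompiledNetwork) else compile_network(model)
    dyn = np.flatnonzero(net.dynamic_mask)
    dyn_species = tuple(net.species[i] for i in dyn)

    x0_full = net.initial_state.copy()
    if np.any(x0_full != np.round(x0_full)):
        raise ValueError("initial counts must be integers for CTMC analysis")
    x0 = tuple(int(x0_full[i]) for i in dyn)

    index: dict[tuple[int, ...], int] = {x0: 0}
    states: list[tuple[int, ...]] = [x0]
    rows: list[int] = []
    cols: list[int] = []
    rates: list[float] = []
    capped = False

    queue = deque([x0])
    full = x0_full.copy()
    net_cols = [net.net_matrix[dyn, j] for j in range(len(net.reactions))]
    while queue:
        state = queue.popleft()
        i = index[state]
        full[dyn] = state
        props = net.propensity_vector(full)
        for j, a_j in enumerate(props):
            if a_j <= 0.0:
                continue
            succ_arr = np.array(state) + net_cols[j]
            if np.any(succ_arr < 0):  # symbolic law positive without reactants
                continue
            succ = tuple(int(v) for v in succ_arr)
            if succ not in index:
                if len(states) >= state_cap:
                    capped = True
                    rows.append(i)
                    cols.append(len(states))  # overflow column (appended below)
                    rates.append(float(a_j))
                    continue
                index[succ] = len(states)
                states.append(succ)
                queue.append(succ)
            rows.append(i)
            cols.append(index.get(succ, len(states)))
            rates.append(float(a_j))

    n = len(states) + (1 if capped else 0)
    # coo_matrix sums duplicate entries, merging parallel transitions
    q = sp.coo_matrix((rates, (rows, cols)), shape=(n, n)).tocsr()
    out_rates = np.asarray(q.sum(axis=1)).ravel()
    generator = q - sp.diags(out_rates)

    p0 = np.zeros(n)
    p0[0] = 1.0
    if t == 0:
        pt = p0
    else:
        pt = expm_multiply(generator.T.tocsc() * t, p0)
    pt = np.clip(pt, 0.0, None)

    leaked = float(pt[len(states)]) if capped else 0.0
    if capped and leaked > leak_tol:
        raise TruncationError(
            f"state cap {state_cap} reached with {leaked:.3g} probability mass "
            f"beyond the truncation (allowed {leak_tol:g})"
        )
    probs = {s: float(pt[i]) for s, i in index.items() if pt[i] > 0.0}
    return TransientDistribution(dyn_species, probs, leaked, float(t), len(states))
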