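"""Named parameter regimes of the (M,R) instantiation.

* ``fig3`` — the baseline regime: converges to a live steady state
  (A=1000, p~577, B~495, f~286, pB~28, fA~28, Bf~14) and its stochastic
  runs consistently survive past 1000 time units.
* ``fig6`` — identical except d2 = 0.07: the faster degradation of the
  catalyst f tips the deterministic dynamics away from the baseline
  attractor (bistability between a live and a collapsed regime).
* ``fig7`` — fast-binding regime (k1 = l1 = m1 = 1) with strong
  degradation: deterministically it still reaches a live steady state, but
  single stochastic runs may die — identical inputs can yield either
  "life" or "death".
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Model
from .mr import MRParams, build_mr_model


@dataclass(frozen=True)
class Preset:
    name: str
    params: MRParams
    description: str

    def build(self) -> Model:
        return build_mr_model(self.params)


_FIG3 = MRParams(
    k1=0.01, k2=100.0, k3=1.0,
    l1=0.01, l2=100.0, l3=1.0,
    m1=0.01, m2=100.0, m3=1.0,
    d1=0.0, d2=0.05, d3=0.02426,
    A_init=1000.0, f_init=1000.0,
    B_init=0.0, p_init=0.0, fA_init=0.0, pB_init=0.0, Bf_init=0.0,
)

PRESETS: dict[str, Preset] = {
    "fig3": Preset("fig3", _FIG3, "baseline steady-state regime"),
    "fig6": Preset(
        "fig6", _FIG3.replace(d2=0.07), "baseline with faster f degradation (bistable)"
    ),
    "fig7": Preset(
        "fig7",
        MRParams(
            k1=1.0, k2=100.0, k3=10.0,
            l1=1.0, l2=100.0, l3=20.0,
            m1=1.0, m2=100.0, m3=10.0,
            d1=0.0, d2=60.0, d3=19.2666666,
            A_init=1000.0, f_init=1000.0,
            B_init=0.0, p_init=0.0, fA_init=0.0, pB_init=0.0, Bf_init=0.0,
        ),
        "fragile regime: deterministically alive, stochastically mortal",
    ),
}


def get_preset(name: str) -> Preset:
    """Look up a preset regime by name."""
    try:
        return PRESETS[name]
    except KeyError:
        available = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown preset {name!r}; available presets: {available}") from None
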