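import numpy as np
import pytest

from mrpepa import MRParams, build_mr_model, compile_network, get_preset
from mrpepa.parser import parse_model

# printed steady-state molecule counts of the baseline regime
BASELINE_STEADY = {"A": 1000, "p": 577, "B": 495, "f": 286, "pB": 28, "fA": 28, "Bf": 14}


@pytest.fixture(scope="session")
def fig3_model():
    return get_preset("fig3").build()

@pytest.fixture(scope="session")
def fig6_model():
    return get_preset("fig6").build()

@pytest.fixture(scope="session")
def fig7_model():
    return get_preset("fig7").build()


@pytest.fixture(scope="session")
def fig3_network(fig3_model):
    return compile_network(fig3_model)


@pytest.fixture
def decay_model():
    """Single first-order decay X -> 0 at rate c, one initial molecule."""

    def build(c: float = 0.3, x0: int = 1):
        return parse_model(
            f"""
            c = {c};
            kineticLawOf decay : fMA(c);
            X = (decay, 1) <<;
            X[{x0}]
            """
        )

    return build


@pytest.fixture(scope="session")
def tiny_mr_model():
    """Small-count (M,R) instance: A=2 held constant, one f, unit rates,
    no degradation — small enough for exact CTMC analysis."""
    return build_mr_model(
        MRParams(
            k1=1, k2=1, k3=1, l1=1, l2=1, l3=1, m1=1, m2=1, m3=1,
            d1=0, d2=0, d3=0,
            A_init=2, f_init=1, B_init=0, p_init=0, fA_init=0, pB_init=0, Bf_init=0,
        )
    )
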