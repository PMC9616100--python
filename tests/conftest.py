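import numpy as np
import pytest

from confmodel.scheme_core import KineticScheme, Reaction
from confmodel.synthetic_data import PRESETS


@pytest.fixture
def decay_scheme():
    """A -> B, k = 1 /s."""
    return KineticScheme(
        species=["A", "B"],
        reactions=[Reaction(("A",), ("B",), "k")],
        rate_constants={"k": 1.0},
        name="decay",
    )


@pytest.fixture
def two_state_scheme():
    """I <-> A with k_ia = 3e-4, k_ai = 1e-4 /s (slow interconversion)."""
    return KineticScheme(
        species=["I", "A"],
        reactions=[Reaction(("I",), ("A",), "k_ia"), Reaction(("A",), ("I",), "k_ai")],
        rate_constants={"k_ia": 3e-4, "k_ai": 1e-4},
        name="two_state",
    )


@pytest.fixture
def bimolecular_scheme():
    """E + L <-> EL, K_D = 1 uM."""
    return KineticScheme(
        species=["E", "L", "EL"],
        reactions=[
            Reaction(("E", "L"), ("EL",), "k_on"),
            Reaction(("EL",), ("E", "L"), "k_off"),
        ],
        rate_constants={"k_on": 1e6, "k_off": 1.0},
        name="one_to_one",
    )


@pytest.fixture(params=["HG3", "HG3.7", "HG3.17"])
def preset(request):
    return PRESETS[request.param]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
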