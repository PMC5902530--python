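import math

import pytest
from hypothesis import strategies as st

from causalform import CapacityModel, Cause, EffectRange


@pytest.fixture
def two_generator_binary():
    """L=0, U=1, two binary generators at strength 0.5 — the textbook case."""
    return CapacityModel(
        EffectRange(0.0, 1.0),
        [Cause("a", "generator", 0.5), Cause("b", "generator", 0.5)],
    )


@pytest.fixture
def mixed_model():
    """Finite bounds with all three roles present."""
    return CapacityModel(
        EffectRange(2.0, 3.0),
        [
            Cause("g1", "generator", 1.2, max_value=2.0),
            Cause("g2", "generator", 0.5, max_value=1.0),
            Cause("r1", "reducer", 0.8, max_value=1.5),
            Cause("b1", "blocker", 0.4, max_value=1.0),
        ],
    )


@st.composite
def finite_models_with_assignments(draw, max_causes=5):
    """A valid finite-bound model plus a valid assignment for it."""
    U = draw(st.floats(0.5, 10.0))
    has_reducer_room = draw(st.booleans())
    L = draw(st.floats(0.5, 10.0)) if has_reducer_room else 0.0
    n = draw(st.integers(1, max_causes))
    causes = []
    values = {}
    for i in range(n):
        roles = ["generator", "blocker"] + (["reducer"] if L > 0 else [])
        role = draw(st.sampled_from(roles))
        M = draw(st.floats(0.25, 2.0))
        bound = {"generator": U, "reducer": L, "blocker": 1.0}[role]
        w = draw(st.floats(0.0, bound / M * 0.999))
        causes.append(Cause(f"c{i}", role, w, M))
        values[f"c{i}"] = draw(st.floats(0.0, M))
    model = CapacityModel(EffectRange(L, U), causes)
    return model, values


@st.composite
def binary_models_with_assignments(draw, max_causes=6):
    """An L=0, U=1 all-binary model (generators + blockers) and 0/1 values."""
    n = draw(st.integers(1, max_causes))
    causes = []
    values = {}
    for i in range(n):
        role = draw(st.sampled_from(["generator", "blocker"]))
        w = draw(st.floats(0.0, 1.0))
        causes.append(Cause(f"c{i}", role, w, 1.0))
        values[f"c{i}"] = float(draw(st.integers(0, 1)))
    model = CapacityModel(EffectRange(0.0, 1.0), causes)
    return model, values


INF = math.inf
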