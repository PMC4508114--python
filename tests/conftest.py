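import numpy as np
import pytest

from tumorsim.statechart import ChartDef, StateNode, TransitionDef, build_chart


@pytest.fixture
def flat_chart() -> ChartDef:
    """root compound with basic children A*, B and one a-transition A->B."""
    return build_chart({
        "states": {"id": "root", "kind": "compound", "initial": "A",
                   "children": ["A", "B"]},
        "transitions": [{"id": "t1", "source": "A", "target": "B", "trigger": "e"}],
    })


@pytest.fixture
def orthogonal_chart() -> ChartDef:
    """Two independent regions R1{A*,B}, R2{C*,D}, both reacting to 'e'."""
    return build_chart({
        "states": {"id": "root", "kind": "orthogonal", "children": [
            {"id": "R1", "kind": "compound", "initial": "A", "children": ["A", "B"]},
            {"id": "R2", "kind": "compound", "initial": "C", "children": ["C", "D"]},
        ]},
        "transitions": [
            {"id": "t1", "source": "A", "target": "B", "trigger": "e"},
            {"id": "t2", "source": "C", "target": "D", "trigger": "e"},
        ],
    })


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
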