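import numpy as np
import pytest

from sacmorph.types import NeuriteTree


def make_tree(nodes):
    """Build a NeuriteTree from (id, parent, x, y, z, radius, kind) tuples."""
    arr = list(nodes)
    return NeuriteTree(
        ids=np.array([n[0] for n in arr]),
        parent=np.array([n[1] for n in arr]),
        xyz=np.array([[n[2], n[3], n[4]] for n in arr], dtype=float),
        radius=np.array([n[5] for n in arr], dtype=float),
        kind=np.array([n[6] if len(n) > 6 else (1 if n[1] == -1 else 3)
                       for n in arr]),
    )


@pytest.fixture
def chain_tree():
    """Soma plus 5 unit-length edges along +x."""
    nodes = [(1, -1, 0, 0, 0, 4.0)]
    for i in range(5):
        nodes.append((i + 2, i + 1, i + 1.0, 0, 0, 0.3))
    return make_tree(nodes)


@pytest.fixture
def bifurcation_tree():
    """One trunk that bifurcates once: soma - trunk - two daughters."""
    return make_tree([
        (1, -1, 0, 0, 0, 4.0),
        (2, 1, 10, 0, 0, 0.3),
        (3, 2, 20, 5, 0, 0.3),
        (4, 2, 20, -5, 0, 0.3),
    ])


@pytest.fixture
def four_trunk_tree():
    """Soma with 4 unbranched trunks at right angles."""
    return make_tree([
        (1, -1, 0, 0, 0, 4.0),
        (2, 1, 50, 0, 0, 0.3),
        (3, 1, 0, 50, 0, 0.3),
        (4, 1, -50, 0, 0, 0.3),
        (5, 1, 0, -50, 0, 0.3),
    ])
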