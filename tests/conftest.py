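import io

import numpy as np
import pytest

from essprot.io import (
    ExpressionMatrix,
    LabelSet,
    LocalizationTable,
    StaticPPINetwork,
    align_dataset,
    canonical_edge,
)


def make_network(edge_pairs):
    edges = frozenset(canonical_edge(u, v) for u, v in edge_pairs)
    nodes = frozenset(x for e in edges for x in e)
    return StaticPPINetwork(nodes=nodes, edges=edges)


@pytest.fixture
def triangle_network():
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def tiny_dataset(triangle_network):
    """Triangle A-B-C; A has a single expression spike, B and C are constant."""
    expr = ExpressionMatrix(
        proteins=("A", "B", "C"),
        timepoints=("t1", "t2", "t3"),
        values=np.array([[0.0, 0.0, 6.0], [2.0, 2.0, 2.0], [1.0, 1.0, 1.0]]),
    )
    loc = LocalizationTable(records=frozenset({("A", "nucleus"), ("B", "nucleus"), ("C", "cytosol")}))
    labels = LabelSet(essential=frozenset({"B"}))
    return align_dataset(triangle_network, expr, loc, labels)


def text(s: str) -> io.StringIO:
    return io.StringIO(s)
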