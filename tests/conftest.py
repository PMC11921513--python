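import numpy as np
import pytest

from tdahotspot import ClustererSpec, DataMatrix


@pytest.fixture
def ward6() -> ClustererSpec:
    return ClustererSpec(method="agglomerative", n_clusters=6, linkage="ward")


@pytest.fixture
def line_data() -> DataMatrix:
    """40 points evenly spaced on a line in the plane."""
    x = np.linspace(0.0, 1.0, 40)
    values = np.column_stack([x, np.zeros_like(x)])
    return DataMatrix(values=values, sample_ids=tuple(f"s{i}" for i in range(40)))


def toy_graph(member_sets, attr=None):
    """Build a MapperGraph from explicit member sets (and optionally
    annotate it from a per-sample attribute vector)."""
    from tdahotspot import MapperVertex, build_nerve
    from tdahotspot.hotspot import annotate_attribute, annotate_gradient

    vertices = [
        MapperVertex(id=i, members=frozenset(m), interval_index=i)
        for i, m in enumerate(member_sets)
    ]
    graph = build_nerve(vertices)
    if attr is not None:
        annotate_attribute(graph, np.asarray(attr, dtype=float))
        annotate_gradient(graph)
    return graph
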