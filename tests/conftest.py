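import pytest

from kgexplore.examples import app_alzheimer_example, app_alzheimer_queryspec
from kgexplore.synth import SynthParams, generate


@pytest.fixture(scope="session")
def app_kg():
    return app_alzheimer_example()


@pytest.fixture(scope="session")
def app_qspec():
    return app_alzheimer_queryspec()


@pytest.fixture(scope="session")
def synth_kg_gt():
    """The default synthetic knowledge graph at seed 0, with ground truth."""
    return generate(SynthParams(seed=0))


def random_dag(rng, n_nodes, edge_prob=0.08):
    """A random DAG over CURIE-named nodes (edges respect a topological order)."""
    from kgexplore.anatomy import BroaderGraph
    from kgexplore.namespaces import CurieRef

    nodes = [CurieRef("obo", f"TESTNODE{i:04d}") for i in range(n_nodes)]
    graph = BroaderGraph()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < edge_prob:
                pair = (nodes[i], nodes[j])
                if rng.uniform() < 0.5:
                    graph.from_partof.add(pair)
                else:
                    graph.from_subclassof.add(pair)
    return graph, nodes
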