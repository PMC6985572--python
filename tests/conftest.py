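import networkx as nx
import pytest

from sdikit.ontology_io import OntologyDag
from sdikit.synthetic_fixtures import FixtureSpec, make_ontology


def dag_from_edges(edges, extra_nodes=()):
    """Build an OntologyDag from (child, parent, relation) triples."""
    graph = nx.DiGraph()
    for node in extra_nodes:
        graph.add_node(node)
    for child, parent, relation in edges:
        graph.add_edge(child, parent, relation=relation)
    return OntologyDag(graph=graph, namespace="cellular_component")


@pytest.fixture
def two_leaf_dag():
    """A is_a R, B is_a R — the worked-example ontology."""
    return dag_from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def chain_dag():
    """C part_of A, A is_a R."""
    return dag_from_edges([("C", "A", "part_of"), ("A", "R", "is_a")])


@pytest.fixture
def random_dag():
    return make_ontology(FixtureSpec(n_terms=30, depth=5, part_of_fraction=0.4, seed=7))


@pytest.fixture
def obo_text():
    return """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: cellular_component

[Term]
id: GO:0000002
name: organelle
namespace: cellular_component
alt_id: GO:0000099
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: membrane piece
namespace: cellular_component
relationship: part_of GO:0000002 ! organelle
relationship: regulates GO:0000001

[Term]
id: GO:0000004
name: some process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000005
name: gone
namespace: cellular_component
is_obsolete: true
"""


@pytest.fixture
def obo_file(tmp_path, obo_text):
    path = tmp_path / "mini.obo"
    path.write_text(obo_text)
    return path
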