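import numpy as np
import pytest

from ontovar.annotations import Domain, DomainRegistry
from ontovar.fixtures import FixtureSpec, make_disease_world, make_ontology
from ontovar.ontology import OntologyGraph, Relation, TermSimilarity, compute_term_stats


def build_graph(edges, root, namespace="T"):
    """Small helper: edges as (child, parent, relation-string) triples."""
    g = OntologyGraph(namespace=namespace, root=root)
    g.dag.add_node(root)
    for child, parent, rel in edges:
        g.dag.add_edge(child, parent, key=Relation(rel).value)
    g.validate()
    return g


@pytest.fixture
def diamond_graph():
    """Root A with children B, C; D below both B and C (B via is_a, C via part_of)."""
    return build_graph(
        [("B", "A", "is_a"), ("C", "A", "is_a"),
         ("D", "B", "is_a"), ("D", "C", "part_of")],
        root="A",
    )


@pytest.fixture
def diamond_engine(diamond_graph):
    return TermSimilarity(diamond_graph)


@pytest.fixture
def chain_graph():
    """Root -> X1 -> X2 -> X3, pure is_a chain."""
    return build_graph(
        [("X1", "R", "is_a"), ("X2", "X1", "is_a"), ("X3", "X2", "is_a")], root="R"
    )


def random_graph(seed, n_terms=None):
    rng = np.random.default_rng(seed)
    n = n_terms or int(rng.integers(5, 51))
    return make_ontology("RG", n, rng, max_depth=6,
                         part_of_fraction=0.3, multi_parent_prob=0.3)


@pytest.fixture(scope="session")
def world():
    """Default high-signal synthetic world (shared; treat as read-only)."""
    return make_disease_world(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def null_world():
    return make_disease_world(FixtureSpec(seed=0, signal=0.0))


@pytest.fixture
def mini_registry():
    """Two tiny registered domains for cross-domain plumbing tests."""
    reg = DomainRegistry()
    reg.register(Domain.HPO, build_graph(
        [("HP:1", "HP:0", "is_a"), ("HP:2", "HP:1", "is_a"), ("HP:3", "HP:1", "is_a")],
        root="HP:0", namespace="HP"))
    reg.register(Domain.GO_BP, build_graph(
        [("GB:1", "GB:0", "is_a"), ("GB:2", "GB:1", "is_a"), ("GB:3", "GB:0", "is_a")],
        root="GB:0", namespace="GB"))
    return reg
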