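"""Ontology graphs, intrinsic information content and term-level semantic similarity.

An ontology is modelled as a rooted directed acyclic graph whose vertices are
terms and whose edges point from a child term to a parent term, typed as
``is_a`` or ``part_of``.  Every other relationship type (``regulates``,
``develops_from``, ...) is dropped at parse time.

Rather than estimating a term's probability of occurrence from an annotation
corpus -- which is biased towards well-studied concepts and drifts as the
corpus evolves -- the probability is derived from graph topology alone.  The
root occurs with probability 1; every other term inherits probability from its
*most informative* direct ancestor, discounted by that ancestor's number of
children and by an edge-type weight that penalizes ``is_a`` edges more than
``part_of`` edges::

    P(root) = 1
    P(t)    = min over parent edges (t --rel--> a) of  (P(a) / C(a)) * w_rel

with ``w_is_a = 0.2`` and ``w_part_of = 0.4`` by default, ``C(a)`` the number
of direct children of ``a``.  Information content is ``IC(t) = -ln P(t)``, so
the root has IC 0 and IC strictly increases away from the root.

Term-to-term similarity is the normalized information content of the most
informative common ancestor (MICA)::

    sim(a, b) = IC(MICA(a, b)) / max(IC(a), IC(b))

A term's similarity to itself is 1 (its MICA is itself); two terms whose only
common ancestor is the root have similarity 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "EdgeWeights",
    "TermStats",
    "OntologyGraph",
    "OboParseError",
    "CycleError",
    "UnreachableTermError",
    "parse_obo",
    "compute_term_stats",
    "mica",
    "term_similarity",
    "TermSimilarity",
    "write_term_stats",
]


class Relation(str, Enum):
    IS_A = "is_a"
    PART_OF = "part_of"


RETAINED_RELATIONS = (Relation.IS_A.value, Relation.PART_OF.value)


@dataclass(frozen=True)
class EdgeWeights:
    """Edge-type discount factors used by the probability recursion.

    ``is_a`` edges receive more weight (a smaller factor, hence a larger IC
    step) than ``part_of`` edges.
    """

    w_is_a: float = 0.2
    w_part_of: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.w_is_a <= 1) or not (0 < self.w_part_of <= 1):
            raise ValueError("edge weights must lie in (0, 1]")

    def weight(self, relation: Relation | str) -> float:
        rel = Relation(relation)
        return self.w_is_a if rel is Relation.IS_A else self.w_part_of


@dataclass(frozen=True)
class TermStats:
    """Per-term occurrence probability, information content and child count."""

    term: str
    p: float
    ic: float
    n_children: int


class OboParseError(ValueError):
    pass


class CycleError(OboParseError):
    pass


class UnreachableTermError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """A rooted DAG of ontology terms with typed child->parent edges.

    ``dag`` stores one directed edge per retained relationship, oriented from
    child to parent and keyed by relation type.  ``root`` is unique; when the
    source declared several namespace roots a virtual root is inserted above
    them so the probability recursion has a single base case.
    """

    namespace: str
    dag: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    root: str = ""
    obsolete: set[str] = field(default_factory=set)
    replaced_by: dict[str, str] = field(default_factory=dict)
    orphans: set[str] = field(default_factory=set)

    @property
    def terms(self) -> set[str]:
        return set(self.dag.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.dag

    def parents(self, term: str) -> list[tuple[str, Relation]]:
        """Direct parents of ``term`` with the relation linking them."""
        return [(a, Relation(k)) for _, a, k in self.dag.out_edges(term, keys=True)]

    def children(self, term: str) -> set[str]:
        return set(c for c, _, _ in self.dag.in_edges(term, keys=True))

    def n_children(self, term: str) -> int:
        return len(self.children(term))

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including the term itself."""
        anc = nx.descendants(self.dag, term)  # edges point child -> parent
        anc.add(term)
        return anc

    def validate(self) -> None:
        try:
            cycle = nx.find_cycle(self.dag)
            raise CycleError(f"cycle among retained edges: {cycle}")
        except nx.NetworkXNoCycle:
            pass
        if self.root not in self.dag:
            raise OboParseError(f"root {self.root!r} not in graph")
        unreachable = [
            t for t in self.dag.nodes if t != self.root and self.root not in self.ancestors(t)
        ]
        if unreachable:
            raise UnreachableTermError(
                f"{len(unreachable)} terms cannot reach root {self.root!r}: "
                f"{sorted(unreachable)[:10]}"
            )


VIRTUAL_ROOT_SUFFIX = ":VROOT"


def _build_graph(
    namespace: str,
    term_edges: Iterable[tuple[str, str, str]],
    all_terms: set[str],
    obsolete: set[str],
    replaced_by: dict[str, str],
) -> OntologyGraph:
    g = OntologyGraph(namespace=namespace, obsolete=obsolete, replaced_by=replaced_by)
    live = all_terms - obsolete
    g.dag.add_nodes_from(live)
    n_dropped = 0
    for child, parent, rel in term_edges:
        if child in obsolete or parent in obsolete:
            n_dropped += 1
            continue
        g.dag.add_edge(child, parent, key=rel)
    if n_dropped:
        logger.info("%s: dropped %d edges touching obsolete terms", namespace, n_dropped)

    try:
        cycle = nx.find_cycle(g.dag)
        raise CycleError(f"cycle among retained edges in {namespace!r}: {cycle}")
    except nx.NetworkXNoCycle:
        pass

    parentless = [t for t in g.dag.nodes if g.dag.out_degree(t) == 0]
    declared_roots = [t for t in parentless if g.dag.in_degree(t) > 0]
    orphans = set(parentless) - set(declared_roots)
    if not declared_roots and len(orphans) == 1:
        # a single isolated term is the namespace root of a trivial ontology
        declared_roots = list(orphans)
        orphans = set()
    if not declared_roots:
        raise OboParseError(f"no root found for namespace {namespace!r}")
    if orphans:
        logger.warning("%s: %d orphan terms excluded: %s", namespace, len(orphans), sorted(orphans)[:10])
        g.dag.remove_nodes_from(orphans)
        g.orphans = orphans
    if len(declared_roots) == 1:
        g.root = declared_roots[0]
    else:
        g.root = namespace + VIRTUAL_ROOT_SUFFIX
        for r in sorted(declared_roots):
            g.dag.add_edge(r, g.root, key=Relation.IS_A.value)
    g.validate()
    return g


def parse_obo(stream: IO[str] | str, namespace: str | None = None) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into an :class:`OntologyGraph`.

    Parameters
    ----------
    stream:
        Open text handle or path to an OBO file.
    namespace:
        If given and the file defines per-term ``namespace`` tags, only terms
        of that namespace are kept (the three Gene Ontology domains share one
        file, for instance).

    Only ``is_a`` and ``part_of`` relationships are retained; all others are
    dropped with a logged count.  Obsolete terms are recorded (with their
    ``replaced_by`` target when declared) but excluded from the graph.
    A term referenced as a parent but never defined is a hard error, as is a
    cycle among retained edges.
    """
    raw = obonet.read_obo(stream, ignore_obsolete=False)

    undefined = sorted(n for n, d in raw.nodes(data=True) if not d)
    if undefined:
        raise OboParseError(f"terms referenced but never defined: {undefined[:10]}")

    def in_ns(node: str) -> bool:
        if namespace is None:
            return True
        ns = raw.nodes[node].get("namespace")
        return ns is None or ns == namespace

    terms = {n for n in raw.nodes if in_ns(n)}
    obsolete = {
        n for n in terms if str(raw.nodes[n].get("is_obsolete", "")).lower() == "true"
    }
    replaced: dict[str, str] = {}
    for n in obsolete:
        rb = raw.nodes[n].get("replaced_by") or []
        if rb:
            replaced[n] = rb[0]

    edges = []
    n_other = 0
    for child, parent, key in raw.edges(keys=True):
        if child not in terms or parent not in terms:
            continue
        if key in RETAINED_RELATIONS:
            edges.append((child, parent, key))
        else:
            n_other += 1
    if n_other:
        logger.info("%s: dropped %d non-is_a/part_of edges", namespace or "obo", n_other)

    return _build_graph(namespace or "obo", edges, terms, obsolete, replaced)


def compute_term_stats(
    graph: OntologyGraph, weights: EdgeWeights | None = None
) -> dict[str, TermStats]:
    """Compute occurrence probability and IC for every term.

    Terms are processed in topological order from the root; each non-root
    term takes the minimum candidate probability over its parent edges
    (the most informative direct ancestor, after applying the edge weight).

    Raises
    ------
    UnreachableTermError
        If any term has no path of retained edges to the root.
    """
    weights = weights or EdgeWeights()
    graph.validate()
    p: dict[str, float] = {graph.root: 1.0}
    # topological order on parent -> child orientation puts root first
    order = list(nx.topological_sort(graph.dag.reverse(copy=False)))
    stats: dict[str, TermStats] = {}
    for t in order:
        if t != graph.root:
            candidates = [
                (p[a] / graph.n_children(a)) * weights.weight(rel)
                for a, rel in graph.parents(t)
            ]
            p[t] = min(candidates)
        pt = p[t]
        ic = 0.0 if pt >= 1.0 else -math.log(pt)
        stats[t] = TermStats(term=t, p=pt, ic=ic, n_children=graph.n_children(t))
    return stats


def mica(a: str, b: str, graph: OntologyGraph, stats: Mapping[str, TermStats]) -> str:
    """Most informative common ancestor of ``a`` and ``b``.

    Ancestor sets include the terms themselves, so ``mica(t, t) == t``.
    Ties are broken lexicographically for determinism; the root is always a
    common ancestor, so the result is always defined.
    """
    common = graph.ancestors(a) & graph.ancestors(b)
    return max(sorted(common), key=lambda t: stats[t].ic)


def term_similarity(
    a: str, b: str, stats: Mapping[str, TermStats], graph: OntologyGraph
) -> float:
    """Normalized-MICA similarity in [0, 1]; symmetric; ``sim(t, t) == 1``."""
    if a == b:
        return 1.0
    m = mica(a, b, graph, stats)
    denom = max(stats[a].ic, stats[b].ic)
    if denom == 0.0:
        return 1.0  # both terms are the root
    return stats[m].ic / denom


class TermSimilarity:
    """Memoized term-pair similarity over one ontology domain.

    All-pairs similarity matrices are never materialized; pairs are computed
    lazily and cached, which is equivalent at any scale that fits in memory.
    """

    def __init__(
        self, graph: OntologyGraph, stats: Mapping[str, TermStats] | None = None,
        weights: EdgeWeights | None = None,
    ):
        self.graph = graph
        self.stats = dict(stats) if stats is not None else compute_term_stats(graph, weights)
        self._anc: dict[str, set[str]] = {}
        self._sim: dict[tuple[str, str], float] = {}

    def ic(self, term: str) -> float:
        return self.stats[term].ic

    def ancestors(self, term: str) -> set[str]:
        if term not in self._anc:
            self._anc[term] = self.graph.ancestors(term)
        return self._anc[term]

    def sim(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        hit = self._sim.get(key)
        if hit is not None:
            return hit
        common = self.ancestors(a) & self.ancestors(b)
        ic_mica = max(self.stats[t].ic for t in common)
        denom = max(self.stats[a].ic, self.stats[b].ic)
        val = 1.0 if denom == 0.0 else ic_mica / denom
        self._sim[key] = val
        return val


def write_term_stats(stats: Mapping[str, TermStats], path: str) -> None:
    """Write per-term stats as TSV: term_id, p, ic, n_children."""
    with open(path, "w") as fh:
        fh.write("term_id\tp\tic\tn_children\n")
        for t in sorted(stats):
            s = stats[t]
            fh.write(f"{s.term}\t{s.p:.17g}\t{s.ic:.17g}\t{s.n_children}\n")
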