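"""Annotation stores: gene/disease term annotations, ortholog maps, cross-ontology bridges.

Seven ontology domains are distinguished: the three Gene Ontology namespaces,
the human phenotype ontology, the cross-species phenotype ontology
(UberPheno-like, hosting mouse/fish model phenotypes), the anatomy ontology
and the pathway ontology.  Every annotation records its provenance source, so
directly curated human annotations stay separable from ortholog-derived and
interactome-inferred ones downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd

from .ontology import OntologyGraph, TermSimilarity, TermStats

logger = logging.getLogger(__name__)

__all__ = [
    "Domain",
    "Source",
    "AnnotationSet",
    "AnnotationIndex",
    "DomainRegistry",
    "CrossOntologyBridge",
    "DiseaseEntry",
    "DiseaseCatalog",
    "OrthologMap",
    "AnnotationLoadError",
    "load_annotations",
    "write_annotations",
    "ortholog_annotations",
    "bridge_terms",
    "load_bridge",
    "write_bridge",
    "load_ortholog_map",
    "write_ortholog_map",
    "load_disease_catalog",
    "write_disease_catalog",
]


class Domain(str, Enum):
    GO_BP = "GO_BP"
    GO_MF = "GO_MF"
    GO_CC = "GO_CC"
    HPO = "HPO"
    UBERPHENO = "UBERPHENO"
    UBERON = "UBERON"
    PATHWAY = "PATHWAY"


PHENOTYPE_DOMAINS = (Domain.HPO, Domain.UBERPHENO)


class Source(str, Enum):
    DIRECT_HUMAN = "DIRECT_HUMAN"
    ORTHOLOG_MOUSE = "ORTHOLOG_MOUSE"
    ORTHOLOG_FISH = "ORTHOLOG_FISH"
    INTERACTOME_INFERRED = "INTERACTOME_INFERRED"
    BRIDGE_INFERRED = "BRIDGE_INFERRED"


@dataclass
class AnnotationSet:
    """Terms of one domain annotating one entity, from one provenance source."""

    entity: str
    domain: Domain
    terms: set[str]
    source: Source = Source.DIRECT_HUMAN


class DomainRegistry:
    """Maps each domain to its ontology graph, term stats and similarity engine."""

    def __init__(self) -> None:
        self._graphs: dict[Domain, OntologyGraph] = {}
        self._engines: dict[Domain, TermSimilarity] = {}

    def register(self, domain: Domain, graph: OntologyGraph,
                 stats: Mapping[str, TermStats] | None = None) -> None:
        self._graphs[domain] = graph
        self._engines[domain] = TermSimilarity(graph, stats)

    @property
    def domains(self) -> list[Domain]:
        return list(self._graphs)

    def graph(self, domain: Domain) -> OntologyGraph:
        return self._graphs[domain]

    def engine(self, domain: Domain) -> TermSimilarity:
        return self._engines[domain]

    def resolve(self, term: str) -> Domain | None:
        """Domain whose ontology contains ``term``, or None."""
        for d, g in self._graphs.items():
            if term in g:
                return d
        return None


class AnnotationLoadError(ValueError):
    pass


class AnnotationIndex:
    """Indexed collection of annotation sets, keyed (entity, domain, source)."""

    def __init__(self) -> None:
        self._data: dict[str, dict[Domain, dict[Source, set[str]]]] = {}

    def add(self, ann: AnnotationSet) -> None:
        by_dom = self._data.setdefault(ann.entity, {})
        by_src = by_dom.setdefault(ann.domain, {})
        by_src.setdefault(ann.source, set()).update(ann.terms)

    def entities(self) -> list[str]:
        return sorted(self._data)

    def terms(self, entity: str, domain: Domain,
              sources: Iterable[Source] | None = None) -> set[str]:
        by_src = self._data.get(entity, {}).get(domain, {})
        if sources is None:
            out: set[str] = set()
            for t in by_src.values():
                out |= t
            return out
        out = set()
        for s in sources:
            out |= by_src.get(s, set())
        return out

    def total_count(self, entity: str, sources: Iterable[Source] | None = None) -> int:
        return sum(
            len(self.terms(entity, d, sources)) for d in self._data.get(entity, {})
        )

    def sets(self) -> Iterable[AnnotationSet]:
        for entity in sorted(self._data):
            for domain in sorted(self._data[entity], key=lambda d: d.value):
                for source in sorted(self._data[entity][domain], key=lambda s: s.value):
                    yield AnnotationSet(entity, domain,
                                        set(self._data[entity][domain][source]), source)

    def __len__(self) -> int:
        return sum(1 for _ in self.sets())


def load_annotations(stream: IO[str] | str, registry: DomainRegistry) -> AnnotationIndex:
    """Load an annotation TSV (entity_id, term_id, domain, source).

    Unresolvable terms are skipped with a logged count; annotations to
    obsolete terms are remapped through the ontology's declared replacement
    when one exists.  More than 50% unresolvable rows is a hard error, since
    that almost always means an ontology/annotation version mismatch.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = {"entity_id", "term_id", "domain", "source"}
    if not required.issubset(df.columns):
        raise AnnotationLoadError(f"annotation TSV must have columns {sorted(required)}")
    index = AnnotationIndex()
    n_bad = 0
    n_rows = len(df)
    if n_rows == 0:
        logger.warning("empty annotation file")
        return index
    for row in df.itertuples(index=False):
        try:
            domain = Domain(row.domain)
            source = Source(row.source)
            term = row.term_id
            entity = row.entity_id
            if not isinstance(term, str) or not isinstance(entity, str):
                raise ValueError("malformed row")
        except ValueError:
            n_bad += 1
            continue
        graph = registry.graph(domain) if domain in registry.domains else None
        if graph is None:
            n_bad += 1
            continue
        if term in graph.obsolete:
            replacement = graph.replaced_by.get(term)
            if replacement is None or replacement not in graph:
                n_bad += 1
                continue
            term = replacement
        if term not in graph:
            n_bad += 1
            continue
        index.add(AnnotationSet(entity, domain, {term}, source))
    if n_bad:
        logger.info("skipped %d/%d annotation rows", n_bad, n_rows)
    if n_bad > 0.5 * n_rows:
        raise AnnotationLoadError(
            f"{n_bad}/{n_rows} annotation rows unresolvable; "
            "probable ontology/annotation version mismatch"
        )
    return index


def write_annotations(index: AnnotationIndex, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("entity_id\tterm_id\tdomain\tsource\n")
        for ann in index.sets():
            for term in sorted(ann.terms):
                fh.write(f"{ann.entity}\t{term}\t{ann.domain.value}\t{ann.source.value}\n")


# ---------------------------------------------------------------------------
# Orthologs

@dataclass
class OrthologMap:
    """Many-to-many human gene <-> model-organism gene map."""

    links: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    # human_gene -> [(model_gene, species)], species in {"mouse", "fish"}

    def add(self, human_gene: str, model_gene: str, species: str) -> None:
        self.links.setdefault(human_gene, []).append((model_gene, species))

    def orthologs(self, human_gene: str) -> list[tuple[str, str]]:
        return self.links.get(human_gene, [])


_SPECIES_SOURCE = {"mouse": Source.ORTHOLOG_MOUSE, "fish": Source.ORTHOLOG_FISH}


def ortholog_annotations(
    gene: str, ortholog_map: OrthologMap, model_annotations: AnnotationIndex
) -> list[AnnotationSet]:
    """Model-organism phenotype annotations attributed to a human gene.

    Phenotypes of mouse/fish orthologs (cross-species phenotype domain) are
    carried over with an ``ORTHOLOG_*`` source so they both support sparse
    human annotation and stay separable from it.  No ortholog yields an
    empty list.
    """
    per_species: dict[Source, set[str]] = {}
    for model_gene, species in ortholog_map.orthologs(gene):
        src = _SPECIES_SOURCE.get(species)
        if src is None:
            logger.warning("unknown ortholog species %r for %s", species, gene)
            continue
        terms = model_annotations.terms(model_gene, Domain.UBERPHENO)
        if terms:
            per_species.setdefault(src, set()).update(terms)
    return [
        AnnotationSet(gene, Domain.UBERPHENO, terms, src)
        for src, terms in sorted(per_species.items(), key=lambda kv: kv[0].value)
    ]


def load_ortholog_map(stream: IO[str] | str) -> OrthologMap:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    omap = OrthologMap()
    for row in df.itertuples(index=False):
        omap.add(row.human_gene, row.model_gene, row.species)
    return omap


def write_ortholog_map(omap: OrthologMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("human_gene\tmodel_gene\tspecies\n")
        for hg in sorted(omap.links):
            for mg, sp in omap.links[hg]:
                fh.write(f"{hg}\t{mg}\t{sp}\n")


# ---------------------------------------------------------------------------
# Cross-ontology bridges

class CrossOntologyBridge:
    """Bidirectional term-to-term links across ontology domains.

    A phenotype term can be bridged to, say, a biological-process term, an
    anatomy term, or a pathway term; reasoning across these links lets a
    query phenotype contribute annotations in non-phenotype domains.
    """

    def __init__(self, links: Iterable[tuple[str, str]] = ()) -> None:
        self._targets: dict[str, set[str]] = {}
        self._pairs: set[tuple[str, str]] = set()
        for s, t in links:
            self.add(s, t)

    def add(self, source_term: str, target_term: str) -> None:
        self._pairs.add((source_term, target_term))
        self._targets.setdefault(source_term, set()).add(target_term)
        self._targets.setdefault(target_term, set()).add(source_term)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._pairs)

    def targets(self, term: str) -> set[str]:
        return set(self._targets.get(term, set()))


def bridge_terms(terms: Iterable[str], bridge: CrossOntologyBridge) -> set[str]:
    """All bridge partners of the input terms (monotone in the input set).

    Input terms are not echoed back unless they are themselves a bridge
    target of another input (or self-linked).
    """
    terms = set(terms)
    out: set[str] = set()
    for t in terms:
        out |= bridge.targets(t)
    return out


def load_bridge(stream: IO[str] | str, registry: DomainRegistry | None = None) -> CrossOntologyBridge:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    bridge = CrossOntologyBridge()
    for row in df.itertuples(index=False):
        if registry is not None:
            if registry.resolve(row.source_term) is None or registry.resolve(row.target_term) is None:
                raise AnnotationLoadError(
                    f"bridge endpoint not in any registered ontology: "
                    f"{row.source_term} -> {row.target_term}"
                )
        bridge.add(row.source_term, row.target_term)
    return bridge


def write_bridge(bridge: CrossOntologyBridge, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("source_term\ttarget_term\n")
        for s, t in sorted(bridge.pairs):
            fh.write(f"{s}\t{t}\n")


# ---------------------------------------------------------------------------
# Disease catalog

@dataclass
class DiseaseEntry:
    phenotype_terms: set[str]
    known_genes: set[str]
    disease_type: str = "unknown"


@dataclass
class DiseaseCatalog:
    """File-based stand-in for curated disease-gene / disease-phenotype catalogs."""

    diseases: dict[str, DiseaseEntry] = field(default_factory=dict)

    def __contains__(self, disease: str) -> bool:
        return disease in self.diseases

    def __len__(self) -> int:
        return len(self.diseases)

    def entry(self, disease: str) -> DiseaseEntry:
        return self.diseases[disease]

    def copy(self) -> "DiseaseCatalog":
        return DiseaseCatalog(
            {
                d: DiseaseEntry(set(e.phenotype_terms), set(e.known_genes), e.disease_type)
                for d, e in self.diseases.items()
            }
        )


def load_disease_catalog(stream: IO[str] | str,
                         registry: DomainRegistry | None = None) -> DiseaseCatalog:
    """Load a disease catalog TSV.

    Columns: disease_id, phenotype_terms (comma-separated), known_genes
    (comma-separated, may be empty), disease_type.
    """
    df = pd.read_csv(stream, sep="\t", dtype=str, keep_default_na=False)
    catalog = DiseaseCatalog()
    for row in df.itertuples(index=False):
        phen = {t for t in row.phenotype_terms.split(",") if t}
        if registry is not None:
            bad = [t for t in phen if registry.resolve(t) is None]
            if bad:
                raise AnnotationLoadError(
                    f"disease {row.disease_id}: phenotype terms not in registered "
                    f"ontologies: {sorted(bad)}"
                )
        genes = {g for g in row.known_genes.split(",") if g}
        catalog.diseases[row.disease_id] = DiseaseEntry(phen, genes, row.disease_type)
    return catalog


def write_disease_catalog(catalog: DiseaseCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tphenotype_terms\tknown_genes\tdisease_type\n")
        for d in sorted(catalog.diseases):
            e = catalog.diseases[d]
            fh.write(
                f"{d}\t{','.join(sorted(e.phenotype_terms))}\t"
                f"{','.join(sorted(e.known_genes))}\t{e.disease_type}\n"
            )
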