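"""Query annotation profiles: the multi-domain description of a disease/phenotype query.

Given a set of query phenotype terms, the profile is assembled from three
sources:

1. *Seed genes* — genes already linked to diseases whose phenotype profile is
   semantically similar to the query; their direct annotations populate every
   domain (provenance SEED_GENE).
2. *Cross-ontology bridges* — explicit term-to-term links let a phenotype
   term contribute, e.g., a biological-process, anatomy or pathway term
   directly (provenance BRIDGE).  This is what frees the method from
   requiring user-supplied seed genes for novel diseases.
3. The *query terms* themselves in the phenotype domains (provenance QUERY).

On provenance collisions for the same (domain, term) the precedence is
SEED_GENE > BRIDGE > QUERY.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

from .annotations import (
    AnnotationIndex,
    CrossOntologyBridge,
    DiseaseCatalog,
    Domain,
    DomainRegistry,
    OrthologMap,
    Source,
    bridge_terms,
    ortholog_annotations,
)
from .semsim import bma_similarity

logger = logging.getLogger(__name__)

__all__ = ["Provenance", "DiseaseProfile", "ProfileConfig", "similar_diseases",
           "build_profile", "mask_test_associations"]


class Provenance(str, Enum):
    SEED_GENE = "SEED_GENE"
    BRIDGE = "BRIDGE"
    QUERY = "QUERY"


_PRECEDENCE = {Provenance.SEED_GENE: 0, Provenance.BRIDGE: 1, Provenance.QUERY: 2}


@dataclass
class ProfileConfig:
    """Knobs for profile construction.

    ``k`` and ``min_sim`` bound which phenotypically similar diseases may
    contribute seed genes; both are deliberately permissive defaults since
    the similarity threshold for "similar phenotypes" is a judgement call.
    ``include_ortholog_phenotypes`` routes the model-organism phenotypes of
    seed genes' orthologs into the cross-species phenotype domain.
    """

    k: int = 50
    min_sim: float = 0.3
    include_ortholog_phenotypes: bool = True


@dataclass
class DiseaseProfile:
    query_terms: set[str]
    per_domain: dict[Domain, dict[str, Provenance]] = field(default_factory=dict)
    contributing_diseases: list[tuple[str, float]] = field(default_factory=list)
    seed_genes: set[str] = field(default_factory=set)

    def add(self, domain: Domain, term: str, provenance: Provenance) -> None:
        slot = self.per_domain.setdefault(domain, {})
        old = slot.get(term)
        if old is None or _PRECEDENCE[provenance] < _PRECEDENCE[old]:
            slot[term] = provenance

    def terms(self, domain: Domain) -> set[str]:
        return set(self.per_domain.get(domain, {}))

    def terms_by_domain(self) -> dict[Domain, set[str]]:
        return {d: set(t) for d, t in self.per_domain.items()}


def _group_by_domain(terms: Iterable[str], registry: DomainRegistry) -> dict[Domain, set[str]]:
    grouped: dict[Domain, set[str]] = {}
    unknown = []
    for t in terms:
        d = registry.resolve(t)
        if d is None:
            unknown.append(t)
        else:
            grouped.setdefault(d, set()).add(t)
    if unknown:
        raise ValueError(f"query terms not in any registered ontology: {sorted(unknown)}")
    return grouped


def _phenotype_match(query_by_domain: Mapping[Domain, set[str]],
                     disease_terms: set[str],
                     registry: DomainRegistry) -> float:
    """Phenotype similarity of a disease to the query.

    Computed per phenotype domain with the BMA measure and averaged over the
    query's domains; with a single phenotype ontology this reduces to one
    BMA score.
    """
    scores = []
    for domain, q_terms in query_by_domain.items():
        graph = registry.graph(domain)
        d_terms = {t for t in disease_terms if t in graph}
        sim = bma_similarity(q_terms, d_terms, registry.engine(domain), domain=domain)
        scores.append(sim.score)
    return sum(scores) / len(scores) if scores else 0.0


def similar_diseases(
    query_terms: Iterable[str],
    catalog: DiseaseCatalog,
    registry: DomainRegistry,
    k: int = 50,
    min_sim: float = 0.3,
) -> list[tuple[str, float]]:
    """Diseases whose phenotype profile matches the query, best first.

    Returns (disease_id, similarity) pairs with similarity >= ``min_sim``,
    truncated to the top ``k``; ties are broken lexicographically by id.
    """
    query_by_domain = _group_by_domain(query_terms, registry)
    scored = []
    for disease_id in sorted(catalog.diseases):
        entry = catalog.diseases[disease_id]
        s = _phenotype_match(query_by_domain, entry.phenotype_terms, registry)
        if s >= min_sim:
            scored.append((disease_id, s))
    scored.sort(key=lambda ds: (-ds[1], ds[0]))
    return scored[:k]


def build_profile(
    query_terms: Iterable[str],
    catalog: DiseaseCatalog,
    bridges: CrossOntologyBridge,
    gene_annotations: AnnotationIndex,
    registry: DomainRegistry,
    config: ProfileConfig | None = None,
    ortholog_map: OrthologMap | None = None,
    model_annotations: AnnotationIndex | None = None,
) -> DiseaseProfile:
    """Assemble the multi-domain annotation profile for a query."""
    config = config or ProfileConfig()
    query_terms = set(query_terms)
    if not query_terms:
        raise ValueError("query_terms must be nonempty")
    query_by_domain = _group_by_domain(query_terms, registry)

    profile = DiseaseProfile(query_terms=query_terms)

    # query phenotype terms themselves
    for domain, terms in query_by_domain.items():
        for t in terms:
            profile.add(domain, t, Provenance.QUERY)

    # cross-ontology bridge targets, routed to their domains
    for t in bridge_terms(query_terms, bridges):
        d = registry.resolve(t)
        if d is None:
            logger.warning("bridge target %s not in any registered ontology; skipped", t)
            continue
        profile.add(d, t, Provenance.BRIDGE)

    # seed genes of phenotypically similar diseases
    ranked = similar_diseases(query_terms, catalog, registry,
                              k=config.k, min_sim=config.min_sim)
    profile.contributing_diseases = ranked
    for disease_id, _ in ranked:
        profile.seed_genes |= catalog.diseases[disease_id].known_genes
    for gene in sorted(profile.seed_genes):
        for domain in registry.domains:
            for t in gene_annotations.terms(gene, domain, sources=[Source.DIRECT_HUMAN]):
                profile.add(domain, t, Provenance.SEED_GENE)
        if config.include_ortholog_phenotypes and ortholog_map and model_annotations:
            for ann in ortholog_annotations(gene, ortholog_map, model_annotations):
                for t in ann.terms:
                    profile.add(ann.domain, t, Provenance.SEED_GENE)
    return profile


def mask_test_associations(
    catalog: DiseaseCatalog, gene: str, disease: str, all_diseases: bool = True
) -> DiseaseCatalog:
    """Catalog copy with a gene-disease association hidden.

    Used to simulate novel gene discovery: the held-out gene must not seed
    its own query profile.  With ``all_diseases`` the gene is scrubbed from
    every disease entry, not just the one under test.
    """
    masked = catalog.copy()
    if disease not in masked.diseases or gene not in masked.diseases[disease].known_genes:
        logger.warning("mask_test_associations: %s not a known gene of %s; no-op", gene, disease)
        return masked
    if all_diseases:
        for entry in masked.diseases.values():
            entry.known_genes.discard(gene)
    else:
        masked.diseases[disease].known_genes.discard(gene)
    return masked
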