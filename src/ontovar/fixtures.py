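"""Synthetic desk-scale fixtures: ontologies, annotations, diseases, interactomes, VCFs.

Everything the loaders read can be generated here with known ground truth,
so the whole pipeline is exercisable without downloading any curated
resource.  The generated world emulates the structure the method relies on:

* one random rooted DAG per ontology domain (terms deeper in the DAG are
  more specific);
* diseases annotated with deep phenotype terms and linked to causal genes;
* causal genes whose annotations are drawn, with probability ``signal``,
  from their disease's phenotype terms and per-domain "module" terms (the
  planted biological signal), the rest being background noise;
* cross-ontology bridges from each disease's phenotype terms to its module
  terms in process/anatomy/pathway domains;
* an interactome in which a disease's causal genes form a clique (plus a
  couple of bystanders), embedded in a random background graph;
* mouse/fish orthologs whose model phenotypes echo the disease phenotype;
* multi-sample VCFs with a class/genotype-realistic background and exactly
  one planted causal variant guaranteed to survive the default filters.

With ``signal = 0`` every planted structure is withdrawn (annotations,
bridges and interactome modules are random), so causal genes are
statistically indistinguishable from background — the null world used to
check that ranking performance collapses to chance.

All generation is deterministic under the spec seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .annotations import (
    AnnotationIndex,
    AnnotationSet,
    CrossOntologyBridge,
    DiseaseCatalog,
    DiseaseEntry,
    Domain,
    DomainRegistry,
    OrthologMap,
    Source,
    load_annotations,
    load_bridge,
    load_disease_catalog,
    load_ortholog_map,
    write_annotations,
    write_bridge,
    write_disease_catalog,
    write_ortholog_map,
)
from .interactome import Interactome, load_interactome, write_interactome
from .ontology import OntologyGraph, Relation, compute_term_stats, parse_obo
from .variants import (
    ConsequenceClass,
    DEFAULT_DROP_CLASSES,
    FilterConfig,
    Genotype,
    InheritanceMode,
)

__all__ = ["FixtureSpec", "World", "make_ontology", "write_obo",
           "make_disease_world", "make_vcf", "load_world", "default_filter_config"]


DEFAULT_N_TERMS: dict[Domain, int] = {
    Domain.GO_BP: 60, Domain.GO_MF: 40, Domain.GO_CC: 30, Domain.HPO: 50,
    Domain.UBERPHENO: 70, Domain.UBERON: 40, Domain.PATHWAY: 40,
}

_NS_PREFIX: dict[Domain, str] = {
    Domain.GO_BP: "GB", Domain.GO_MF: "GM", Domain.GO_CC: "GC", Domain.HPO: "HP",
    Domain.UBERPHENO: "UP", Domain.UBERON: "UB", Domain.PATHWAY: "PW",
}

BRIDGED_DOMAINS = (Domain.GO_BP, Domain.UBERON, Domain.PATHWAY)
MODULE_DOMAINS = (Domain.GO_BP, Domain.GO_MF, Domain.GO_CC, Domain.UBERON, Domain.PATHWAY)


@dataclass
class FixtureSpec:
    """Generator parameters; defaults are the desk-scale study conditions."""

    seed: int = 0
    n_terms: dict[Domain, int] = field(default_factory=lambda: dict(DEFAULT_N_TERMS))
    max_depth: int = 6
    part_of_fraction: float = 0.2
    multi_parent_prob: float = 0.15
    n_background_genes: int = 250
    mean_annotations: float = 2.5  # per gene per domain, 1 + Poisson(mean)
    domain_dropout: float = 0.25
    n_diseases: int = 12
    genes_per_disease: int = 3
    phenotype_terms_uberpheno: int = 3
    phenotype_terms_hpo: int = 2
    module_terms_per_domain: int = 3
    signal: float = 0.8
    mean_degree: float = 1.5  # background interactome, per-gene 1 + Poisson
    # VCF layout
    n_variants: int = 100
    n_affected: int = 2
    n_unaffected: int = 1
    planted_class: ConsequenceClass = ConsequenceClass.MISSENSE
    inheritance: InheritanceMode = InheritanceMode.RECESSIVE
    #: background consequence-class mix: benign / missense / other damaging
    class_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)


def make_ontology(
    namespace: str,
    n_terms: int,
    seed: int | np.random.Generator = 0,
    max_depth: int = 6,
    part_of_fraction: float = 0.2,
    multi_parent_prob: float = 0.15,
) -> OntologyGraph:
    """Random rooted DAG; term i's parents always have smaller index (acyclic)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"{namespace}:{i:07d}" for i in range(n_terms)]
    g = OntologyGraph(namespace=namespace, root=ids[0])
    g.dag.add_node(ids[0])
    depth = {0: 0}
    for i in range(1, n_terms):
        eligible = [j for j in range(i) if depth[j] < max_depth]
        parent = int(rng.choice(eligible))
        rel = Relation.PART_OF if rng.random() < part_of_fraction else Relation.IS_A
        g.dag.add_edge(ids[i], ids[parent], key=rel.value)
        depth[i] = depth[parent] + 1
        if i > 1 and rng.random() < multi_parent_prob:
            others = [j for j in eligible if j != parent]
            if others:
                p2 = int(rng.choice(others))
                rel2 = Relation.PART_OF if rng.random() < part_of_fraction else Relation.IS_A
                g.dag.add_edge(ids[i], ids[p2], key=rel2.value)
                depth[i] = max(depth[i], depth[p2] + 1)
    g.validate()
    return g


def write_obo(graph: OntologyGraph, path: str, namespace: str | None = None) -> None:
    """Emit the graph as OBO 1.2 text that :func:`~ontovar.ontology.parse_obo` round-trips."""
    ns = namespace or graph.namespace
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"ontology: {ns}\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {ns}\n")
            for parent, rel in sorted(graph.parents(term)):
                if rel is Relation.IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
        for term in sorted(graph.obsolete):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {ns}\nis_obsolete: true\n")
            if term in graph.replaced_by:
                fh.write(f"replaced_by: {graph.replaced_by[term]}\n")


@dataclass
class World:
    """A generated study world plus its ground-truth manifest."""

    spec: FixtureSpec
    registry: DomainRegistry
    annotations: AnnotationIndex          # direct human gene annotations
    model_annotations: AnnotationIndex    # model-organism gene phenotypes
    ortholog_map: OrthologMap
    bridges: CrossOntologyBridge
    catalog: DiseaseCatalog
    interactome: Interactome
    genes: list[str]
    disease_type_codes: dict[str, int]
    manifest: dict

    def causal_pairs(self) -> list[tuple[str, str]]:
        return [
            (d, g)
            for d in sorted(self.catalog.diseases)
            for g in sorted(self.catalog.diseases[d].known_genes)
        ]

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for domain in self.registry.domains:
            write_obo(self.registry.graph(domain), os.path.join(outdir, f"{domain.value}.obo"))
        write_annotations(self.annotations, os.path.join(outdir, "annotations.tsv"))
        write_annotations(self.model_annotations, os.path.join(outdir, "model_annotations.tsv"))
        write_ortholog_map(self.ortholog_map, os.path.join(outdir, "orthologs.tsv"))
        write_bridge(self.bridges, os.path.join(outdir, "bridges.tsv"))
        write_disease_catalog(self.catalog, os.path.join(outdir, "catalog.tsv"))
        write_interactome(self.interactome, os.path.join(outdir, "interactome.tsv"))
        spec_dict = asdict(self.spec)
        spec_dict["n_terms"] = {d.value: n for d, n in self.spec.n_terms.items()}
        spec_dict["planted_class"] = self.spec.planted_class.value
        spec_dict["inheritance"] = self.spec.inheritance.value
        with open(os.path.join(outdir, "fixture_spec.json"), "w") as fh:
            json.dump(spec_dict, fh, indent=1)
        with open(os.path.join(outdir, "manifest.jsonl"), "w") as fh:
            for key in sorted(self.manifest):
                fh.write(json.dumps({"key": key, "value": self.manifest[key]}) + "\n")


def _deep_terms(graph: OntologyGraph, quantile: float = 0.6) -> list[str]:
    """Terms in the most-informative tail of the ontology (specific terms)."""
    stats = compute_term_stats(graph)
    ics = np.array([stats[t].ic for t in sorted(stats)])
    cutoff = float(np.quantile(ics, quantile))
    return [t for t in sorted(stats) if stats[t].ic >= cutoff]


def _sample_terms(pool: list[str], n: int, rng: np.random.Generator) -> set[str]:
    n = min(n, len(pool))
    return set(rng.choice(pool, size=n, replace=False))


def make_disease_world(spec: FixtureSpec | None = None) -> World:
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    registry = DomainRegistry()
    deep: dict[Domain, list[str]] = {}
    all_terms: dict[Domain, list[str]] = {}
    for domain in DEFAULT_N_TERMS:
        n = spec.n_terms.get(domain, DEFAULT_N_TERMS[domain])
        graph = make_ontology(
            _NS_PREFIX[domain], n, rng, spec.max_depth,
            spec.part_of_fraction, spec.multi_parent_prob,
        )
        registry.register(domain, graph)
        deep[domain] = _deep_terms(graph)
        all_terms[domain] = sorted(graph.terms - {graph.root})

    n_causal = spec.n_diseases * spec.genes_per_disease
    genes = [f"GENE{i:04d}" for i in range(spec.n_background_genes + n_causal)]
    causal_genes = list(rng.choice(genes, size=n_causal, replace=False))

    signal = spec.signal
    catalog = DiseaseCatalog()
    bridges = CrossOntologyBridge()
    modules: dict[str, dict[Domain, set[str]]] = {}
    phenos: dict[str, dict[Domain, set[str]]] = {}
    gene_disease: dict[str, str] = {}
    disease_types = ["recessive", "dominant"]
    for i in range(spec.n_diseases):
        disease = f"DIS{i:03d}"
        p_up = _sample_terms(deep[Domain.UBERPHENO], spec.phenotype_terms_uberpheno, rng)
        p_hp = _sample_terms(deep[Domain.HPO], spec.phenotype_terms_hpo, rng)
        phenos[disease] = {Domain.UBERPHENO: p_up, Domain.HPO: p_hp}
        modules[disease] = {
            d: _sample_terms(deep[d], spec.module_terms_per_domain, rng)
            for d in MODULE_DOMAINS
        }
        dgenes = set(causal_genes[i * spec.genes_per_disease:(i + 1) * spec.genes_per_disease])
        for g in dgenes:
            gene_disease[g] = disease
        catalog.diseases[disease] = DiseaseEntry(
            p_up | p_hp, dgenes, disease_types[int(rng.integers(len(disease_types)))]
        )
        # bridges: each cross-species phenotype term to one module term per bridged domain
        for t in sorted(p_up):
            for d in BRIDGED_DOMAINS:
                if signal > 0:
                    target = str(rng.choice(sorted(modules[disease][d])))
                else:
                    target = str(rng.choice(all_terms[d]))
                bridges.add(t, target)

    annotations = AnnotationIndex()
    for gene in genes:
        disease = gene_disease.get(gene)
        for domain in DEFAULT_N_TERMS:
            if rng.random() < spec.domain_dropout:
                continue
            n_ann = 1 + int(rng.poisson(spec.mean_annotations))
            pool: list[str] = []
            if disease is not None and signal > 0:
                if domain in (Domain.UBERPHENO, Domain.HPO):
                    pool = sorted(phenos[disease][domain])
                elif domain in MODULE_DOMAINS:
                    pool = sorted(modules[disease][domain])
            terms = set()
            for _ in range(n_ann):
                if pool and rng.random() < signal:
                    terms.add(str(rng.choice(pool)))
                else:
                    terms.add(str(rng.choice(all_terms[domain])))
            annotations.add(AnnotationSet(gene, domain, terms, Source.DIRECT_HUMAN))

    # interactome: random background plus per-disease causal cliques
    edges: set[tuple[str, str]] = set()
    for gene in genes:
        k = 1 + int(rng.poisson(spec.mean_degree))
        for partner in rng.choice(genes, size=k, replace=False):
            partner = str(partner)
            if partner != gene:
                edges.add(tuple(sorted((gene, partner))))
    if signal > 0:
        for disease in sorted(catalog.diseases):
            dgenes = sorted(catalog.diseases[disease].known_genes)
            for a in dgenes:
                for b in dgenes:
                    if a < b:
                        edges.add((a, b))
            bystanders = rng.choice(genes, size=2, replace=False)
            for bys in bystanders:
                bys = str(bys)
                if bys not in dgenes:
                    edges.add(tuple(sorted((bys, dgenes[int(rng.integers(len(dgenes)))]))))
    interactome = Interactome.from_edges(sorted(edges))

    # orthologs with model phenotypes
    ortholog_map = OrthologMap()
    model_annotations = AnnotationIndex()
    # ortholog presence is independent of causality: only the *content* of the
    # model phenotypes carries signal, never the existence of an ortholog
    for gene in genes:
        disease = gene_disease.get(gene)
        for species, prefix, p_has in (("mouse", "MMU_", 0.5), ("fish", "DRE_", 0.25)):
            if rng.random() >= p_has:
                continue
            model_gene = prefix + gene
            ortholog_map.add(gene, model_gene, species)
            if disease is not None and signal > 0:
                pool = sorted(phenos[disease][Domain.UBERPHENO])
            else:
                pool = all_terms[Domain.UBERPHENO]
            n_ann = 2 + int(rng.integers(3))
            terms = {str(t) for t in rng.choice(pool, size=min(n_ann, len(pool)), replace=False)}
            model_annotations.add(
                AnnotationSet(model_gene, Domain.UBERPHENO, terms, Source.DIRECT_HUMAN)
            )

    manifest = {
        "seed": spec.seed,
        "signal": signal,
        "diseases": {
            d: {
                "genes": sorted(catalog.diseases[d].known_genes),
                "phenotype_terms": sorted(catalog.diseases[d].phenotype_terms),
                "disease_type": catalog.diseases[d].disease_type,
            }
            for d in sorted(catalog.diseases)
        },
    }
    return World(
        spec=spec, registry=registry, annotations=annotations,
        model_annotations=model_annotations, ortholog_map=ortholog_map,
        bridges=bridges, catalog=catalog, interactome=interactome, genes=genes,
        disease_type_codes={t: i for i, t in enumerate(disease_types)},
        manifest=manifest,
    )


def load_world(indir: str) -> World:
    """Reload a written world through the ordinary file loaders."""
    with open(os.path.join(indir, "fixture_spec.json")) as fh:
        raw = json.load(fh)
    raw["n_terms"] = {Domain(k): v for k, v in raw["n_terms"].items()}
    raw["planted_class"] = ConsequenceClass(raw["planted_class"])
    raw["inheritance"] = InheritanceMode(raw["inheritance"])
    raw["class_mix"] = tuple(raw["class_mix"])
    spec = FixtureSpec(**raw)
    registry = DomainRegistry()
    for domain in DEFAULT_N_TERMS:
        path = os.path.join(indir, f"{domain.value}.obo")
        registry.register(domain, parse_obo(path))
    annotations = load_annotations(os.path.join(indir, "annotations.tsv"), registry)
    model_annotations = load_annotations(os.path.join(indir, "model_annotations.tsv"), registry)
    ortholog_map = load_ortholog_map(os.path.join(indir, "orthologs.tsv"))
    bridges = load_bridge(os.path.join(indir, "bridges.tsv"), registry)
    catalog = load_disease_catalog(os.path.join(indir, "catalog.tsv"), registry)
    interactome = load_interactome(os.path.join(indir, "interactome.tsv"))
    manifest: dict = {}
    with open(os.path.join(indir, "manifest.jsonl")) as fh:
        for line in fh:
            row = json.loads(line)
            manifest[row["key"]] = row["value"]
    genes = sorted(
        set(annotations.entities())
        | {g for d in catalog.diseases.values() for g in d.known_genes}
    )
    disease_types = sorted({d.disease_type for d in catalog.diseases.values()})
    return World(
        spec=spec, registry=registry, annotations=annotations,
        model_annotations=model_annotations, ortholog_map=ortholog_map,
        bridges=bridges, catalog=catalog, interactome=interactome, genes=genes,
        disease_type_codes={t: i for i, t in enumerate(disease_types)},
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# VCF generation

_BASES = np.array(list("ACGT"))
_BENIGN = (ConsequenceClass.SYNONYMOUS, ConsequenceClass.INTRONIC, ConsequenceClass.UTR)
_DAMAGING_OTHER = (ConsequenceClass.NONSENSE, ConsequenceClass.FRAMESHIFT,
                   ConsequenceClass.SPLICE)


def default_filter_config(affected: list[str], unaffected: list[str],
                          inheritance: InheritanceMode = InheritanceMode.RECESSIVE,
                          ) -> FilterConfig:
    """Default filter cascade: benign classes out, qual >= 20, AF <= 0.01, inheritance."""
    return FilterConfig(
        drop_classes=DEFAULT_DROP_CLASSES,
        min_qual=20.0,
        max_af=0.01,
        inheritance_mode=inheritance,
        affected=affected,
        unaffected=unaffected,
    )


def _gt_string(gt: Genotype, rng: np.random.Generator) -> str:
    return {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1",
            Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}[gt]


def make_vcf(
    spec: FixtureSpec,
    world: World,
    path: str,
    planted_gene: str | None = None,
    seed: int | None = None,
) -> dict:
    """Write a multi-sample VCF with one planted causal variant.

    The background mixes consequence classes (benign / missense / other
    damaging per ``spec.class_mix``), random genotypes, occasional low
    quality and non-rare allele frequencies, so every filter stage has work
    to do.  The planted variant sits in ``planted_gene`` (default: the first
    causal gene of the first disease), is damaging in class, high quality,
    AF-absent, and carries the inheritance-consistent genotype layout --
    by construction it survives :func:`default_filter_config`.  Background
    variants avoid the planted gene so no spurious compound-het in an
    unaffected sample can mask it.

    Returns the truth record (planted gene/position/samples).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if planted_gene is None:
        first = sorted(world.catalog.diseases)[0]
        planted_gene = sorted(world.catalog.diseases[first].known_genes)[0]
    affected = [f"AFF{i+1}" for i in range(spec.n_affected)]
    unaffected = [f"UNAFF{i+1}" for i in range(spec.n_unaffected)]
    samples = affected + unaffected

    chroms = [f"chr{i}" for i in range(1, 6)]
    used: set[tuple[str, int]] = set()

    def fresh_site() -> tuple[str, int]:
        while True:
            site = (str(rng.choice(chroms)), int(rng.integers(1, 1_000_000)))
            if site not in used:
                used.add(site)
                return site

    bg_genes = [g for g in world.genes if g != planted_gene]
    p_benign, p_mis, p_other = spec.class_mix
    rows = []
    for i in range(spec.n_variants):
        chrom, pos = fresh_site()
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        gene = str(rng.choice(bg_genes))
        u = rng.random()
        if u < p_benign:
            cls = _BENIGN[int(rng.integers(len(_BENIGN)))]
        elif u < p_benign + p_mis:
            cls = ConsequenceClass.MISSENSE
        else:
            cls = _DAMAGING_OTHER[int(rng.integers(len(_DAMAGING_OTHER)))]
        csq = [f"{alt}|{gene}|{gene}_tx1|{cls.value}"]
        if rng.random() < 0.15:  # transcript plurality: second, benign transcript
            csq.append(f"{alt}|{gene}|{gene}_tx2|{ConsequenceClass.SYNONYMOUS.value}")
        qual = 8.0 + 52.0 * rng.random() if rng.random() < 0.1 else 20.0 + 40.0 * rng.random()
        info = f"CSQ={','.join(csq)}"
        if rng.random() < 0.5:
            info += f";AF={rng.random() * 0.2:.4f}"
        gts = [
            _gt_string(
                [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT][
                    int(rng.choice(3, p=[0.6, 0.3, 0.1]))
                ],
                rng,
            )
            for _ in samples
        ]
        rows.append((chrom, pos, ref, alt, qual, info, gts))

    chrom, pos = fresh_site()
    ref = str(rng.choice(_BASES))
    alt = str(rng.choice([b for b in _BASES if b != ref]))
    csq = f"CSQ={alt}|{planted_gene}|{planted_gene}_tx1|{spec.planted_class.value}"
    if spec.inheritance is InheritanceMode.DOMINANT:
        gts = ["0/1"] * len(affected) + ["0/0"] * len(unaffected)
    else:
        gts = ["1/1"] * len(affected) + ["0/1"] * len(unaffected)
    rows.append((chrom, pos, ref, alt, 55.0, csq, gts))

    order = sorted(range(len(rows)), key=lambda i: (rows[i][0], rows[i][1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length=1000000>\n")
        fh.write('##INFO=<ID=CSQ,Number=.,Type=String,Description="ALT|GENE|TRANSCRIPT|CLASS">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in order:
            c, p, r, a, q, info, gts = rows[i]
            fh.write(f"{c}\t{p}\t.\t{r}\t{a}\t{q:.1f}\t.\t{info}\tGT\t" + "\t".join(gts) + "\n")

    return {
        "planted_gene": planted_gene,
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "affected": affected,
        "unaffected": unaffected,
        "n_records": len(rows),
    }
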