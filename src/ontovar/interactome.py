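"""Protein-protein interaction neighborhoods and annotation enrichment.

Interacting proteins tend to participate in the same processes, so a poorly
annotated candidate gene can borrow the annotations of its direct interaction
partners.  To keep noise down, only terms *over-represented* in the
neighborhood relative to the whole-interactome background are transferred:
a one-sided Fisher's exact test per term, Bonferroni-corrected over the terms
tested for that neighborhood, retaining corrected P < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotations import AnnotationIndex, Domain, Source

__all__ = [
    "Interactome",
    "EnrichmentResult",
    "load_interactome",
    "write_interactome",
    "neighborhood",
    "enrich_neighborhood",
    "fisher_greater_p",
    "interactome_proximity",
    "PROXIMITY_MAX",
]


def fisher_greater_p(k_in, n_in, k_out, n_out):
    """One-sided (greater) Fisher's exact P for a 2x2 over-representation table.

    Equals the upper hypergeometric tail P(X >= k_in) with population
    ``n_in + n_out``, ``k_in + k_out`` successes and ``n_in`` draws.
    Vectorizes over array inputs.
    """
    return hypergeom.sf(np.asarray(k_in) - 1, np.asarray(n_in) + np.asarray(n_out),
                        np.asarray(k_in) + np.asarray(k_out), np.asarray(n_in))

#: sentinel proximity for genes disconnected from (or absent with) the seeds
PROXIMITY_MAX = 10


@dataclass
class Interactome:
    """Undirected PPI graph; self-loops and duplicate edges are rejected."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "Interactome":
        g = nx.Graph()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


def load_interactome(stream: IO[str] | str) -> Interactome:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    return Interactome.from_edges(zip(df["gene_a"], df["gene_b"]))


def write_interactome(interactome: Interactome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in interactome.graph.edges):
            fh.write(f"{a}\t{b}\n")


def neighborhood(gene: str, interactome: Interactome) -> set[str]:
    """Genes sharing a direct interaction with ``gene`` (gene itself excluded)."""
    if gene not in interactome:
        return set()
    return set(interactome.graph.neighbors(gene))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    domain: Domain
    k_neigh: int
    n_neigh: int
    k_bg: int
    n_bg: int
    p_raw: float
    p_corrected: float
    retained: bool


def enrich_neighborhood(
    neigh: set[str],
    annotations: AnnotationIndex,
    interactome: Interactome,
    alpha: float = 0.01,
    domains: Iterable[Domain] | None = None,
    include_neigh_in_background: bool = False,
) -> list[EnrichmentResult]:
    """Terms over-represented in an interactome neighborhood.

    For every (domain, term) annotating at least one neighborhood gene, a
    2x2 table is built -- annotated/not x inside/outside the neighborhood,
    the outside column being the rest of the interactome -- and tested with
    a one-sided (greater) Fisher's exact test.  Bonferroni correction runs
    over the m terms actually tested for this neighborhood; only those with
    corrected P < ``alpha`` are flagged retained.

    Results are sorted by (domain, term), independent of iteration order.
    """
    if not neigh:
        return []
    background = interactome.nodes
    if not neigh <= background:
        raise ValueError("neighborhood contains genes absent from the interactome")
    outside = background if include_neigh_in_background else background - neigh
    n_neigh = len(neigh)
    n_out = len(outside)

    domains = list(domains) if domains is not None else list(Domain)
    # term -> set of annotated genes, restricted to direct annotations
    counts: dict[tuple[Domain, str], tuple[int, int]] = {}
    for domain in domains:
        term_genes: dict[str, set[str]] = {}
        for gene in background:
            for t in annotations.terms(gene, domain, sources=[Source.DIRECT_HUMAN]):
                term_genes.setdefault(t, set()).add(gene)
        for t, genes in term_genes.items():
            k_neigh = len(genes & neigh)
            if k_neigh == 0:
                continue
            counts[(domain, t)] = (k_neigh, len(genes & outside))

    m = len(counts)
    ordered = sorted(counts, key=lambda dt: (dt[0].value, dt[1]))
    k_n = np.array([counts[dt][0] for dt in ordered])
    k_o = np.array([counts[dt][1] for dt in ordered])
    p_raws = fisher_greater_p(k_n, n_neigh, k_o, n_out) if m else []
    results = []
    for (domain, term), kn, ko, p_raw in zip(ordered, k_n, k_o, p_raws):
        p_corr = min(1.0, float(p_raw) * m)
        results.append(
            EnrichmentResult(term, domain, int(kn), n_neigh, int(ko), n_out,
                             float(p_raw), p_corr, p_corr < alpha)
        )
    return results


def write_enrichment(results: list[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("term\tdomain\tk_neigh\tn_neigh\tk_bg\tn_bg\tp_raw\tp_corrected\tretained\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.domain.value}\t{r.k_neigh}\t{r.n_neigh}\t{r.k_bg}\t"
                f"{r.n_bg}\t{r.p_raw:.6g}\t{r.p_corrected:.6g}\t{int(r.retained)}\n"
            )


def interactome_proximity(gene: str, seed_genes: set[str], interactome: Interactome) -> int:
    """Shortest-path distance from ``gene`` to the nearest seed gene.

    0 if the gene is itself a seed; :data:`PROXIMITY_MAX` if unreachable or
    either side is absent from the interactome.
    """
    if gene in seed_genes:
        return 0
    if gene not in interactome or not seed_genes:
        return PROXIMITY_MAX
    lengths = nx.single_source_shortest_path_length(
        interactome.graph, gene, cutoff=PROXIMITY_MAX - 1
    )
    dists = [d for g, d in lengths.items() if g in seed_genes]
    return min(dists) if dists else PROXIMITY_MAX
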