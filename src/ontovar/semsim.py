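"""Entity-level semantic similarity: the IC-adjusted best-match-average (BMA).

Gene and disease entities are annotated with sets of terms, so a set-level
aggregate of pairwise term similarities is needed.  The best-match-average
matches every term on one side with its best-scoring partner on the other
side, averages each direction, and averages the two directions.

Plain BMA is biased by shallow annotations: a term always matches itself with
similarity 1, so two otherwise unrelated genes sharing an uninformative
high-level term (the classic 'protein binding' case) get an undeserved boost.
Exact matches are therefore adjusted by the matched term's information
content: a self-match of term ``t`` contributes ``min(1, IC_t / ic_cap)``
instead of 1, where ``ic_cap`` defaults to the 95th-percentile IC of the
domain ontology.  Deep exact matches still contribute ~1; shallow ones are
discounted in proportion to how little they say.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .annotations import Domain, DomainRegistry
from .ontology import TermSimilarity

__all__ = ["EntitySimilarity", "default_ic_cap", "bma_similarity", "profile_similarity",
           "DomainMismatchError"]


class DomainMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class EntitySimilarity:
    """One entity-vs-entity similarity score within a single ontology domain.

    ``n_terms_a``/``n_terms_b`` record the annotation counts behind the score
    so that a gene with no annotations in a domain (score 0, count 0) stays
    distinguishable from a well-annotated gene that genuinely scores low.
    ``support`` sums the ICs of the best-match MICAs backing the score.
    """

    domain: Domain | None
    score: float
    n_terms_a: int
    n_terms_b: int
    mean_ic_a: float
    support: float


IC_CAP_PERCENTILE = 95.0


def default_ic_cap(engine: TermSimilarity) -> float:
    """95th-percentile IC over the domain's terms, memoized on the engine."""
    cap = getattr(engine, "_default_ic_cap", None)
    if cap is None:
        ics = np.array([s.ic for s in engine.stats.values()])
        cap = float(np.percentile(ics, IC_CAP_PERCENTILE))
        cap = cap if cap > 0 else 1.0
        engine._default_ic_cap = cap
    return cap


def _check_domain(terms: Iterable[str], engine: TermSimilarity) -> None:
    missing = [t for t in terms if t not in engine.graph]
    if missing:
        raise DomainMismatchError(
            f"terms not in this domain's ontology (mixed domains?): {sorted(missing)[:10]}"
        )


def _pair_score(a: str, b: str, engine: TermSimilarity, ic_cap: float) -> float:
    if a == b:
        return min(1.0, engine.ic(a) / ic_cap)
    return engine.sim(a, b)


def bma_similarity(
    A: Iterable[str],
    B: Iterable[str],
    engine: TermSimilarity,
    ic_cap: float | None = None,
    domain: Domain | None = None,
) -> EntitySimilarity:
    """IC-adjusted best-match-average similarity between two term sets.

    Symmetric in (A, B).  Either side empty gives score 0 with the emptiness
    recorded in the count fields.  All terms must live in the engine's
    ontology; mixed-domain input is a hard error.
    """
    A, B = sorted(set(A)), sorted(set(B))
    _check_domain(A, engine)
    _check_domain(B, engine)
    if ic_cap is None:
        ic_cap = default_ic_cap(engine)
    if ic_cap <= 0:
        raise ValueError("ic_cap must be positive")
    mean_ic_a = float(np.mean([engine.ic(a) for a in A])) if A else 0.0
    if not A or not B:
        return EntitySimilarity(domain, 0.0, len(A), len(B), mean_ic_a, 0.0)

    support = 0.0
    best_a = []
    for a in A:
        scores = [_pair_score(a, b, engine, ic_cap) for b in B]
        i = int(np.argmax(scores))
        best_a.append(scores[i])
        support += min(engine.ic(a), engine.ic(B[i]))
    best_b = []
    for b in B:
        scores = [_pair_score(a, b, engine, ic_cap) for a in A]
        i = int(np.argmax(scores))
        best_b.append(scores[i])
        support += min(engine.ic(b), engine.ic(A[i]))
    score = (float(np.mean(best_a)) + float(np.mean(best_b))) / 2.0
    return EntitySimilarity(domain, score, len(A), len(B), mean_ic_a, support)


def profile_similarity(
    gene_terms_by_domain: Mapping[Domain, Iterable[str]],
    profile_terms_by_domain: Mapping[Domain, Iterable[str]],
    registry: DomainRegistry,
    ic_caps: Mapping[Domain, float] | None = None,
) -> dict[Domain, EntitySimilarity]:
    """Per-domain BMA similarity of a gene's annotations against a query profile.

    Every registered domain yields one score; a domain where the gene (or the
    profile) has no terms scores 0 with a zero count, which downstream feature
    construction treats differently from a genuine low score.
    """
    out: dict[Domain, EntitySimilarity] = {}
    for domain in registry.domains:
        engine = registry.engine(domain)
        cap = ic_caps.get(domain) if ic_caps else None
        out[domain] = bma_similarity(
            gene_terms_by_domain.get(domain, ()),
            profile_terms_by_domain.get(domain, ()),
            engine,
            ic_cap=cap,
            domain=domain,
        )
    return out
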