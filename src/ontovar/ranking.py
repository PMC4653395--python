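"""Candidate gene scoring and ranking.

Each candidate gene is summarized as a fixed 32-entry feature vector against
the query profile:

* per-domain direct similarity scores (7),
* per-domain direct annotation counts (7),
* per-domain mean IC of direct annotations (7) -- the "informativeness"
  behind each score,
* per-domain similarity of interactome-neighborhood *enriched* annotations
  to the profile (7),
* ortholog phenotype similarity, mouse and fish (2),
* shortest-path proximity in the interactome to the profile's seed genes (1),
* disease type as an integer category code (1).

Domains where the gene has no annotations are encoded as score 0 with count
0, which is distinct from a genuinely low score on real annotations; features
that cannot be computed at all (no interactome node, no ortholog) use the
sentinel ``UNKNOWN``.

Three ranking schemes are provided: the unweighted average of the seven
direct domain scores; a weighted average that upweights phenotype domains
and drops unannotated domains from the denominator; and a random-forest
posterior.  The forest (600 trees, 6 features per split) is trained on
disease genes vs. matched random genes, then cleaned by removing instances
misclassified under 10-fold cross-validation and refit; the posterior of a
candidate is the fraction of trees voting for the disease-gene class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .annotations import AnnotationIndex, Domain, DomainRegistry, OrthologMap, Source
from .interactome import (
    Interactome,
    PROXIMITY_MAX,
    enrich_neighborhood,
    interactome_proximity,
    neighborhood,
)
from .profile import DiseaseProfile
from .semsim import bma_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "UNKNOWN",
    "DOMAIN_ORDER",
    "FEATURE_LAYOUT_VERSION",
    "feature_names",
    "ScoringContext",
    "extract_features",
    "score_average",
    "score_weighted_average",
    "DEFAULT_DOMAIN_WEIGHTS",
    "TrainingInstance",
    "RFConfig",
    "RankingModel",
    "build_training_set",
    "train_model",
    "posterior",
    "CandidateScore",
    "rank_candidates",
    "save_model",
    "load_model",
]

#: sentinel for features that cannot be computed for a gene
UNKNOWN = -1.0

DOMAIN_ORDER: tuple[Domain, ...] = (
    Domain.GO_BP, Domain.GO_MF, Domain.GO_CC, Domain.HPO,
    Domain.UBERPHENO, Domain.UBERON, Domain.PATHWAY,
)

PHENOTYPE_LINK_DOMAINS = (Domain.HPO, Domain.UBERPHENO)

FEATURE_LAYOUT_VERSION = "ontovar-32f-v1"


def feature_names() -> list[str]:
    names: list[str] = []
    for d in DOMAIN_ORDER:
        names.append(f"sim_{d.value}")
    for d in DOMAIN_ORDER:
        names.append(f"n_{d.value}")
    for d in DOMAIN_ORDER:
        names.append(f"mean_ic_{d.value}")
    for d in DOMAIN_ORDER:
        names.append(f"neigh_sim_{d.value}")
    names += ["ortholog_sim_mouse", "ortholog_sim_fish",
              "interactome_proximity", "disease_type"]
    assert len(names) == 32
    return names


_IDX = {name: i for i, name in enumerate(feature_names())}


@dataclass
class ScoringContext:
    """Everything needed to turn (gene, profile) into a feature vector."""

    registry: DomainRegistry
    annotations: AnnotationIndex
    interactome: Interactome
    ortholog_map: OrthologMap | None = None
    model_annotations: AnnotationIndex | None = None
    disease_type_codes: dict[str, int] = field(default_factory=dict)
    enrichment_alpha: float = 0.01
    _enriched_cache: dict[str, dict[Domain, set[str]]] = field(default_factory=dict)

    def disease_type_code(self, label: str) -> float:
        if label not in self.disease_type_codes:
            return UNKNOWN
        return float(self.disease_type_codes[label])

    def enriched_terms(self, gene: str) -> dict[Domain, set[str]]:
        """Neighborhood-enriched terms per domain, cached per gene."""
        if gene not in self._enriched_cache:
            terms: dict[Domain, set[str]] = {}
            neigh = neighborhood(gene, self.interactome)
            if neigh:
                for r in enrich_neighborhood(
                    neigh, self.annotations, self.interactome, alpha=self.enrichment_alpha
                ):
                    if r.retained:
                        terms.setdefault(r.domain, set()).add(r.term)
            self._enriched_cache[gene] = terms
        return self._enriched_cache[gene]


def extract_features(
    gene: str,
    profile: DiseaseProfile,
    ctx: ScoringContext,
    disease_type: str = "unknown",
    mask_phenotype_link: bool = False,
) -> np.ndarray:
    """32-entry feature vector for one candidate gene against one profile.

    Deterministic given its inputs.  With ``mask_phenotype_link`` the
    human-phenotype features that would directly tie the gene to the query
    disease (phenotype-domain similarities/counts/ICs and the ortholog
    phenotype similarities) are replaced by the unknown sentinel, for
    novel-gene simulation on catalogs whose gene phenotype annotations derive
    from the very associations being tested.
    """
    x = np.zeros(32)
    profile_terms = profile.terms_by_domain()

    any_annotation = False
    for d in DOMAIN_ORDER:
        gene_terms = ctx.annotations.terms(gene, d, sources=[Source.DIRECT_HUMAN])
        any_annotation = any_annotation or bool(gene_terms)
        sim = bma_similarity(gene_terms, profile_terms.get(d, set()),
                             ctx.registry.engine(d), domain=d)
        x[_IDX[f"sim_{d.value}"]] = sim.score
        x[_IDX[f"n_{d.value}"]] = sim.n_terms_a
        x[_IDX[f"mean_ic_{d.value}"]] = sim.mean_ic_a

    if gene in ctx.interactome:
        enriched = ctx.enriched_terms(gene)
        for d in DOMAIN_ORDER:
            sim = bma_similarity(enriched.get(d, set()), profile_terms.get(d, set()),
                                 ctx.registry.engine(d), domain=d)
            x[_IDX[f"neigh_sim_{d.value}"]] = sim.score
        x[_IDX["interactome_proximity"]] = interactome_proximity(
            gene, profile.seed_genes, ctx.interactome
        )
    else:
        for d in DOMAIN_ORDER:
            x[_IDX[f"neigh_sim_{d.value}"]] = UNKNOWN
        x[_IDX["interactome_proximity"]] = PROXIMITY_MAX

    for species, feat in (("mouse", "ortholog_sim_mouse"), ("fish", "ortholog_sim_fish")):
        x[_IDX[feat]] = UNKNOWN
        if ctx.ortholog_map is not None and ctx.model_annotations is not None:
            terms: set[str] = set()
            for model_gene, sp in ctx.ortholog_map.orthologs(gene):
                if sp == species:
                    terms |= ctx.model_annotations.terms(model_gene, Domain.UBERPHENO)
            if terms:
                sim = bma_similarity(
                    terms, profile_terms.get(Domain.UBERPHENO, set()),
                    ctx.registry.engine(Domain.UBERPHENO), domain=Domain.UBERPHENO,
                )
                x[_IDX[feat]] = sim.score

    x[_IDX["disease_type"]] = ctx.disease_type_code(disease_type)

    if mask_phenotype_link:
        for d in PHENOTYPE_LINK_DOMAINS:
            x[_IDX[f"sim_{d.value}"]] = UNKNOWN
            x[_IDX[f"n_{d.value}"]] = UNKNOWN
            x[_IDX[f"mean_ic_{d.value}"]] = UNKNOWN
        x[_IDX["ortholog_sim_mouse"]] = UNKNOWN
        x[_IDX["ortholog_sim_fish"]] = UNKNOWN

    if not any_annotation:
        logger.warning("gene %s absent from all annotation sources", gene)
    return x


# ---------------------------------------------------------------------------
# Aggregate scoring schemes

def score_average(features: np.ndarray) -> float:
    """Unweighted mean of the seven direct per-domain similarity scores."""
    sims = np.array([features[_IDX[f"sim_{d.value}"]] for d in DOMAIN_ORDER])
    sims = np.where(sims == UNKNOWN, 0.0, sims)
    return float(np.mean(sims))


#: phenotype-domain-heavy default weights: a matching (model-organism)
#: phenotype is a much stronger predictor than, e.g., cellular localization
DEFAULT_DOMAIN_WEIGHTS: dict[Domain, float] = {
    Domain.GO_BP: 1.0, Domain.GO_MF: 1.0, Domain.GO_CC: 1.0,
    Domain.HPO: 2.0, Domain.UBERPHENO: 2.0, Domain.UBERON: 1.0, Domain.PATHWAY: 1.0,
}


def score_weighted_average(
    features: np.ndarray, weights: Mapping[Domain, float] | None = None
) -> float:
    """Weighted mean of direct domain scores over *annotated* domains only.

    A domain where the gene has no annotations (count 0) is dropped from both
    numerator and denominator -- the dynamic adjustment that stops missing
    annotation from masquerading as evidence of dissimilarity.  Returns 0
    when no domain is annotated.
    """
    weights = dict(weights or DEFAULT_DOMAIN_WEIGHTS)
    if all(w == 0 for w in weights.values()):
        raise ValueError("all domain weights are zero")
    num = den = 0.0
    for d in DOMAIN_ORDER:
        n = features[_IDX[f"n_{d.value}"]]
        s = features[_IDX[f"sim_{d.value}"]]
        if n <= 0 or s == UNKNOWN:
            continue
        w = weights.get(d, 1.0)
        num += w * s
        den += w
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Random-forest training

@dataclass
class TrainingInstance:
    features: np.ndarray
    label: int  # 1 = disease gene, 0 = non-disease gene
    gene: str = ""
    disease: str = ""


@dataclass
class RFConfig:
    n_trees: int = 600
    features_per_split: int = 6
    cv_folds: int = 10
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.features_per_split >= 32:
            raise ValueError("features_per_split must be < 32")


@dataclass
class RankingModel:
    forest: RandomForestClassifier
    config: RFConfig
    layout_version: str = FEATURE_LAYOUT_VERSION
    n_instances_pre: int = 0
    n_instances_post: int = 0
    removed_indices: list[int] = field(default_factory=list)


def _annotation_strata(counts: Sequence[int], n_strata: int = 5) -> np.ndarray:
    """Quintile stratum index per gene by total annotation count."""
    counts = np.asarray(counts, dtype=float)
    edges = np.quantile(counts, np.linspace(0, 1, n_strata + 1)[1:-1])
    return np.searchsorted(edges, counts, side="right")


def build_training_set(
    catalog_diseases: Mapping[str, tuple[set[str], str]],
    profile_fn: Callable[[str, str], DiseaseProfile],
    feature_fn: Callable[[str, DiseaseProfile, str], np.ndarray],
    gene_pool: Sequence[str],
    pool_annotation_counts: Sequence[int],
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> list[TrainingInstance]:
    """Disease-gene vs. matched-random-gene training instances.

    ``catalog_diseases`` maps disease id -> (known genes, disease type); a
    ``fraction`` of diseases (two-thirds by default) is drawn at random.  For
    every known gene of a selected disease one positive instance is built --
    features against the disease profile with the gene's own association
    masked (``profile_fn`` receives (disease, masked gene)) -- plus one
    negative from a random pool gene matched to the positive by total
    annotation-count quintile, so the model cannot simply learn annotation
    richness.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    disease_ids = sorted(catalog_diseases)
    n_sel = max(1, int(round(fraction * len(disease_ids))))
    selected = sorted(rng.choice(disease_ids, size=n_sel, replace=False))

    gene_pool = list(gene_pool)
    strata = _annotation_strata(pool_annotation_counts)
    by_stratum: dict[int, list[str]] = {}
    stratum_of: dict[str, int] = {}
    for g, s in zip(gene_pool, strata):
        by_stratum.setdefault(int(s), []).append(g)
        stratum_of[g] = int(s)

    instances: list[TrainingInstance] = []
    for disease in selected:
        known_genes, dtype = catalog_diseases[disease]
        for gene in sorted(known_genes):
            prof = profile_fn(disease, gene)
            instances.append(
                TrainingInstance(feature_fn(gene, prof, dtype), 1, gene, disease)
            )
            target = stratum_of.get(gene, int(np.median(list(by_stratum))))
            negative = _draw_matched_negative(target, by_stratum, known_genes | {gene}, rng)
            instances.append(
                TrainingInstance(feature_fn(negative, prof, dtype), 0, negative, disease)
            )
    return instances


def _draw_matched_negative(
    target: int,
    by_stratum: Mapping[int, list[str]],
    exclude: set[str],
    rng: np.random.Generator,
) -> str:
    for dist in range(max(by_stratum) + 1):
        for s in (target - dist, target + dist):
            pool = [g for g in by_stratum.get(s, []) if g not in exclude]
            if pool:
                if dist > 0:
                    logger.warning("empty stratum %d, fell back to %d", target, s)
                return str(rng.choice(sorted(pool)))
    raise ValueError("no eligible negative gene in any stratum")


def _make_forest(config: RFConfig) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        random_state=config.random_seed,
        n_jobs=1,
    )


def train_model(instances: Sequence[TrainingInstance], config: RFConfig | None = None) -> RankingModel:
    """Fit, clean by cross-validated misclassification, and refit.

    Step 1 fits the forest on all instances; step 2 runs stratified 10-fold
    cross-validation with the same configuration and drops every instance
    misclassified in its held-out fold (likely label outliers); step 3 refits
    on the cleaned set.  A class emptied by cleaning is a hard error.
    """
    config = config or RFConfig()
    X = np.vstack([inst.features for inst in instances])
    y = np.array([inst.label for inst in instances])
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 instances per class")

    forest = _make_forest(config)
    forest.fit(X, y)

    n_folds = min(config.cv_folds, int(min(np.bincount(y))))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.random_seed)
    y_hat = cross_val_predict(clone(forest), X, y, cv=cv)
    keep = y_hat == y
    removed = [int(i) for i in np.flatnonzero(~keep)]
    if removed:
        logger.info("CV cleaning removed %d/%d instances", len(removed), len(y))
    y_clean = y[keep]
    if len(np.unique(y_clean)) < 2:
        raise ValueError("a class was emptied by CV cleaning; degenerate training set")

    final = _make_forest(config)
    final.fit(X[keep], y_clean)
    return RankingModel(
        forest=final, config=config,
        n_instances_pre=len(y), n_instances_post=int(keep.sum()),
        removed_indices=removed,
    )


def posterior_batch(model: RankingModel, X: np.ndarray) -> np.ndarray:
    """Per-row fraction of trees voting for the disease-gene class."""
    X = np.asarray(X, dtype=float)
    votes = np.zeros(len(X))
    for tree in model.forest.estimators_:
        votes += tree.predict(X) == 1
    return votes / len(model.forest.estimators_)


def posterior(model: RankingModel, features: np.ndarray) -> float:
    """Fraction of trees voting for the disease-gene class (multiple of 1/n_trees)."""
    x = np.asarray(features, dtype=float).reshape(1, -1)
    return float(posterior_batch(model, x)[0])


# ---------------------------------------------------------------------------
# Ranking

@dataclass
class CandidateScore:
    gene: str
    features: np.ndarray
    score_avg: float
    score_wavg: float
    posterior: float | None
    rank: int = 0

    def score(self, scheme: str) -> float:
        if scheme == "avg":
            return self.score_avg
        if scheme == "wavg":
            return self.score_wavg
        if scheme == "rf":
            if self.posterior is None:
                raise ValueError("no model posterior available")
            return self.posterior
        raise ValueError(f"unknown scheme {scheme!r}")


def rank_candidates(
    genes: Iterable[str],
    profile: DiseaseProfile,
    ctx: ScoringContext,
    scheme: str = "rf",
    model: RankingModel | None = None,
    disease_type: str = "unknown",
    weights: Mapping[Domain, float] | None = None,
    mask_phenotype_link: bool = False,
    precomputed: Mapping[str, np.ndarray] | None = None,
) -> list[CandidateScore]:
    """Score and rank candidate genes, best first.

    Ranks are a permutation of 1..n, descending in the selected scheme's
    score with deterministic lexicographic tie-break on gene id.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValueError("no candidate genes to rank")
    scored = []
    for gene in genes:
        if precomputed is not None and gene in precomputed:
            x = precomputed[gene]
        else:
            x = extract_features(gene, profile, ctx, disease_type, mask_phenotype_link)
        scored.append(
            CandidateScore(
                gene=gene,
                features=x,
                score_avg=score_average(x),
                score_wavg=score_weighted_average(x, weights),
                posterior=posterior(model, x) if model is not None else None,
            )
        )
    scored.sort(key=lambda c: (-c.score(scheme), c.gene))
    for i, c in enumerate(scored, start=1):
        c.rank = i
    return scored


def write_ranking(scored: list[CandidateScore], path: str) -> None:
    with open(path, "w") as fh:
        sim_cols = "\t".join(f"sim_{d.value}" for d in DOMAIN_ORDER)
        fh.write(f"rank\tgene\tposterior\tscore_avg\tscore_wavg\t{sim_cols}\n")
        for c in scored:
            sims = "\t".join(
                f"{c.features[_IDX[f'sim_{d.value}']]:.4f}" for d in DOMAIN_ORDER
            )
            post = "" if c.posterior is None else f"{c.posterior:.6f}"
            fh.write(f"{c.rank}\t{c.gene}\t{post}\t{c.score_avg:.6f}\t{c.score_wavg:.6f}\t{sims}\n")


# ---------------------------------------------------------------------------
# Serialization

def save_model(model: RankingModel, path: str) -> None:
    joblib.dump(
        {
            "format": "ontovar-model-v1",
            "layout_version": model.layout_version,
            "feature_names": feature_names(),
            "rf_config": model.config,
            "n_instances_pre": model.n_instances_pre,
            "n_instances_post": model.n_instances_post,
            "removed_indices": model.removed_indices,
            "forest": model.forest,
        },
        path,
    )


def load_model(path: str) -> RankingModel:
    blob = joblib.load(path)
    if blob.get("layout_version") != FEATURE_LAYOUT_VERSION:
        raise ValueError(
            f"model layout {blob.get('layout_version')!r} does not match "
            f"{FEATURE_LAYOUT_VERSION!r}"
        )
    return RankingModel(
        forest=blob["forest"],
        config=blob["rf_config"],
        layout_version=blob["layout_version"],
        n_instances_pre=blob["n_instances_pre"],
        n_instances_post=blob["n_instances_post"],
        removed_indices=blob["removed_indices"],
    )
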