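"""Ranking evaluation: held-out disease genes vs. random decoys, AUC and rank buckets.

The benchmark protocol simulates novel gene discovery: for each (disease,
causal gene) test pair, every association of that gene is masked from the
catalog, the query profile is rebuilt from what remains, and the true gene
is ranked together with 200 randomly drawn decoy genes that carry at least
minimal Gene Ontology annotation (entirely unannotated decoys would make the
task artificially easy).

Per replicate the quality measure is the fraction of decoys the true gene
outscores (ties count half) -- the Mann-Whitney statistic, identical to the
area under the ROC curve for that replicate's 1-vs-200 scoring.  Replicate
fractions are averaged into the reported AUC, and the true gene's ranks are
summarized into first/top-10/top-25/top-100 buckets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotations import Domain, Source
from .fixtures import World
from .profile import DiseaseProfile, ProfileConfig, build_profile, mask_test_associations
from .ranking import (
    CandidateScore,
    RankingModel,
    RFConfig,
    ScoringContext,
    build_training_set,
    extract_features,
    posterior,
    posterior_batch,
    score_average,
    score_weighted_average,
    train_model,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationResult",
    "evaluate_ranking",
    "replicate_auc",
    "rank_buckets",
    "make_context",
    "split_diseases",
    "train_on_world",
    "run_benchmark",
    "run_paired_benchmark",
]

GO_DOMAINS = (Domain.GO_BP, Domain.GO_MF, Domain.GO_CC)


@dataclass
class EvaluationResult:
    replicates: int
    auc: float
    rank_buckets: dict[str, int]
    ranks: list[int] = field(default_factory=list)
    per_replicate_auc: list[float] = field(default_factory=list)
    truth_genes: list[str] = field(default_factory=list)

    def gene_level_auc(self) -> dict[str, float]:
        """Mean replicate AUC per distinct truth gene (the clustering unit)."""
        sums: dict[str, list[float]] = {}
        for g, f in zip(self.truth_genes, self.per_replicate_auc):
            sums.setdefault(g, []).append(f)
        return {g: float(np.mean(v)) for g, v in sums.items()}

    def auc_confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Normal-theory CI for the AUC, clustered by truth gene.

        Replicates sharing a truth gene are strongly correlated (only the
        decoy draw changes), so the distinct truth genes are the effective
        sample; treating raw replicates as independent would understate the
        uncertainty badly.
        """
        from scipy import stats as _st

        vals = np.array(list(self.gene_level_auc().values()))
        if len(vals) < 2:
            return (0.0, 1.0)
        z = _st.norm.ppf(0.5 + level / 2)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        m = float(vals.mean())
        return (m - z * se, m + z * se)


def replicate_auc(truth_score: float, decoy_scores: Sequence[float]) -> float:
    """Fraction of decoys the truth outscores, ties counting one half."""
    decoys = np.asarray(decoy_scores, dtype=float)
    if decoys.size == 0:
        raise ValueError("no decoy scores")
    return float((np.sum(truth_score > decoys) + 0.5 * np.sum(truth_score == decoys))
                 / decoys.size)


def evaluate_ranking(
    truth: str, ranked: Sequence[CandidateScore], scheme: str = "rf"
) -> tuple[int, float]:
    """The truth gene's rank and its decoy-beating fraction for one replicate."""
    by_gene = {c.gene: c for c in ranked}
    if truth not in by_gene:
        raise ValueError(f"truth gene {truth!r} absent from ranking")
    t = by_gene[truth]
    decoys = [c.score(scheme) for c in ranked if c.gene != truth]
    return t.rank, replicate_auc(t.score(scheme), decoys)


_BUCKETS = (("first", 1), ("top10", 10), ("top25", 25), ("top100", 100))


def rank_buckets(ranks: Iterable[int]) -> dict[str, int]:
    """Cumulative rank buckets plus the leftover 'beyond' count.

    first <= top10 <= top25 <= top100, and top100 + beyond == replicates.
    """
    ranks = list(ranks)
    out = {name: sum(1 for r in ranks if r <= cut) for name, cut in _BUCKETS}
    out["beyond"] = len(ranks) - out["top100"]
    return out


# ---------------------------------------------------------------------------
# World-level benchmark machinery

def make_context(world: World) -> ScoringContext:
    return ScoringContext(
        registry=world.registry,
        annotations=world.annotations,
        interactome=world.interactome,
        ortholog_map=world.ortholog_map,
        model_annotations=world.model_annotations,
        disease_type_codes=world.disease_type_codes,
    )


def decoy_pool(world: World) -> list[str]:
    """Genes with at least one Gene Ontology annotation (any GO domain)."""
    return [
        g for g in world.genes
        if any(world.annotations.terms(g, d, sources=[Source.DIRECT_HUMAN])
               for d in GO_DOMAINS)
    ]


def split_diseases(world: World, fraction: float = 2.0 / 3.0,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Deterministic train/test split of the disease catalog."""
    rng = np.random.default_rng(seed)
    ids = sorted(world.catalog.diseases)
    n_train = max(1, int(round(fraction * len(ids))))
    train = sorted(rng.choice(ids, size=n_train, replace=False))
    test = [d for d in ids if d not in set(train)]
    return train, test


class _ProfileCache:
    def __init__(self, world: World, config: ProfileConfig | None = None):
        self.world = world
        self.config = config or ProfileConfig()
        self._profiles: dict[tuple[str, str], DiseaseProfile] = {}
        self._features: dict[tuple[str, str, str], np.ndarray] = {}
        self.ctx = make_context(world)

    def profile(self, disease: str, masked_gene: str) -> DiseaseProfile:
        key = (disease, masked_gene)
        if key not in self._profiles:
            catalog = mask_test_associations(self.world.catalog, masked_gene, disease)
            query = self.world.catalog.diseases[disease].phenotype_terms
            self._profiles[key] = build_profile(
                query, catalog, self.world.bridges, self.world.annotations,
                self.world.registry, self.config,
                ortholog_map=self.world.ortholog_map,
                model_annotations=self.world.model_annotations,
            )
        return self._profiles[key]

    def features(self, disease: str, masked_gene: str, gene: str) -> np.ndarray:
        key = (disease, masked_gene, gene)
        if key not in self._features:
            dtype = self.world.catalog.diseases[disease].disease_type
            self._features[key] = extract_features(
                gene, self.profile(disease, masked_gene), self.ctx, disease_type=dtype
            )
        return self._features[key]


def train_on_world(
    world: World,
    train_diseases: Sequence[str],
    rf_config: RFConfig | None = None,
    cache: "_ProfileCache | None" = None,
) -> RankingModel:
    """Train the random-forest ranker on a subset of the world's diseases."""
    cache = cache or _ProfileCache(world)
    rf_config = rf_config or RFConfig()
    pool = decoy_pool(world)
    counts = [world.annotations.total_count(g, sources=[Source.DIRECT_HUMAN]) for g in pool]
    catalog_diseases = {
        d: (set(world.catalog.diseases[d].known_genes), world.catalog.diseases[d].disease_type)
        for d in train_diseases
    }

    key_of: dict[int, tuple[str, str]] = {}

    def profile_fn(disease: str, masked_gene: str) -> DiseaseProfile:
        prof = cache.profile(disease, masked_gene)
        key_of[id(prof)] = (disease, masked_gene)
        return prof

    def feature_fn(gene: str, prof: DiseaseProfile, _dtype: str) -> np.ndarray:
        disease, masked_gene = key_of[id(prof)]
        return cache.features(disease, masked_gene, gene)

    instances = build_training_set(
        catalog_diseases,
        profile_fn=profile_fn,
        feature_fn=feature_fn,
        gene_pool=pool,
        pool_annotation_counts=counts,
        fraction=1.0,  # the train/test split already happened at disease level
        seed=rf_config.random_seed,
    )
    return train_model(instances, rf_config)


def run_paired_benchmark(
    world: World,
    n_replicates: int,
    seed: int = 0,
    schemes: Sequence[str] = ("avg", "wavg", "rf"),
    model: RankingModel | None = None,
    test_diseases: Sequence[str] | None = None,
    n_decoys: int = 200,
    profile_config: ProfileConfig | None = None,
    pair_order: str = "random",
    cache: "_ProfileCache | None" = None,
) -> dict[str, EvaluationResult]:
    """Benchmark several scoring schemes on identical replicates.

    Each replicate takes one (disease, causal gene) test pair and one decoy
    set, shared across schemes, so scheme comparisons are paired.  With
    ``pair_order="random"`` pairs are drawn with replacement; with
    ``"cycle"`` they are visited round-robin, which guarantees every truth
    gene appears equally often (the truth gene is the natural clustering
    unit of the replicate fractions).  With fewer than ``n_decoys`` eligible
    decoys all available ones are used with a warning.  Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    cache = cache or _ProfileCache(world, profile_config)
    if "rf" in schemes and model is None:
        raise ValueError("scheme 'rf' requires a trained model")

    pool = decoy_pool(world)
    pool_set = set(pool)
    # truth genes must meet the same minimal-annotation eligibility as decoys,
    # otherwise the comparison is biased against (or for) the truth
    pairs = [
        (d, g) for d, g in world.causal_pairs()
        if (test_diseases is None or d in set(test_diseases)) and g in pool_set
    ]
    if not pairs:
        raise ValueError("no eligible (disease, gene) test pairs")

    ranks: dict[str, list[int]] = {s: [] for s in schemes}
    fracs: dict[str, list[float]] = {s: [] for s in schemes}
    # scores depend only on (disease, masked truth, gene, scheme); cache across replicates
    score_cache: dict[tuple[str, str], dict[str, dict[str, float]]] = {}
    truth_genes: list[str] = []
    for rep in range(n_replicates):
        if pair_order == "cycle":
            disease, truth = pairs[rep % len(pairs)]
        else:
            disease, truth = pairs[int(rng.integers(len(pairs)))]
        truth_genes.append(truth)
        known = world.catalog.diseases[disease].known_genes
        eligible = [g for g in pool if g != truth and g not in known]
        k = min(n_decoys, len(eligible))
        if k < n_decoys:
            logger.warning("only %d eligible decoys (wanted %d); using all", k, n_decoys)
        decoys = [str(g) for g in rng.choice(eligible, size=k, replace=False)]

        pair_scores = score_cache.setdefault((disease, truth), {s: {} for s in schemes})
        genes = [truth] + decoys
        missing = [g for g in genes if g not in pair_scores[schemes[0]]]
        if missing:
            feats = {g: cache.features(disease, truth, g) for g in missing}
            for scheme in schemes:
                if scheme == "rf":
                    votes = posterior_batch(model, np.vstack([feats[g] for g in missing]))
                    for g, v in zip(missing, votes):
                        pair_scores[scheme][g] = float(v)
                else:
                    for g in missing:
                        pair_scores[scheme][g] = _scheme_score(scheme, feats[g], model)
        for scheme in schemes:
            scores = pair_scores[scheme]
            t = scores[truth]
            rank = 1 + sum(
                1 for g in decoys if scores[g] > t or (scores[g] == t and g < truth)
            )
            ranks[scheme].append(rank)
            fracs[scheme].append(replicate_auc(t, [scores[g] for g in decoys]))

    return {
        s: EvaluationResult(
            replicates=n_replicates,
            auc=float(np.mean(fracs[s])),
            rank_buckets=rank_buckets(ranks[s]),
            ranks=ranks[s],
            per_replicate_auc=fracs[s],
            truth_genes=list(truth_genes),
        )
        for s in schemes
    }


def _scheme_score(scheme: str, x: np.ndarray, model: RankingModel | None) -> float:
    if scheme == "avg":
        return score_average(x)
    if scheme == "wavg":
        return score_weighted_average(x)
    if scheme == "rf":
        assert model is not None
        return posterior(model, x)
    raise ValueError(f"unknown scheme {scheme!r}")


def run_benchmark(
    world: World,
    n_replicates: int,
    seed: int = 0,
    scheme: str = "avg",
    model: RankingModel | None = None,
    **kwargs,
) -> EvaluationResult:
    """Single-scheme convenience wrapper around :func:`run_paired_benchmark`."""
    return run_paired_benchmark(
        world, n_replicates, seed=seed, schemes=(scheme,), model=model, **kwargs
    )[scheme]
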