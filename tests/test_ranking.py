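"""Feature extraction, scoring schemes and the random-forest training protocol."""

import numpy as np
import pytest

from ontovar.annotations import Domain
from ontovar.evaluate import _ProfileCache, decoy_pool
from ontovar.interactome import PROXIMITY_MAX
from ontovar.ranking import (
    DEFAULT_DOMAIN_WEIGHTS,
    DOMAIN_ORDER,
    RFConfig,
    TrainingInstance,
    UNKNOWN,
    build_training_set,
    extract_features,
    feature_names,
    load_model,
    posterior,
    posterior_batch,
    rank_candidates,
    save_model,
    score_average,
    score_weighted_average,
    train_model,
)

IDX = {n: i for i, n in enumerate(feature_names())}


def vec(**kwargs):
    x = np.zeros(32)
    for k, v in kwargs.items():
        x[IDX[k]] = v
    return x


class TestScoreAverage:
    def test_all_zero(self):
        assert score_average(vec()) == 0.0

    def test_all_one(self):
        x = vec(**{f"sim_{d.value}": 1.0 for d in DOMAIN_ORDER})
        assert score_average(x) == pytest.approx(1.0)

    def test_single_domain_one_seventh(self):
        assert score_average(vec(sim_GO_BP=1.0)) == pytest.approx(1 / 7)


class TestScoreWeightedAverage:
    def test_single_annotated_domain_returns_its_score(self):
        x = vec(sim_HPO=0.6, n_HPO=3)
        assert score_weighted_average(x) == pytest.approx(0.6)

    def test_two_domains_weighted_two_to_one(self):
        x = vec(sim_HPO=1.0, n_HPO=2, sim_GO_BP=0.0, n_GO_BP=1)
        # HPO weight 2, GO_BP weight 1 under the defaults
        assert score_weighted_average(x) == pytest.approx(2 / 3)

    def test_unannotated_domain_does_not_dilute(self):
        annotated = vec(sim_HPO=0.8, n_HPO=2, sim_GO_BP=0.4, n_GO_BP=1)
        with_zero_count = annotated.copy()
        with_zero_count[IDX["sim_PATHWAY"]] = 0.0   # zero-count domain, score 0
        assert score_weighted_average(with_zero_count) == pytest.approx(
            score_weighted_average(annotated)
        )
        # including it in the denominator would give a strictly smaller value
        w = DEFAULT_DOMAIN_WEIGHTS
        diluted = (w[Domain.HPO] * 0.8 + w[Domain.GO_BP] * 0.4) / (
            w[Domain.HPO] + w[Domain.GO_BP] + w[Domain.PATHWAY]
        )
        assert score_weighted_average(with_zero_count) > diluted

    def test_no_annotations_returns_zero(self):
        assert score_weighted_average(vec()) == 0.0

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            score_weighted_average(vec(sim_HPO=1, n_HPO=1), {d: 0.0 for d in DOMAIN_ORDER})

    def test_schemes_coincide_when_uniform_and_fully_annotated(self):
        rng = np.random.default_rng(0)
        sims = rng.random(7)
        x = vec(**{f"sim_{d.value}": s for d, s in zip(DOMAIN_ORDER, sims)},
                **{f"n_{d.value}": 2 for d in DOMAIN_ORDER})
        uniform = {d: 1.0 for d in DOMAIN_ORDER}
        assert score_weighted_average(x, uniform) == pytest.approx(score_average(x))


def separable_instances(n=40, flip=None, seed=0):
    """Two well-separated classes in 32-d; optionally flip one label."""
    rng = np.random.default_rng(seed)
    instances = []
    for i in range(n):
        label = i % 2
        x = rng.normal(loc=3.0 * label, scale=0.3, size=32)
        instances.append(TrainingInstance(x, label, gene=f"G{i}"))
    if flip is not None:
        instances[flip].label = 1 - instances[flip].label
    return instances


class TestTrainingProtocol:
    def test_separable_set_keeps_everything(self):
        model = train_model(separable_instances(), RFConfig(random_seed=0))
        assert model.n_instances_pre == 40
        assert model.n_instances_post == 40
        assert model.removed_indices == []

    def test_flipped_label_removed_by_cv_cleaning(self):
        model = train_model(separable_instances(flip=7), RFConfig(random_seed=0))
        assert model.removed_indices == [7]
        assert model.n_instances_post == 39

    def test_posterior_is_vote_fraction(self):
        model = train_model(separable_instances(), RFConfig(random_seed=0))
        probe = np.full(32, 1.5)
        p = posterior(model, probe)
        assert 0.0 <= p <= 1.0
        assert (p * 600) == pytest.approx(round(p * 600), abs=1e-9)

    def test_extreme_probes_saturate(self):
        model = train_model(separable_instances(), RFConfig(random_seed=0))
        assert posterior(model, np.full(32, 3.0)) == 1.0
        assert posterior(model, np.zeros(32)) == 0.0

    def test_fixed_seed_reproducible(self):
        m1 = train_model(separable_instances(flip=3), RFConfig(random_seed=42))
        m2 = train_model(separable_instances(flip=3), RFConfig(random_seed=42))
        probes = np.random.default_rng(1).normal(1.5, 1.0, size=(20, 32))
        assert np.array_equal(posterior_batch(m1, probes), posterior_batch(m2, probes))

    def test_batch_matches_single(self):
        model = train_model(separable_instances(), RFConfig(random_seed=0))
        probes = np.random.default_rng(2).normal(1.5, 1.0, size=(5, 32))
        batch = posterior_batch(model, probes)
        for i in range(5):
            assert batch[i] == pytest.approx(posterior(model, probes[i]))

    def test_degenerate_class_rejected(self):
        inst = [TrainingInstance(np.zeros(32), 1) for _ in range(4)]
        with pytest.raises(ValueError, match="per class"):
            train_model(inst, RFConfig())

    def test_round_trip_serialization(self, tmp_path):
        model = train_model(separable_instances(flip=3), RFConfig(random_seed=1))
        path = tmp_path / "model.joblib"
        save_model(model, str(path))
        back = load_model(str(path))
        probes = np.random.default_rng(3).normal(1.5, 1.0, size=(10, 32))
        assert np.array_equal(posterior_batch(model, probes), posterior_batch(back, probes))
        assert back.removed_indices == model.removed_indices


class TestBuildTrainingSet:
    def _setup(self):
        diseases = {f"D{i}": ({f"P{i}a", f"P{i}b"}, "recessive") for i in range(3)}
        pool = [f"N{i}" for i in range(50)] + [g for gs, _ in diseases.values() for g in gs]
        counts = list(range(len(pool)))
        profiles = {}

        def profile_fn(d, g):
            key = (d, g)
            profiles.setdefault(key, object())
            return profiles[key]

        def feature_fn(gene, prof, dtype):
            return np.zeros(32)

        return diseases, pool, counts, profile_fn, feature_fn

    def test_counting_and_balance(self):
        diseases, pool, counts, pf, ff = self._setup()
        inst = build_training_set(diseases, pf, ff, pool, counts, fraction=2 / 3, seed=0)
        # 2 of 3 diseases, 2 genes each, one matched negative per positive
        assert len(inst) == 8
        assert sum(i.label for i in inst) == 4

    def test_determinism_under_seed(self):
        diseases, pool, counts, pf, ff = self._setup()
        a = build_training_set(diseases, pf, ff, pool, counts, seed=5)
        b = build_training_set(diseases, pf, ff, pool, counts, seed=5)
        assert [(i.gene, i.disease, i.label) for i in a] == \
               [(i.gene, i.disease, i.label) for i in b]

    def test_negatives_never_known_genes(self):
        diseases, pool, counts, pf, ff = self._setup()
        inst = build_training_set(diseases, pf, ff, pool, counts, fraction=1.0, seed=1)
        for i in inst:
            if i.label == 0:
                assert i.gene not in diseases[i.disease][0]


@pytest.fixture(scope="module")
def cache(world):
    return _ProfileCache(world)


class TestExtractFeatures:
    def test_seed_gene_has_zero_proximity(self, world, cache):
        disease = sorted(world.catalog.diseases)[0]
        genes = sorted(world.catalog.diseases[disease].known_genes)
        # mask one gene; another known gene of the same disease stays a seed
        x = cache.features(disease, genes[0], genes[1])
        assert x[IDX["interactome_proximity"]] == 0.0

    def test_gene_without_interactome_node_gets_sentinels(self, world, cache):
        prof = cache.profile(sorted(world.catalog.diseases)[0], "GENE0000")
        x = extract_features("NOT_A_GENE", prof, cache.ctx)
        assert x[IDX["interactome_proximity"]] == PROXIMITY_MAX
        for d in DOMAIN_ORDER:
            assert x[IDX[f"neigh_sim_{d.value}"]] == UNKNOWN

    def test_phenotype_link_masking(self, world, cache):
        disease = sorted(world.catalog.diseases)[0]
        gene = sorted(world.catalog.diseases[disease].known_genes)[0]
        prof = cache.profile(disease, gene)
        x = extract_features(gene, prof, cache.ctx, mask_phenotype_link=True)
        for d in (Domain.HPO, Domain.UBERPHENO):
            assert x[IDX[f"sim_{d.value}"]] == UNKNOWN
            assert x[IDX[f"n_{d.value}"]] == UNKNOWN
        assert x[IDX["ortholog_sim_mouse"]] == UNKNOWN

    def test_deterministic(self, world, cache):
        disease = sorted(world.catalog.diseases)[0]
        gene = "GENE0005"
        prof = cache.profile(disease, "GENE0000")
        a = extract_features(gene, prof, cache.ctx)
        b = extract_features(gene, prof, cache.ctx)
        assert np.array_equal(a, b)


class TestRankCandidates:
    def test_posterior_ordering(self, world):
        cache = _ProfileCache(world)
        disease = sorted(world.catalog.diseases)[0]
        truth = sorted(world.catalog.diseases[disease].known_genes)[0]
        prof = cache.profile(disease, truth)
        genes = [truth] + decoy_pool(world)[:20]
        ranked = rank_candidates(genes, prof, cache.ctx, scheme="wavg")
        assert sorted(c.rank for c in ranked) == list(range(1, len(ranked) + 1))
        scores = [c.score("wavg") for c in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_tie_break_lexicographic(self, world):
        cache = _ProfileCache(world)
        disease = sorted(world.catalog.diseases)[0]
        prof = cache.profile(disease, "GENE0000")
        # two genes absent from every source score identically (all zero)
        ranked = rank_candidates(["ZZZ_B", "ZZZ_A"], prof, cache.ctx, scheme="avg")
        assert [c.gene for c in ranked] == ["ZZZ_A", "ZZZ_B"]

    def test_rank_improves_when_annotations_copied_from_profile(self, world):
        # paired run: the same probe gene ranks strictly better once its
        # annotations are copied from the profile (deepest terms per domain)
        cache = _ProfileCache(world)
        disease = sorted(world.catalog.diseases)[0]
        truth = sorted(world.catalog.diseases[disease].known_genes)[0]
        prof = cache.profile(disease, truth)
        from ontovar.annotations import AnnotationSet, Source

        probe = "PROBE_GENE"
        genes = [probe] + decoy_pool(world)[:50]

        def rank_of_probe():
            ranked = rank_candidates(genes, prof, cache.ctx, scheme="wavg")
            return [c.rank for c in ranked if c.gene == probe][0]

        bare_rank = rank_of_probe()
        try:
            for domain in DOMAIN_ORDER:
                terms = prof.terms(domain)
                if terms:
                    engine = world.registry.engine(domain)
                    deepest = sorted(terms, key=lambda t: -engine.ic(t))[:6]
                    world.annotations.add(
                        AnnotationSet(probe, domain, set(deepest), Source.DIRECT_HUMAN)
                    )
            annotated_rank = rank_of_probe()
        finally:
            world.annotations._data.pop(probe, None)
        assert annotated_rank < bare_rank
        assert annotated_rank <= 10
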