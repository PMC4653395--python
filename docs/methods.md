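# Methods

`ontovar` prioritizes candidate disease genes from exome variant calls by
combining classic variant filtering with knowledge-based scoring against a
multi-ontology description of the query phenotype. This note documents the
model, its parameters and defaults, the synthetic data the tests run on, and
the design decisions taken where several readings were defensible.

## Ontologies and intrinsic information content

Each ontology domain (the three Gene Ontology namespaces, human phenotype,
cross-species phenotype, anatomy, pathway) is a rooted DAG of terms with
child-to-parent edges typed `is_a` or `part_of`; every other relationship
type is dropped at parse time with a logged count. Obsolete terms are
excluded from the graph but remembered together with their declared
replacement so annotation loading can remap them. If a namespace declares
several roots, a virtual root is inserted above them so the recursion below
has a unique base case. OBO has no explicit root marker, so a parentless
term with at least one child (or the sole term of its namespace) is treated
as a declared root; parentless, childless terms are reported as orphans and
excluded.

A term's probability of occurrence is derived from graph topology rather
than from an annotation corpus (corpus-based IC inherits curation bias and
drifts as the corpus evolves):

    P(root) = 1
    P(t)    = min over parent edges (t --rel--> a) of  (P(a) / C(a)) * w_rel

with `C(a)` the number of direct children of `a` (counted over retained edge
types) and edge weights `w_is_a = 0.2`, `w_part_of = 0.4`. Information
content is `IC(t) = -ln P(t)` (nats). Taking the *minimum* candidate means
only the most informative direct ancestor shapes a term's probability, which
avoids the specificity inflation that product-over-all-parents formulas show
on multi-parent terms. Two consequences used as analytic test anchors:
`IC(root) = 0` exactly, and IC strictly increases along every edge by at
least `ln(1/w_part_of)`.

Design choices worth recording:

* The edge weight is applied *before* selecting the most informative
  ancestor, i.e. the minimum runs over weighted candidates. The alternative
  (pick the ancestor by IC first, then apply its edge weight) differs only
  when a higher-IC ancestor connects via `part_of`; the chosen reading keeps
  the selected route the one that actually yields the most informative
  result.
* `C(a)` counts children through retained edge types only, consistent with
  the rest of the graph model.

Term similarity is the normalized IC of the most informative common
ancestor (MICA), `sim(a,b) = IC(MICA(a,b)) / max(IC(a), IC(b))`, with
ancestor sets including the terms themselves. Hence `sim(t,t) = 1` (also for
the root, by the self-identity rule covering the 0/0 case) and terms whose
only common ancestor is the root score exactly 0. MICA ties break
lexicographically for determinism. Pairwise similarities are computed
lazily with a per-domain memo rather than materializing all-pairs matrices.

## Entity similarity: IC-adjusted best-match average

Entities (genes, diseases, profiles) carry term *sets*, aggregated with the
best-match average (BMA): each term's best partner score on the other side,
averaged per side, then averaged across the two directions. Plain BMA is
inflated by shallow exact matches ('protein binding'-style annotations), so
an exact match of term `t` contributes `min(1, IC_t / ic_cap)` instead of 1.
`ic_cap` defaults to the 95th-percentile IC of the domain's ontology:
deep exact matches still contribute ~1, shallow ones proportionally less,
and the score never exceeds 1 (the cap is configurable so the uncapped
reading can be explored). Empty term sets give score 0 with the emptiness
recorded in the count fields — a gene unannotated in a domain is
distinguishable from a gene that genuinely scores low there.

## Query profiles

A query is a set of phenotype term ids (or a catalog disease, which supplies
them). Its multi-domain annotation profile combines, with recorded
provenance and precedence SEED_GENE > BRIDGE > QUERY on collisions:

1. direct annotations of *seed genes* — genes of catalog diseases whose
   phenotype sets score at least `min_sim = 0.3` BMA similarity against the
   query, the top `k = 50` diseases contributing (no threshold for "similar
   phenotype" is canonical; both knobs are exposed);
2. *bridge* targets of the query terms — explicit bidirectional
   term-to-term links across ontologies (phenotype to process, anatomy,
   pathway, ...), supplied as an input table so synthetic fixtures and real
   extracts share one code path;
3. the query terms themselves in their phenotype domains.

Model-organism phenotypes of seed genes' orthologs also enter the
cross-species phenotype domain by default (config-toggleable). Seed-gene
annotations enter unweighted; weighting them by the contributing disease's
phenotype similarity is left as a non-default option. When a query's
phenotype terms span several phenotype ontologies, disease phenotype
matching scores each domain separately and averages over the query's
domains; with one phenotype ontology this reduces to a single BMA.

For novel-gene simulation, a (gene, disease) association is masked by
removing the gene from the catalog copy (by default from every disease), so
the held-out gene cannot seed its own profile. Separately,
`extract_features(..., mask_phenotype_link=True)` replaces the
phenotype-domain features with the unknown sentinel, for catalogs whose gene
phenotype annotations are themselves derived from the association being
tested; the synthetic benchmark does not use this flag because generated
phenotype annotations are planted independently of the catalog, so there is
no circularity to hide.

## Interactome neighborhood enrichment

A candidate's neighborhood is the set of genes sharing a direct physical
interaction with it. To extend sparse annotation without importing noise,
only terms *over-represented* in the neighborhood against the
whole-interactome background transfer: per term, a one-sided Fisher's exact
test (computed as the hypergeometric upper tail) on the 2x2 table
annotated/not x in-neighborhood/rest-of-interactome, Bonferroni-corrected
over the terms actually tested for that neighborhood (terms with no
neighborhood annotation are not tests), retaining corrected P < 0.01. The
background excludes the neighborhood itself from the outside column by
default (standard 2x2 construction; a flag includes it). Correction runs
jointly across domains per neighborhood. Enriched terms feed a separate
per-domain similarity feature; they are never merged into the gene's direct
annotations.

Interactome proximity to the profile's seed genes is the shortest-path
length, 0 for a seed, capped at a sentinel of 10 for unreachable or absent
genes.

## Variant filtering

Filters run in the order class → region/quality/allele-frequency →
genotype; the two per-variant stages are pure predicates (order-independent
among themselves), and the genotype stage runs last so compound-heterozygote
counting only sees variants that survived the earlier stages. Class
filtering is per transcript: a variant benign in one transcript but damaging
in another survives (codon-position plurality). Region intervals are 1-based
and inclusive on both ends; an absent allele-frequency annotation never
removes a variant. In recessive mode a variant is retained when every
affected sample is homozygous-alt or carries at least two retained
heterozygous variants in the same gene, while no unaffected sample satisfies
the same condition; no phasing is attempted (two hets suffice — a documented
over-approximation). Any explicit per-sample genotype requirement can be
given instead; missing genotypes satisfy no requirement unless explicitly
allowed. Diploid genotype codes only; sex-chromosome hemizygosity is out of
scope. Multi-allelic records are split per alt allele with genotypes recoded
relative to that allele. Genes are ranked, not individual variants; a
ranked gene lists its surviving variants.

## Features and ranking schemes

Each candidate is a fixed 32-entry vector: per-domain direct similarity (7),
per-domain direct annotation count (7), per-domain mean IC of direct
annotations (7), per-domain similarity of neighborhood-enriched terms (7),
mouse and fish ortholog phenotype similarity (2), interactome proximity to
seed genes (1), and an integer disease-type code (1). Features that cannot
be computed (no interactome node, no ortholog) take the sentinel -1; the
layout is versioned into saved models.

Three schemes produce ranks (descending score, lexicographic tie-break):

* **avg** — unweighted mean of the seven direct domain scores;
* **wavg** — weighted mean over *annotated* domains only (zero-count domains
  leave both numerator and denominator), defaults weighting the two
  phenotype domains 2.0 and the rest 1.0 — a matching (model-organism)
  phenotype is a far stronger predictor than, say, cellular localization;
* **rf** — a random forest of 600 trees, 6 features per split, trained on
  disease genes (features against their disease's profile with the gene's
  own association masked) versus one random gene per positive, matched by
  total-annotation-count quintile so the model cannot simply learn
  annotation richness. Training fits once, removes every instance
  misclassified in its held-out fold of a stratified 10-fold
  cross-validation (likely label outliers), and refits on the cleaned set.
  A candidate's posterior is the explicit fraction of trees voting for the
  disease-gene class — a multiple of 1/600 — not the averaged leaf
  probabilities.

The tree learner is scikit-learn's `RandomForestClassifier`; the bespoke
part is the training protocol and vote-fraction posterior, not the trees.

## Synthetic worlds and what they do (and do not) show

The fixture generator builds complete desk-scale worlds: one random rooted
DAG per domain (40-70 terms, depth ≤ 6, 20% `part_of` edges, 15%
multi-parent), 286 genes (250 background + 12 diseases x 3 causal genes),
annotations of 1 + Poisson(2.5) terms per gene per domain with 25% domain
dropout, a disease catalog with deep phenotype terms (3 cross-species + 2
human-phenotype per disease), bridges from each disease's phenotype terms to
its per-domain "module" terms, an interactome with causal-gene cliques
embedded in a random background (mean extra degree 1 + Poisson(1.5)),
ortholog maps (mouse 50%, fish 25% of genes, independent of causality), and
multi-sample VCFs with a class-realistic background (60% benign / 30%
missense / 10% other damaging — fixture constants, not empirical claims)
plus exactly one planted causal variant guaranteed by construction to
survive the default filters.

Signal strength is a single dial: with probability `signal` (default 0.8) a
causal gene's annotations are drawn from its disease's phenotype/module
terms instead of uniformly. At `signal = 0` the planted structure is
withdrawn entirely — annotations, bridges and interactome modules are
random, and ortholog presence was made causality-independent precisely so
that nothing but annotation *content* separates causal genes from
background. These worlds exercise every code path with known ground truth;
they do not emulate real annotation sparsity patterns, literature bias,
ontology depth distributions, or linkage structure in variants, so passing
benchmarks bounds correctness of the machinery, not expected accuracy on
real exomes.

## Evaluation protocol

Per replicate, one (disease, causal gene) pair is drawn, the gene's
associations are masked, the profile rebuilt, and the gene ranked together
with 200 random decoys carrying at least one Gene Ontology annotation.
Truth genes must meet the same minimal-annotation eligibility as decoys;
otherwise the comparison is biased and the null expectation is no longer
exactly one half. The replicate statistic is the fraction of decoys the
truth outscores (ties half) — the Mann-Whitney form of the ROC AUC, which
the tests verify against trapezoidal integration to 1e-9. Replicates are
summarized by mean AUC and cumulative rank buckets
(first/top-10/top-25/top-100).

Replicates sharing a truth gene are strongly correlated (only the decoy
draw changes), so confidence intervals are computed over per-truth-gene
means, and the null-world chance check aggregates three independently
seeded null worlds (about a hundred truth-gene clusters). The
method-ordering check follows the stated protocol — paired one-sided
t-tests over 200 shared replicates on a high-signal world, train/test split
two-thirds / one-third at the disease level. Problem sizes throughout
(286-gene worlds, 200 replicates, 50-200 decoys) were chosen as the
smallest at which the ordinal comparisons stabilize.

## Numerical and degenerate-input conventions

* Root IC is emitted as exactly 0.0 (not -0.0); probabilities compare to
  machine precision against the memo-free recursion in tests.
* Deterministic tie-breaks everywhere: lexicographic on term ids (MICA), on
  disease ids (similar-disease ranking), on gene ids (candidate ranks).
* Empty neighborhoods, empty term sets, unknown genes, and header-only VCFs
  all return empty/zero results rather than erroring; corrupt structure
  (cycles, undefined parents, unreachable terms, samples missing from the
  VCF, neighborhoods outside the interactome) errors loudly.
* All generators and the training/benchmark stack are deterministic under
  their seeds; model serialization round-trips bit-identical posteriors.

## Known limitations

* Compound-heterozygote logic is phase-unaware by design.
* The 32-feature layout is this package's concrete proposal for the feature
  families it encodes; other layouts would need a new layout version.
* The weighted-average's domain weights are heuristic defaults, not fitted.
* Cross-domain Bonferroni pooling per neighborhood is one defensible choice;
  per-domain correction is not currently offered.
* The synthetic evaluation measures ordinal properties (scheme ordering,
  chance collapse at null); absolute AUCs on synthetic worlds carry no
  meaning for real data.
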