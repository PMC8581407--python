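# Methods

## Signature scheme

Inflammasome signaling is profiled step-wise by five scores over nine gene
sets: one *core* set for the sensing step (the inflammasome-complex genes)
and, for each of the four post-translationally regulated nodes (CASP1, GSDMD,
IL1B, IL18), a pair of directional sets — genes up-regulated and genes
down-regulated downstream of the node. Set sizes in the packaged compendium
are 15 (IC), 24+10 (CASP1), 9+4 (GSDMD), 50+22 (IL1B), and 6+2 (IL18); one
gene (CXCL8) belongs to both the CASP1 and IL1B up-sets, so the union is 141
unique symbols. The packaged lists are a *synthetic stand-in*: biologically
plausible symbols with the published set sizes and overlap structure, not a
transcription of any curated compendium. Users with a real compendium supply
it as a GMT file plus a direction sidecar TSV (`set_name, score_name, step,
direction`); the loader validates completeness (all five scores, correct
directions) and refuses empty or unannotated sets.

The curation operations regenerate such sets from perturbation data:
`screen_degs` screens case vs control log-expression profiles with a per-gene
Welch t-test (|logFC| > 1, p < 0.05 by default; a single-replicate mode
returns logFC-only records, since no within-arm variance exists), and
`intersect_regulated` performs a vote-counting meta-analysis — a gene is kept
when it moves in a consistent direction in at least `min_support` datasets
(default: all), and direction-conflicted genes are dropped outright. Welch's
t was chosen as the dependency-light analog of a moderated linear model; it
has no information sharing across genes, so at 2–3 replicates per arm it is
conservative. With `min_support` equal to the number of lists the procedure
reduces to the strict direction-consistent intersection.

## Scoring

`ssgsea_score` implements the single-sample rank-weighted running sum. Per
sample: genes are ranked by expression (ascending rank value r, so the
most-expressed gene carries r = n_genes; ties averaged by default);
walking down the list from the top, the score accumulates
(cumulative in-set weight fraction − cumulative out-of-set count fraction),
with in-set weights r^α. The enrichment score is the *sum* over the whole
list (the single-sample convention), not the supremum deviation used by
two-group GSEA. Defaults: α = 0.25; tie policy `average` (deterministic
without a seed; `min` and seeded `random` are available); no cross-sample
normalization (`minmax_across_samples` is exposed because some
implementations rescale by default — both modes are legitimate, and the
choice is recorded in the score-matrix sidecar). Gene-set members absent
from the matrix are dropped per the data's gene universe; coverage below 50%
logs a warning, zero coverage is an error.

The composite scores are plain differences, up-set enrichment minus down-set
enrichment, so a positive value indicates the node's downstream program is
transcriptionally engaged. `score_matrix` assembles the samples × 5 matrix in
fixed column order (IC, CASP1, GSDMD, IL1B, IL18) and z-scores each column
across samples by default. The scaling decision matters: the five raw scores
have different dynamic ranges (set sizes differ by an order of magnitude),
and unscaled K-means would be dominated by the widest column. The transform
is recorded so raw-mode sensitivity checks remain possible.

Upper-quartile normalization (count mode): each sample is scaled so the 75th
percentile of its *nonzero* counts equals the reference (default 1000), then
log2(x+1). All-zero samples are a named hard error.

## Consensus clustering

Monti-style resampled consensus: `resamples` (default 500; 200 in the
acceptance run) subsamples of ⌈0.8·n⌉ samples without replacement, each
partitioned by K-means (k-means++, 20 restarts, Euclidean distance) for every
K in 2..8. The same subsample draw is reused across K, and all draws plus the
per-(K, resample) K-means seeds derive from one `numpy` generator seeded by
the caller, so results are bitwise reproducible and the recorded draws allow
an independent replay of the consensus matrices. Consensus(i, j) =
co-clusterings / co-samplings; never-co-sampled pairs are flagged missing and
excluded from the CDF. Final per-K labels come from average-linkage
hierarchical clustering of (1 − consensus), the convention of the standard
consensus-clustering tooling, rather than a final K-means run.

Diagnostics per K: cluster-consensus (mean within-cluster consensus), the
exact area A(K) under the empirical CDF of consensus values on [0, 1], the
relative delta area (ΔA(2) = A(2); ΔA(K) = (A(K) − A(K−1))/A(K−1) for K ≥ 3),
and the average silhouette width s = (b − a)/max(a, b) of the per-K labels in
score space (singletons get 0).

**K selection.** The published analyses confirm cluster stability
qualitatively from these diagnostics; this package codifies an explicit,
auditable rule. Candidate K must pass two gates: ΔA(K) > 0.05 (the move from
K−1 to K still adds material consensus structure) and average silhouette
≥ 0.25 (the resulting partition is geometrically cohesive). Among candidates
the silhouette argmax wins, ties going to the larger K; if no K qualifies,
the silhouette argmax over all K is returned with a warning. A
largest-qualifying-K rule with a fixed delta-area floor was tried first and
found non-identifiable: across datasets the delta area of a *spurious* split
of one well-separated cluster can exceed the delta area of the *true* final
split in another dataset, so no single floor orders both correctly, whereas
the silhouette argmax over elbow-qualified K recovers the planted K in both
regimes. The full decision trace (both diagnostic vectors, gates, candidates,
fallback flag) is persisted with the result.

**Semantic labels.** With exactly six clusters, centroids are ranked by IC
(ties broken by CASP1): bottom/middle/top pairs become the Low/Mid/High IC
strata; the Low pair is split by IL1B, the Mid pair by IL18 − CASP1 dominance,
the High pair by IL18. Canonical numbering 1..6 follows the semantic-name
order (IC^Low IL1B^Low … IC^High IL18^High); numbering from the names rather
than from a secondary IL18 sort is deliberate, since IL18 does not
discriminate the IC-low pair. Any other cluster count yields numeric labels
only.

## Cluster characterization

- *Composition*: upper-tail hypergeometric p = P(X ≥ k) for each
  (tumor type, cluster) pair, X ~ Hypergeom(N, K_type, n_cluster), BH across
  all pairs. A single-type cohort degenerates to p = 1 with a warning.
- *Binary genomic features*: one-vs-rest 2×2 chi-square without continuity
  correction; when any expected cell is below 5 the record switches to
  Fisher's exact test and is flagged. Effect = in-cluster frequency − rest
  frequency. Constant features are skipped with a notice.
- *Expression*: one-vs-rest Mann–Whitney rank-sum with logFC = difference of
  log-scale means; BH per feature class; significance thresholds per class
  (coding and miRNA |logFC| > 1, lncRNA |logFC| > 2, all FDR < 0.01). The
  rank-sum test replaces a moderated linear model deliberately: it is
  distribution-free and dependency-light, at some power cost for small
  clusters; direction and thresholding are unchanged. BH families are one per
  feature class across all clusters.
- *Similarity map*: S(i, j) = 1/(1 + d(i, j)), d Euclidean over the five
  scores. S ∈ (0, 1], symmetric, S = 1 iff identical score vectors.
- *Survival*: overall log-rank test across clusters (lifelines); pairwise
  univariate Cox models give the hazard-ratio table oriented row-cluster vs
  column-cluster, with a masked copy hiding pairs at p ≥ 0.05 (the figure
  convention). Zero events overall is a hard error; degenerate pairs that
  break the Cox fit are left missing and logged.

## Cluster predictor

Two-layer validation: stratified 80/20 split by the caller's seed; stratified
five-fold CV of all six algorithms on the training split (inner layer);
a single holdout evaluation on the 20% split (outer layer). Features are
standardized with training-split statistics only. Accuracy is plain
multiclass accuracy; the report carries both layers because a single
"prediction accuracy" number is ambiguous between them. The shipped model is
an RBF-kernel SVM (C = 1, class-balanced weights — the kernel and C are
config-exposed since only "SVM" is specified upstream) fitted on all labeled
samples, stored with its StandardScaler and the SHA-256 fingerprint of the
signature scheme. Prediction re-applies the stored scaling — never refits it
on external data — and hard-fails on a fingerprint mismatch rather than
silently rescaling. Semantic class labels travel with the model so external
cohorts missing clusters stay interpretable.

## Synthetic data generator

The generator emulates the data regime the analysis assumes: a gene × sample
matrix of log2-scale expression with per-gene baselines μ_g ~ N(5, 1),
per-cluster program shifts, and residual noise N(0, σ²). The shift table maps
each of the six clusters to a level in {−δ_high, −δ_low, 0, +δ_low, +δ_high}
per program, encoding the six published score patterns (cluster 1: sensing
and IL1B programs strongly down; cluster 6: sensing and IL18 strongly up;
etc.). Shifts are applied with the program's direction — an "up" level moves
up-regulated members up and down-regulated members down — so composites
respond coherently. Defaults: 2000 genes (141 signature + background),
100 samples per cluster, δ_high/δ_low = 1.5/0.6 log2 units, σ = 1.0, chosen
so recovery is reliable but not trivial (average silhouette ≈ 0.5 at the
planted K, in the range of real molecular-subtype separations). Tumor types:
eight synthetic labels; each cluster draws its type from a multinomial that
over-weights one designated type at 0.45 (rest uniform), making composition
enrichment non-trivial but decodable. Survival: exponential event times with
hazard 0.02 × multiplier(cluster), multipliers (0.7, 0.8, 1.1, 1.2, 1.0,
2.0) so the IC^High IL18^High cluster has the worst prognosis; censoring is an
independent exponential time calibrated to censor ≈ 30% at multiplier 1 —
exponential rather than uniform censoring keeps the planted
proportional-hazards structure exact. Three spawned generator streams
(expression, types, survival) derive from the single config seed; identical
configs reproduce cohorts bitwise.

What the generator does *not* emulate: count overdispersion (a thin
Poisson-lognormal count mode exists only to exercise upper-quartile
normalization), gene–gene correlation beyond the planted programs, batch
effects, tumor-type-specific expression signatures (types are labels only,
independent of expression given the cluster), and non-proportional hazards.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated model, not performance on real cohorts with
correlated backgrounds and lineage signal.

`generate_regulated_profiles` supplies matched case/control profiles with
planted up/down shifts for a chosen node, feeding curation round-trip tests.

## Numerical and reproducibility choices

- Ranking ties: average ranks by default (deterministic); the running-sum
  walk uses a stable sort, so tied genes contribute in input order.
- Consensus CDF area is the exact integral of the step ECDF on [0, 1], not a
  histogram approximation.
- All tables are written with sorted row/column order; JSON with sorted keys;
  reruns from identical configs are byte-identical (tested).
- One top-level seed fans out to named substreams via a keyed blake2b hash
  (`derive_seed(seed, name)` < 2^31), so stages can be re-run independently.
- Scale: the default test and acceptance runs use n = 600 samples and 200
  consensus resamples with 20 K-means restarts — sizes at which the full
  suite completes in about a minute while keeping planted-structure recovery
  comfortably away from degeneracy.

## Known limitations

- The packaged compendium is synthetic; scientific use requires a real
  curated GMT (the loader and fingerprinting make substitution safe).
- The rank-sum DE screen is less powerful than moderated models at very
  small group sizes (the ≥3-samples-per-side precondition is a floor, not a
  recommendation).
- Consensus clustering stores full n × n matrices per K; memory grows
  quadratically (fine at cohort scale of 10^3–10^4, the intended regime).
- Semantic labeling assumes the six-cluster geometry; other K fall back to
  numeric labels by design.
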