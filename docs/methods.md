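# Methods

This note documents the statistical models, the synthetic-data design, the
numerical conventions and the open design choices behind `epiorigin`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and conventions

Beta values are methylation fractions in [0, 1]; missing entries are the
literal token `NA` on disk and a NaN mask in memory — never a sentinel
number, which would collide with valid beta values. All genomic coordinates
are 1-based and inclusive; minus-strand genes have TSS > TES. The sample
sheet is the single source of truth for class labels, tumor/normal condition,
pairing and cohort: matrices are subset to it on load, and every dropped or
unknown identifier is itemized in the load report (validation is total — no
silent partial loads).

## Probe QC and imputation

Probes are removed when they lie on chrX/chrY, are SNP-flagged,
multi-mapping, or have a missing fraction strictly greater than 0.5 (a probe
missing in exactly half its samples is kept). A probe is counted once in the
filter report, under the first matching rule in that order, making the
counts deterministic. SNP/cross-reactivity status comes from manifest flags
rather than built-in catalogs, keeping the tool data-driven.

Imputation is probe-space KNN: for a missing (probe *p*, sample *s*) the
donors are the *k* probes nearest to *p* in Euclidean distance over
pairwise-complete samples that are observed at *s*, and the imputed value is
their uniform mean (default *k* = 10, a standard choice for methylation
arrays; exposed in the config). `sklearn.impute.KNNImputer` applied to the
probes × samples orientation implements exactly this contract. Observed
entries are never altered; imputation of a complete matrix is the identity.

## Differential analysis

Methylation: per-probe two-sided Mann–Whitney U, tumor vs normal. Exact
enumeration is used when both groups have ≤ 8 samples, and a tie-corrected
normal approximation with continuity correction otherwise; the approximation
agrees with the exact null to |Δp| ≤ 0.011 at the 8 + 8 boundary (the
worst case of the standard approximation; dropping the continuity correction
or using a t-reference is measurably worse). Significance requires both
BH-adjusted *p* < 0.05 and |Δβ| > 0.2, with Δβ = mean(tumor) − mean(normal),
so "hyper" means hypermethylated in tumor.

Expression: counts are scaled to counts-per-million per sample and
transformed to log2(CPM + 1). Each gene gets a moderated two-sample
t-statistic whose variance is shrunk halfway toward the mean variance over
all genes (weight 0.5, residual df n₁ + n₂ − 2); log2FC is the group mean
difference on the transformed scale. This is a deliberately self-contained
moderated test with a fixed transform and shrinkage weight, not a port of
any external package. Genes with zero counts everywhere report
log2FC = 0, *p* = 1 by contract. Gates: *q* < 0.05 and |log2FC| > 2.

BH adjustment is the standard step-up procedure (statsmodels) applied within
each call; the suite cross-checks it against a from-scratch step-up
implementation.

## Epi-driver discovery

**Co-expression network and modules.** Adjacency is |Pearson r| of
log2(CPM+1) over tumor samples, with an edge when |r| ≥ τ (default 0.6);
constant genes are excluded and counted. Modules come from average-linkage
hierarchical clustering of the distance 1 − |r|, cut at height 0.3, keeping
clusters of at least 10 genes. This is a small deterministic equivalent of
heavier co-expression machinery, not a port of it. A module is
tumor-specific when the per-sample mean of z-scored member expression
differs between tumor and normal (rank-sum, BH over modules, *q* < 0.05) —
a shift in either direction qualifies; the network genes are those with at
least one supra-threshold edge.

**Directed networks.** Metabolic mode: enzyme A feeds enzyme B when some
product of a reaction catalyzed by A is a substrate of a reaction catalyzed
by B (A ≠ B). PPI mode: each undirected edge with weight ≥ 0.4 is expanded
to both directions so that downstream neighbourhoods are defined uniformly.

**Importance score.** For gene A with downstream neighbours,

    Score_A = |AUC_ROC − 0.5| · log2( (C_in/C_all) / (N_in/N_all) )

with C_in/C_all the counts of A's downstream neighbours inside
tumor-specific modules vs overall, and N_in/N_all the tumor-specific vs
total gene counts of the co-expression network. The AUC construction is an
interpretation (the formula's provenance does not pin it down): labels are
A's downstream neighbours vs non-neighbours within the co-expression
network, the score is |Pearson r| with A over tumor samples, and the AUC is
the rank statistic with ties counted ½. Genes with C_in = 0 receive −∞ and
can never be key genes. Key genes are the top `key_fraction` (default 10%)
of finite scores — a deterministic quantile rather than a permutation
cutoff, ties broken toward the smaller gene id. The suite verifies the whole
computation against an all-pairs brute-force oracle to 1e−12.

**Calling.** A gene is an epi-driver iff it is differentially expressed,
key in the metabolic *or* the PPI network (union; intersection available),
and has at least one significantly associated CpG in the cancer-type-
corrected association model. Overlaps between per-class driver sets are
scored with a one-sided Fisher exact test, BH-adjusted across class pairs.

## Methylation–expression association

Region windows are strand-aware: upstream = 1–1,500 bp 5′ of the TSS
(excluding the TSS base), downstream = 0–1,500 bp 3′ (including it), gene
body = the rest of the TSS–TES span; the upstream/downstream boundary
convention fixes the inherent "0–1,500" ambiguity deterministically. Within
one gene the precedence is upstream > downstream > body; a probe may serve
several genes, and probes in no window get a single intergenic record.

For each (probe, gene, region) pair, expression (log2(CPM+1)) is regressed
on beta across tumor samples, plain or with cancer type as a categorical
covariate (implemented by within-class demeaning of both sides —
Frisch–Waugh — with df = n − C − 1). The "methylation event" is the probe's
beta directly, with no region-level averaging; p-values come from the
slope's t-statistic and are BH-adjusted within each (region, model) family.
Probes with zero beta variance are skipped with a reason. The gene-level
flag is "any associated CpG with q < 0.05", with positive/negative slope
tallies per gene.

The permutation null uses the whole-window variant: gene-level methylation
is the mean beta over the gene's assigned probes, and each iteration
permutes the sample columns of that matrix only (expression and class labels
fixed), recounting genes significant under the corrected model. A test hook
accepts explicit permutations (e.g. the identity) for exactness checks.

## Marker selection

Stage 1 filters CpGs in epi-driver genes per (probe, class) with a Welch
one-vs-rest t-test (unequal variances fit the unbalanced design),
BH-adjusted across probes within each class (Bonferroni available as a
switch), gated at *q* < 0.05 and SD > 0.2. The SD is read as the pooled
standard deviation of the probe's beta across **all** tumor samples — a
genuinely tissue-specific CpG is spread out between classes even when tight
within each — with a per-class variant available in the config. Classes
with fewer than 3 tumor samples are skipped with a warning.

Stage 2 fits one multiclass gradient-boosted tree ensemble (200 rounds,
depth 3, learning rate 0.1, column subsample 0.8, fixed seed, single
thread) and ranks each probe by the mean absolute exact tree-path Shapley
attribution over samples and classes; ties break by probe id. The column
subsample lets exactly collinear probes share attribution instead of one
copy absorbing all of it.

The panel size is the smallest *k* whose next `patience` (default 2)
increments of 10-fold CV random-forest accuracy on the top-*k* probes each
gain less than ε (default 0.005); near the end of the curve the rule uses
whatever increments remain (at least one), and if it never fires the full
length is returned. The CV folds are fixed across *k* so that successive
increments share fold noise. Note that ε = 0.005 is finer than the accuracy
granularity 1/n of small cohorts; plateau detection at that ε is only
meaningful once the CV cohort exceeds ~200 samples.

## Origin classifier

The tumor cohort is split 7:3 per class (rounding toward training,
seed-deterministic); matched normals follow their tumor pair so pairs never
straddle cohorts. For each class, the rest classes are under-sampled without
replacement to match the positive count, allocated as evenly as possible
with remainders assigned by a seeded draw; if the rest pool is too small
everything is kept with a warning. Hyperparameters (trees ∈ {10, 25, 50,
100}, criterion gini/entropy) are chosen by out-of-bag score, ties resolved
toward fewer trees, then gini; 10-fold CV accuracy/AUC on the balanced set
are recorded.

Multi-class prediction renormalizes per-class positive probabilities to sum
to one and takes the argmax, ties resolved toward the larger training
prevalence, then lexicographically — the fusion rule is a design choice, as
is the CI construction (fold-SE on CV, 1,000 stratified bootstrap resamples
on held-out data, clipped to [0, 1]). SVM and logistic-regression baselines
run behind the same split/balance protocol but are off by default. Missing
panel probes in a prediction input are an error naming the probes — never a
silent imputation.

## Synthetic cohorts: what they emulate, and what they do not

Defaults describe the study design at desk scale: 5 tissue classes × 40
tumor/normal pairs, 1,000 probes, 200 genes, 10 planted epi-driver genes,
six marker CpGs hosted in five driver genes (2, 1, 1, 1, 1 per class),
coupling |r| = 0.7, Δβ = 0.3, marker separation 0.4, beta noise SD 0.05,
NB dispersion 0.02, 10% confounded genes.

Each planted driver carries a per-tumor-sample methylation latent *u*: its
gene-body and downstream probes track *u* (positive coupling; the second
positive probe keeps the gene's window-mean methylation informative, since
the body/promoter pair alone cancels in the mean), its promoter probe tracks
1 − *u* (negative coupling), and the same latent drives a tumor-only
co-expression factor shared with an 11-gene companion block. The achieved
beta-vs-log-expression correlation is verified on the emitted matrices and
the factor loading raised under a bounded retry before declaring a config
infeasible. Drivers are 8-fold shifted on the **CPM** scale — the raw shift
is inflated by the tumor/normal library-composition ratio, solved by a short
fixed-point iteration — with signs alternating by module so composition
stays balanced; companions shift by ±1.5 log2 (tumor-specific but mostly
below the DE gate). Background genes carry most of the library mass: with
modest factor loadings (0.8 log2) and noise (0.15 log2, NB dispersion
0.02), this keeps CPM's compositional coupling from correlating unrelated
genes — with strong loadings the library total itself swings with the module
factor and every other gene inherits an anti-correlated echo.

In the reaction table each driver's product feeds four companions and a
three-enzyme chain continues downstream; chain enzymes and background genes
also get out-edges but diluted with targets outside any module, so only true
drivers are *enriched* for module members downstream — background genes
score finite but at or below zero, which is exactly the contrast the
importance score is built to detect. In the PPI table drivers are hubs wired
to all companions; sparse background edges include sub-0.4 weights to
exercise the cutoff.

Marker probes are tight and high (rest mean + separation) in the marked
class's tumors and a 50/50 mixture of two tight modes (β ≈ 0.05 / 0.45)
everywhere else, mirroring the bimodality of real CpGs; the between-mode
spread keeps the pooled SD above the 0.2 gate while the distribution is
identical across unmarked classes, so a marker probe carries information
about its own class only. Confounded genes shift both omics between classes
(evenly spaced shifts, permuted per gene) with no within-class coupling —
precisely the artifact the cancer-type-corrected model must remove. About
2% of beta entries are missing at random, plus three probes above 50%
missingness; nuisance probes on chrX/chrY and with SNP/multi-mapping flags
exercise the filters.

Not emulated: array chemistry and probe-type effects, batch effects, tumor
purity, copy number, library-preparation artifacts beyond a per-sample scale
factor, and inter-gene regulatory structure beyond the planted modules.
Consequently, passing tests demonstrate that the pipeline recovers effects
of the designed kind and size from clean, well-specified data; they do not
certify performance on real consortium data, where effect sizes are smaller,
confounding richer and annotation noisier.

## Numerical and reproducibility choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; xgboost and the forests run single-threaded with
fixed seeds. The pipeline manifest hashes every input and output file
(sha256), and a rerun with an identical config is bit-identical, which the
suite asserts. Beta noise is added on the logit scale and clipped to
[0.001, 0.999] so additive effects respect [0, 1]. Heatmaps z-score rows
(constant rows become zeros with a warning) and order rows and columns by
complete-linkage Euclidean clustering with deterministic, id-stable leaf
order; the suite checks the cluster structure against a from-scratch
agglomerative oracle.

## Known limitations

* The AUC inside the importance score is one consistent reading of an
  under-specified construction; it is configurable in spirit (the labels and
  score are isolated in one helper) but only the default is tested.
* The rank-sum approximation is the standard normal one; exactness holds
  only on the enumeration path.
* The moderated expression test is a fixed-weight shrinkage contract, not an
  empirical-Bayes fit; with very few genes the prior variance estimate is
  itself noisy.
* Plateau-based panel sizing inherits the granularity of CV accuracy;
  on cohorts with fewer than ~1/ε samples it can overshoot by one.
* The permutation null permutes whole methylation columns, preserving
  between-probe correlation but not class-conditional structure; it matches
  the intended null (no sample-linked methylation–expression coupling), not
  a within-class-stratified variant.
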