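# Methods

## Problem and model

Histone-modification ChIP-seq signal is spatially correlated well beyond the
single gene: repressive and active chromatin organise into multi-gene
domains.  `epidomain` detects such domains by modelling the *sequence of
genes along a chromosome* as a hidden Markov chain.  The observation at gene
i is an m-vector x_i of per-mark summary scores; the hidden state is the
gene's domain type.  Emissions are multivariate Gaussian with **diagonal
covariance** — each mark contributes an independent univariate Gaussian per
state — so a state is characterised by per-mark means μ_s and variances
Σ_s.  No covariance between marks is modelled; this is a deliberate
simplification that keeps the parameter count at 2·S·m and is adequate when
marks are assayed independently.  Raw per-bin counts might suggest Poisson
emissions, but the scores are *averages* of counts over many bins, which the
central limit theorem pushes toward Gaussianity, and they are non-integer,
so the Gaussian family is used throughout.

Each chromosome is one independent chain; all chains share a single global
parameter set, and EM pools sufficient statistics across chains.  Chains are
never continued across a chromosome boundary.

## Summary scores

For promoter-peaked marks (H3K4me2, H3K4me3, H3K9me3, H3K27me3) the score is
the mean tag count per `bin_width` (default 100 bp) bin over
[TSS − flank, TSS + flank) with `flank` = 2 kb, strand-resolved.  H3K36me3
accumulates toward the 3′ end of transcribed regions, so its window is the
terminal `span` (default 2 kb) of the coding sequence on the transcribed
strand.  The averaging unit (count per 100-bp bin) is a configuration choice
that places scores in the 0.1–15 range the reference emission parameters
occupy; the score scales linearly with sequencing depth, so conditions must
be depth-normalised before comparison (see *Differential* below).

Genes with more than 50% repeat-masked sequence in **either** window are
excluded (strict inequality), and excluded genes are removed from the chain
entirely — their neighbours become adjacent.  This mirrors standard
practice of dropping repeat-dominated promoters whose mapped-tag counts are
unreliable.

## Choosing the number of states

An initial guess for the number of domain types comes from k-means (Lloyd's
algorithm, 10 restarts, best inertia kept) and the gap statistic

Gap(K) = E[log W_K] − log W\*_K,

with W\*_K the pooled within-cluster sum of squares and the expectation a
Monte-Carlo mean over reference datasets drawn uniformly over each feature's
observed range (the simplest of Tibshirani's references).  `best_k` is the
argmax of Gap over the evaluated range.  Two caveats are documented rather
than hidden: (1) the argmax rule is the package's contract, although on
strongly heteroscedastic data Gap can keep growing with K — on blobs carrying
the full reference per-state variances (active-state H3K4me3 variance ≈ 62)
both this implementation and R's `cluster::clusGap` find Gap monotone
through K = 6, so the model-selection fixture uses well-separated blobs at
the reference state means with unit spherical noise; (2) the "k-means
average agglomeration" wording sometimes attached to this procedure is
internally inconsistent — the within-cluster-sum-of-squares objective and
"cluster means" language are k-means notions, so standard Lloyd k-means is
what is implemented.

## HMM estimation and decoding

**Initialisation.**  The recommended route copies k-means cluster means and
(floored) variances into the emission parameters, sets a sticky transition
matrix (diagonal 0.9, uniform off-diagonal — domains are multi-gene, so
self-transition dominates) and uses cluster occupancies as the initial
distribution.  The alternative draws parameters from a semi-conjugate
hierarchical prior: per mark k and state s, σ²_ks ~ scaled-Inv-χ²(ν_k)
scaled so E[σ²_ks] = s²_k (the mark's sample variance; the raw
"(ν−2)⁻¹ = s²" scaling is dimensionally ambiguous as usually printed, and
the expectation-matching reading is implemented), then
μ_ks ~ N(θ_k, s²_k) with θ_k the mark's sample mean.  ν defaults to 10,
which keeps the draw's relative spread moderate (sd/mean = √(2/(ν−4)) ≈ 0.58)
while satisfying ν > 2 for a finite mean.  On simulated reference-parameter
data, the cluster-based start reaches a final log-likelihood at least as
high as the best of many random prior starts (tested).

**EM.**  Standard Baum–Welch with scaled forward–backward recursions (per-row
emission rescaling plus per-step normalisation; scaling factors reconstruct
the log-likelihood exactly).  The M-step uses MLE (divide-by-weight) moment
updates with a variance floor of 1e−6 against degenerate spikes.
Convergence: |Δ log L| < 1e−4, max 500 iterations; the log-likelihood trace
is asserted non-decreasing (to 1e−8 slack) in the test suite.  Chains
shorter than two genes carry no transition information and are skipped with
a warning.

**Decoding.**  Viterbi (log-space dynamic program) gives the joint-MLE path
and is the default gene-state assignment; forward–backward gives per-gene
posteriors and the per-position MAP path.  The two are distinct decoders —
Viterbi is *not* an approximation of forward–backward, although on
well-separated states they agree at nearly every gene (≥95% agreement is a
tested property on simulated reference data; on real data agreement near
99.8% has been reported).  Both are verified against exhaustive path
enumeration for small instances (n ≤ 8, S ≤ 3) and against hmmlearn under
fixed parameters.

**State semantics.**  After fitting, states are named by their mark profile:
*active* = largest H3K4me3 mean, *null* = smallest total mean, remaining
state(s) *non-active* (high H3K27me3).

## Domain significance

Maximal same-state runs within a chromosome are domains.  Domain j with
genes x_i is scored with

λ_j = −2 Σ_i [log N(x_i; μ_0, Σ_0) − log N(x_i; μ_s, Σ_s)],

where (μ_0, Σ_0) are the mean and diagonal MLE variance of the entire score
matrix and (μ_s, Σ_s) are the decoded state's parameters.  λ_j is referred
to χ² with df = 2·S·m − 2·m (all 2·S·m state parameters counted free against
the 2·m global ones; with S = 3, m = 5 this is 20).  This df is the method's
definition and is kept as such, with a caveat: under standard large-sample
LRT theory only one state's 2·m parameters enter a single domain's
likelihood, so the printed df is anti-conservative in general.  The χ²
machinery is calibration-tested in the regime where the formula is exact —
S = 2 (df = 2m), domains drawn from the global model, per-domain ML state
parameters — where the empirical type-I fraction at α = 0.05 is within 2
percentage points of nominal.

Singleton runs are scored like any other domain; the commonly observed
minimum *significant* domain size of 2 emerges from the significance filter,
not from a hard rule.  Multiplicity is controlled by Benjamini–Hochberg;
domains with q ≤ 0.01 (configurable) are significant.  MLE (divide-by-n)
variance estimators are used for the global model, matching the EM M-step.

## Permutation validation

All validation nulls preserve genomic contiguity: each permutation round
draws, for every observed significant multi-gene domain, one *contiguous*
run of the same number of genes, uniformly over all valid start positions on
chromosomes long enough to hold it.  Scattered gene sets would destroy the
local autocorrelation of annotation and expression and overstate
significance.  With B rounds the attainable minimum p-value is exactly 1/B
(the observed arrangement always counts once); B defaults to 1000, giving a
floor of 0.001.

* **Score coherence** — mean over significant domains of the unbiased
  within-domain variance, per mark; direction *less*.
* **Expression coherence** — the same statistic on a per-gene Z-score
  (focal cell line normalised against the across-line mean and unbiased SD);
  genes with zero across-line variance are dropped.  Direction *less*.
* **GO accordance** — per domain, Fleiss' kappa of a (terms × 2) table in
  which every annotated gene of the domain "rates" every term of a fixed
  slim vocabulary as annotated/not annotated; the observed statistic is the
  mean kappa over domains with ≥ 2 annotated genes; direction *greater*.
  The rater/subject construction is one deliberate design choice among
  several defensible ones and is isolated in a single function
  (`validate._window_kappa`) so it can be swapped.  Kappa is undefined when
  every rating lands in one category; such windows are skipped.

## Simulation study

`simulate_scores` draws hidden states from a first-order Markov chain with
self-transition 1 − 1/L (L = mean domain length, default 10 genes, near the
average significant-domain size observed in real data) and emissions from
per-mark independent Gaussians with the reference per-state means and
variances, optionally scaled by a variance multiplier.  Draws are **not**
truncated at zero by default: clipping would inflate low-signal state means
by up to ~17% (null-state H3K4me2: mean 0.216, sd 0.288) and bias both the
law-of-large-numbers checks and parameter recovery; real scores are
non-negative, but at the reference parameter values the sub-zero Gaussian
mass only matters for the weakest marks, and `clip_at_zero=True` is
available when realism there matters more than exactness.

`run_accuracy_experiment` is the pipeline's self-check: simulate, run the
*blind* inference (k-means init → EM → Viterbi), align inferred to true
labels with the accuracy-maximising (Hungarian) permutation, and average the
per-gene recovery fraction over replicates.  Defaults: 5,000 genes ×
10 replicates per condition.  Viterbi is the decoder under test because it
is the pipeline's assignment method; posterior decoding gives nearly
identical accuracy on these parameters.  Accuracy is invariant to global
relabeling by construction and non-increasing in the variance multiplier on
average (both tested).

`make_fixture_bundle` generates a complete miniature dataset for end-to-end
runs: genes on three chromosomes with three-state domain structure, per-mark
tag BEDs Poisson-scattered at each state's mean rate per bin (so scoring
recovers the generating means to within sampling error), a repeat mask
covering ~5% of promoters, a 23-line expression matrix whose focal column
tracks the active state, and GO terms shared within domains.  What it does
**not** emulate: mappability structure, input/control tracks, fragment-length
effects, covariance between marks, and realistic gene-length/spacing
distributions — so green end-to-end tests demonstrate pipeline correctness
under the model's own assumptions, not robustness to every artefact of real
ChIP-seq.

## Two-condition comparison

The second condition is depth-normalised per mark against the reference —
default `median_ratio` (divide by the median alt/ref score ratio over genes
with positive reference signal); `nb_regression` fits an intercept-only
negative-binomial regression with log-reference offset and divides by the
fitted scale (a deliberately simple GLM formulation; its scale recovery is
tested on synthetic gamma-Poisson data).  The reference model's parameters
are then held fixed and the second condition re-decoded with Viterbi — no
re-estimation, so state identities are directly comparable.  A reference
domain is *changed* iff at least one of its genes decodes to a different
state; within each reference domain the new path induces a sub-domain
refinement, each sub-domain labelled with its ordered transition type
(6 possible ordered state pairs for S = 3, plus "unchanged").

## Numerical and interface choices

* Coordinates are 0-based half-open everywhere (BED convention).
* Gene order within a chromosome is TSS order; ties broken by gene id.
* Tag membership in a window is decided by the tag's start coordinate.
* Scaled (normalised) forward–backward recursions rather than log-sum-exp;
  equivalent in exact arithmetic, and the scaling route exposes the
  log-likelihood as a sum of log normalisers.
* Negative λ (global model fitting better than the state) maps to p = 1.
* Fleiss' kappa raises on the degenerate all-one-category table instead of
  returning a sentinel; callers that aggregate (GO accordance) skip such
  windows.
* All stochastic entry points take explicit seeds; the pipeline manifest
  records every seed, parameter and input digest, and reruns are
  byte-identical.

## Limitations

Gene-level scores preclude basepair-precise domain boundaries.  Marks are
modelled independently (no emission covariance).  The χ² reference for λ_j
is anti-conservative in general (see above), so the FDR threshold is best
read as a ranking device, as in the original formulation.  The negative-
binomial normalisation is a simplified scale fit, not a full regression
normalisation.  Raw-read alignment, input-track normalisation and
web-service enrichment analyses are out of scope.
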