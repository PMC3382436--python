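# Methods

This note documents the statistical model behind `setlevel`, the choices
made where the literature leaves the procedure under-specified, and what
the synthetic benchmarks do and do not demonstrate.

## Data model

An expression dataset is a matrix *E* ∈ ℝ^{p×N} of normalized expressions
e_{j,i} for genes G = {g₁…g_p} over samples S = {s₁…s_N}, partitioned into
two phenotype classes C₀ ∪ C₁. Values are assumed complete and already
normalized; missing or non-finite entries are rejected rather than
imputed. Class strings read from a labels file are encoded {0, 1} in
lexicographic order, which fixes the sign convention of the SetSig
signature and of the signal-to-noise score. A gene-set collection 𝒢 holds
named sets Γ ⊆ G (GMT format); sets with fewer than 5 or more than 200
genes are discarded by the default size filter, and every statistic
operates on a set's *effective* genes — the members actually measured in
the dataset, in dataset gene order.

## Gene-set ranking

All three dedicated statistics share one permutation null: the class-label
vector is permuted uniformly at random (class sizes are preserved by
construction), the statistic is recomputed under each of B permutations,
and p = (b + 1)/(B + 1), where b counts permuted statistics at least as
extreme as the observed one. The add-one form avoids zero p-values. The
same label permutations are shared across all sets of a collection, which
preserves the gene–gene correlation structure under the null and makes
ranking 500 sets with B = 199 a sub-second operation. Sets are ordered by
(p ascending, |statistic| descending, name ascending), a fully
deterministic key.

**Signal-to-noise score.** Gene-level association with the phenotype is
(μ₀ − μ₁)/(σ₀ + σ₁) with n−1 standard deviations. A zero denominator
yields 0 when the class means agree and a sign-preserving cap (default
10⁶) otherwise, so degenerate fixtures stay runnable.

**GSEA.** The weighted enrichment score with exponent w = 1 by default
(w is exposed; w = 0 gives the unweighted variant). Hits add
|s|ʷ/Σ_hits|s|ʷ, misses subtract 1/(p − N_H); the score is the signed
running-sum value of maximum magnitude. The walk's extremes occur only
immediately before and after hit positions, so the implementation
evaluates just those 2·N_H candidates in chronological order — magnitude
ties therefore resolve exactly as in a literal step-by-step walk. If every
hit score is exactly zero the hit increments fall back to 1/N_H. The
normalized-ES/FDR machinery of full GSEA is out of scope: the workflow
consumes ranks, not significance calls.

**SAM-GS.** Implemented literally as the Euclidean distance between the
two class centroids restricted to the effective set. The originally
published statistic is a moderated sum of squared t-like terms with a
fudge factor; the centroid-distance form is kept deliberately (it is the
description this framework evaluates), and the moderated variant would be
a straightforward extension.

**Global test.** The score-statistic form Q = zᵀXXᵀz/m, with X the N × m
submatrix of member genes standardized to mean 0, sd 1 across samples
(zero-variance genes dropped from m) and z = y − ȳ. Using the permutation
null instead of the asymptotic gamma approximation keeps all three methods
on one footing; the Bioconductor implementation of the asymptotic test can
serve as an external cross-check but is not a dependency.

Whether genes should be standardized before SAM-GS (they are not here) and
which GSEA weight the original comparative runs used are not recoverable
from the framework's description; both choices are documented defaults,
not claims about any historical run.

## Aggregation

All aggregation models obey a strict fit-on-train / apply-to-any contract.

* **AVG** — arithmetic mean of the member expressions; independent of
  other samples.
* **SVD** — the first right-singular direction of the training submatrix
  centered with the training per-gene means; any sample (train or test) is
  centered with those same means and projected. The direction's sign is
  fixed by making the largest-|loading| coordinate positive, so results
  are reproducible across linear-algebra back-ends. Training projections
  are mean-zero and their variance equals the leading covariance
  eigenvalue.
* **SetSig** — Pearson correlations of the sample's effective-set vector
  with every reference (training) sample, then the pooled-variance
  two-sample Student t of the class-0 vs class-1 correlation populations.
  Positive values mean "correlates with class 0". When a training sample
  is evaluated, it is excluded from its own class's population (its
  self-correlation of 1 would bias the contrast); this self-exclusion is a
  flag, default on, since the original description does not state it.
  Pooled rather than Welch variance is used, likewise as a documented
  default. Zero pooled variance returns 0 for equal means, else a ±10⁶
  cap. The statistic needs ≥ 3 effective genes and ≥ 2 references per
  class after exclusion.
* **None** — the deduplicated union of the selected sets' effective genes,
  in dataset gene order, passed through unaggregated.

## Generic feature selection

Information gain discretizes a continuous feature by the single best
binary split (thresholds at midpoints of consecutive distinct sorted
values, base-2 entropy) — the simplest scheme consistent with a one-line
"expected reduction in class entropy" definition. SVM-RFE trains a linear
soft-margin SVM (C = 1) on features standardized with training mean/sd
and repeatedly eliminates the feature(s) with smallest |weight|, ties
broken by feature index; the chunked schedule removes ⌊F·2⁻ⁱ⌋ features
(minimum 1) at iteration i, so F = 8 removes 4, 2, 1, 1. At the set
level, aggregation necessarily precedes generic ranking, since these
scorers see one value per feature.

## Workflow and factorial design

Each cross-validation fold ranks the collection on the training fold,
selects the sets named by the rank selector ("k" = the rank-k set, "1:10"
= top ten, "n−9:n" = bottom ten), fits the aggregation on the training
fold, reformulates both folds, trains the learner, and scores test
accuracy. Ranking inside the fold (rather than once on all data) is the
only option offered: ranking on the full dataset would leak test
information into feature selection. Folds are stratified by shuffling each
class and dealing round-robin — deterministic under the seed, per-fold
class proportions within one sample of the global proportion; classes
smaller than the fold count are tolerated with a warning.

Learner back-ends come from scikit-learn with near-default settings:
linear SVC (C = 1) on train-fitted z-scores, 1-NN and 3-NN with the
Euclidean metric on raw features, Gaussian naive Bayes, and a CART
decision tree with a two-sample leaf floor as a mild pruning stand-in.
Bit-compatibility with any other ML toolkit's implementations is not
attempted; all framework-level conclusions are relative comparisons under
a fixed learner, which such differences do not disturb.

The full factorial design — 2 collections × 3 rankers × 22 rank selectors
× 4 aggregations × 5 learners × 30 datasets × 10 folds — enumerates
792,000 workflow executions (79,200 fold-averaged measurements) plus
1,500 baseline executions (150 measurements). The runner derives each
configuration's seed from a master seed via CRC32 of the configuration
key, making grids reproducible, order-independent and resumable. The
default permutation count inside the workflow is 199: ranks stabilize
much faster than p-values, and the workflow consumes ranks.

## Evaluation statistics

Factor comparisons pair measurements equal in all factors except the one
under test and apply the Wilcoxon signed-rank test to fold-averaged
accuracy differences. Zero differences are dropped (the classical
convention; other treatments exist and would shift borderline p-values).
The exact distribution is used for n ≤ 25 pairs without ties in |d|,
otherwise the normal approximation with continuity correction.
Multiplicity uses the Bonferroni–Dunn adjustment min(1, p·m). Ranking
tables report median/mean/sd/IQR (linear-interpolation quantiles) pooled
over datasets and learners, and average sub-ranks within dataset × learner
cells (ties get average ranks; a complete design's sub-ranks average to
(n_combos + 1)/2). Gene-set group statistics report nominal size,
effective size, and the smallest number of principal components reaching
50% / 90% of a set's expression variance, compared across groups with
Mann–Whitney U (normal approximation with tie correction); the Bonferroni
factor defaults to (group pairs) × (4 metrics) and is recorded in the
output.

## Random control collections

For every genuine set Γ, a counterpart of the same size is drawn uniformly
without replacement from the pooled gene universe Σ (the union of all
member sets). Draws are independent across sets — a gene may recur in
several random sets, just as in curated collections. Degree-preserving
randomization (matching per-gene frequencies) is intentionally not
provided.

## Synthetic data: what it emulates and what it does not

The generator produces x = σ(√ρ·z_Γ + √(1−ρ)·ε) for member genes of each
set (one latent factor per set, giving exact within-set equicorrelation ρ
and variance σ²), i.i.d. N(0, σ²) background genes, and a +δ mean shift
on signal-set genes in class 1. Sets occupy disjoint gene blocks by
default; an overlap fraction can share genes between consecutive sets.
Defaults — 30 + 30 samples, 200 sets of 5–50 genes, 3 signal sets, δ = 1,
ρ = 0.3, σ = 1 — describe a moderately easy two-class study: a one-sd
shift concentrated in a few correlated sets, the regime set-level methods
are designed for. A variance-shift signal option exists but is not used by
the validation suites.

This construction is deliberately idealized: no probe effects, batch
effects, heteroscedasticity, heavy tails, or realistic pathway overlap
topology. Passing tests therefore demonstrate correctness of the
implementation and the qualitative behavior of the methods (calibrated
nulls, signal recovery, top-ranked > bottom-ranked, genuine > random) —
not performance claims about any real cohort.

## Validation suites and problem sizes

The test suite validates each statistic against an independent oracle
(brute-force running-sum walk for ES, covariance eigendecomposition for
SVD, an independently coded two-sample t for SetSig, exhaustive threshold
enumeration for information gain, exhaustive sign-flip enumeration for the
signed-rank test) and checks: null calibration (KS distance of permutation
p-values from U(0,1) below 0.08 over 500 null sets at B = 199), planted-set
recovery (the Global test ranks a δ = 1, ρ = 0.3, 20-gene set among 200
decoys first in ≥ 90% of 50 replicates at n = 30 + 30), the directional
benchmark findings on 5 synthetic datasets of 100 sets (paired one-sided
Wilcoxon p < 0.05 for top-vs-bottom ranks and genuine-vs-random
collections; negative accuracy-vs-rank slope), and a leakage guard
(perturbing test-fold labels leaves selected sets, fitted models and
predictions bit-identical). These problem sizes were chosen so the whole
suite runs in well under a minute of compute per heavy check on a single
CPU while keeping the statistical checks well-powered.

## Known limitations

* Binary phenotypes only (SetSig is inherently two-class; the harness
  follows suit).
* The Global test uses permutation p-values only; no asymptotic option.
* No internal cross-validation for choosing the number of feature sets;
  the rank selectors are fixed alternatives.
* Pathway-topology-weighted aggregation is out of scope.
* The decision tree is CART-based; classifiers from other toolkits will
  differ in detail.
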