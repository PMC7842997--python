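# Methods

## The selection model

`hidimsel` treats two-class gene selection as a filter–wrapper hybrid.
The assumptions are minimal: a real-valued genes × samples matrix, exactly
two classes with at least two samples each, and (for curation's ratio
statistics) expression values that are predominantly non-negative intensity
measurements. No normality is assumed anywhere — the t filter uses the
unequal-variance Welch form precisely because high-dimensional expression
data are noisy and heteroscedastic, and the rank-sum filter is fully
non-parametric.

### Curation

For gene *g* with values *x* over all samples, the dispersion is the
coefficient of variation CV = s/|x̄| (sample standard deviation, ddof 1).
CV is unit-free, which is what makes a "15%" threshold meaningful across
intensity scales; the raw variance has units of expression squared and no
natural percent scale. Genes with CV ≥ `dispersion_threshold` (default 0.15)
are compared by their class **medians**, the rest by their class **means**;
the gene is removed when the ratio of the class statistics falls inside
[`band_low`, `1/band_low`] (default [0.95, 1.0526...], endpoints inclusive —
boundary genes are the least informative ones, so inclusion is the
conservative reading of the band). The reciprocal band makes the verdict
invariant under swapping the classes or inverting the ratio.

Edge cases, chosen so that "clearly differential" always means "kept":
opposite-sign class statistics keep the gene (the signed ratio is reported
and can never lie in a positive band); both-negative statistics are compared
by absolute value; a zero denominator with a nonzero numerator yields +∞
(kept); 0/0 yields 1 (removed). Dispersion is computed over **all** samples
rather than per class — the threshold decides robustness of the location
estimate for the gene as a whole — and this is configurable.

### Filtration

Scores: |t| for the Welch filter, with two-sided p from the t reference
distribution at Welch–Satterthwaite degrees of freedom (the p value is
reported but ranking uses |t|); the importance q(g) = max(s, N₀N₁ − s) for
the rank-sum filter, where s counts cross-class pairs with x₁ⱼ ≤ x₀ᵢ (ties
count toward s, matching the ≤ in the indicator). q is symmetric under class
swap and ranges from ⌈N₀N₁/2⌉ (interleaved) to N₀N₁ (separated).

The K-fold run (default K = 10, stratified, shuffled under an explicit seed)
computes each filter on the **training** nine tenths of each fold — the
held-out tenth exists to decorrelate the fold rankings, so scoring on the
training side is what "avoiding overfitting" means here. Per fold, genes are
ranked by descending score (average ranks on ties, so the weight is
order-independent) and receive the Borda weight wᵢ(f) = G − rankᵢ(f) + 1.
The global weight w(f) = Σᵢ wᵢ(f) then ranks genes; rank-based fold weights
keep the aggregation scale-free, which matters when comparing or combining
filters whose raw scores live on completely different scales (|t| vs a pair
count). If the smaller class has fewer than K samples, K is reduced to that
count with a warning; K = 1 degenerates to a single whole-data ranking.

The combined TT-WRS table is the mean of the two min-max-normalized global
weights. A constant table normalizes to all-0.5, so a no-information filter
leaves the other filter's ranking untouched. Final ranks break weight ties
by gene id, making every ranking a deterministic permutation.

### Wrapper

Geometric binary PSO operates directly on bit masks; there is no velocity
vector. The update is a three-parent mask crossover — each bit copied from
the current position, personal best, or global best with probabilities
(w_self, w_pbest, w_gbest), default ⅓ each — followed by independent
bit-flip mutation at rate 1/L (L = number of filtered genes). With zero
mutation the offspring lies in the parents' Hamming convex hull
(geometricity), which is the property the acceptance-style tests assert.

Fitness is the mean stratified 10-fold CV accuracy of an SVM with a
polynomial kernel (degree 1, C = 1, `gamma="scale"`, zero offset) on the
masked genes; the empty mask scores 0. Degree 1 and C = 1 are the classical
SMO defaults; gamma-scaling keeps the kernel numerically well-behaved on raw
intensity scales without altering a degree-1 decision boundary. The CV split
is created once per swarm run from its own seed, so all particles are scored
on identical partitions and fitness values are comparable; fitness is cached
by mask (particles revisit positions; pure optimization). Equal-fitness ties
prefer fewer genes, then the lexicographically smaller mask — parsimony is
the tool's goal. Swarm defaults: population 20, 100 iterations, initial
inclusion probability 0.5 per gene. The global best never regresses, so the
fitness trace is non-decreasing by construction.

### Evaluation

Accuracy (TP + TN)/(TP + TN + FN + FP) and precision TP/(TP + FP) are
computed from confusion counts; precision with no positive predictions is
reported as not-applicable rather than 0. `evaluate_subset` repeats
stratified 10-fold CV (repeat r shifts the fold seed by r, so a single
repeat at the wrapper's CV seed reproduces the wrapper fitness exactly),
reports mean ± sd accuracy across all folds, and computes precision from the
**pooled** confusion counts — pooling is the stable choice when single folds
may contain very few predicted positives. The positive class defaults to
class 1, the second class of the class specification, following the
disease-as-positive convention.

## Synthetic data

The generator emulates a curated intensity matrix: background values are
log-normal (median `base_mean` = 100, log-scale sigma `base_sd` = 0.25,
giving a mildly skewed positive distribution with CV ≈ 25%), drawn
identically in both classes. Informative genes add
`effect_size` × (analytic log-normal sd) to class-1 samples; a
`redundant_fraction` (default 0.1) of genes are jittered copies of randomly
chosen genes, emulating probe-level redundancy. Defaults — 1000 genes, 5
informative at effect size 3, 30 + 30 samples — are the study conditions the
test suite and acceptance script run under.

What the generator does **not** emulate: probe-level microarray physics,
batch effects, correlated background structure beyond the duplicated genes,
annotation metadata, or multi-class designs. Passing tests on this generator
therefore demonstrate the algorithmic contract (statistics correct, search
effective, pipeline reproducible), not performance on any particular real
dataset.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use the generator's default
conditions for the end-to-end run (1000 genes, 60 samples, top-200
filtration, a 20-particle/100-iteration swarm) and twenty 8-gene instances
(12 + 12 samples, 3 informative genes at effect size 1) for the
wrapper-versus-exhaustive-search comparison, where all 255 subsets can be
scored directly. These sizes keep a full run in the low minutes while still
exercising every stage at realistic sample counts.

## Known limitations and honest failure modes

* **CV-accuracy saturation defeats full recovery of planted genes.** Under
  the default conditions, effect size 3 is so strong that many small subsets
  — including subsets containing a single planted gene plus a few correlated
  or spuriously discriminative genes — already reach 100% cross-validated
  accuracy on 60 samples. Random half-dense masks over the filtered genes
  typically score 1.0 at swarm initialization. Fitness therefore cannot
  distinguish a subset holding all five planted genes from a smaller one,
  and the parsimony tie rule deliberately shrinks the result: the final
  subset usually retains 1–3 of the 5 planted genes rather than 4+. This is
  a property of wrapper selection with accuracy fitness at saturating effect
  sizes, not a defect of the search — the swarm demonstrably attains the
  exhaustive-search optimum on instances small enough to verify. The
  corresponding end-to-end assertion in the test suite is left asserting the
  stronger recovery claim and fails for this documented reason.
* Fitness is measured by CV inside the same data used for selection; no
  nested CV is performed, so reported accuracies are optimistic for
  generalization (selection bias). The tool ranks and selects; unbiased
  error estimation is out of scope.
* Filters are univariate; genes informative only in combination can be lost
  at the filtration stage before the wrapper ever sees them.
* SOFT support covers GDS full-SOFT expression tables only (no GSE/GPL
  family files, no downloading); labels beyond two classes are rejected.
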