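# Methods

## Model

The classifier is an ensemble of K gene pairs operating on a single
sample's expression profile. For an unordered pair (a, b) define the
class-conditional ordering probabilities p₁ = P(Xₐ < X_b | poor) and
p₀ = P(Xₐ < X_b | good), estimated as unweighted empirical frequencies
on the training cohort with *strict* comparison (a tie is "not less
than"). The switch score is Δ = |p₁ − p₀| ∈ [0, 1]. The pair's vote
orientation follows the sign of p₁ − p₀: the ordering relatively
enriched in the poor class votes poor; at Δ = 0 the orientation is
`none` and the pair always votes good, so an uninformative pair can
never generate a spurious poor-prognosis call.

Pairs are ranked by Δ (descending), then by a secondary rank score γ,
then lexicographically by gene identifiers, giving a deterministic
total order. γ is the absolute between-class difference of the mean
within-sample rank gap: with each sample's full profile ranked
(average ranks on ties), γ = |E_poor[r(a) − r(b)] − E_good[r(a) − r(b)]|.
The primary statistic of the method is Δ; γ exists only to break exact
Δ ties, which are common because Δ takes values on a lattice of
1/(n₁·n₀) at small sample sizes. γ is always computed on the *full*
measured profile, never on a reduced candidate set, so greedy removal
of genes (below) does not perturb the scores of surviving pairs.

Greedy disjoint selection takes the top-ranked pair, removes its two
genes, takes the top pair among the remaining genes, and so on. Because
both Δ and γ depend only on the pair's own two genes (γ via the fixed
full-profile ranks), this is implemented as a single walk down the
ranked list skipping pairs that reuse a gene; the test suite checks the
equivalence against a literal rescore-after-each-removal
re-implementation. No backtracking or optimal disjoint matching is
attempted: the greedy order is part of the method's definition.

A sample's prognostic score is the number of pairs, among the first K,
whose observed ordering matches their poor orientation; the sample is
called poor when the score reaches the integer threshold τ ∈ [1, K].

## Model selection

K and τ are chosen by resubstitution on the training cohort. For each
K in a window (default 6–10, configurable), the training scores of the
first K pairs are computed; a threshold τ is admissible only if every
poor-prognosis training sample scores ≥ τ (training sensitivity
exactly 1.0 — the design premise that missing a true recurrence is the
costly error). Among admissible (K, τ) the pair maximising training
specificity is chosen; exact ties prefer the smaller K (parsimony),
then the larger τ. Since specificity is non-decreasing in τ, this is
equivalent to choosing the largest τ that preserves perfect
sensitivity. If some poor sample collects zero votes at every K, no
admissible threshold exists and training fails with a per-K diagnostic
of minimum poor scores rather than silently relaxing the constraint.

Resubstitution is defensible here because each pair contributes a
single binary comparison: the score is a sum of K coarse features, not
a flexible fit. The resubstitution-AUC-versus-K curve (`auc_curve`,
default K = 1..15) is exported for inspecting the peak region when
choosing the search window; it plays no automatic role in selection.

## Evaluation

Confusion metrics use poor as the positive class. The ROC enumerates
all integer thresholds from max(score)+1 down to 0; its trapezoidal
area is required (and tested) to equal the normalised Mann–Whitney
statistic with ties counted ½. The AUC confidence interval is a
stratified percentile bootstrap: the poor and good samples are
resampled separately with replacement keeping class sizes fixed,
default 2000 replicates, seed mandatory so the interval is exactly
reproducible. The percentile method was chosen over BCa for
transparency; at the vote score's coarse granularity the difference is
immaterial.

Survival comparison uses the product-limit (Kaplan–Meier) estimator
and the two-group log-rank test with hypergeometric variance, referred
to χ² with 1 df; both are implemented directly (they are a dozen lines
each) and cross-checked against lifelines in the test suite. The
log-rank comparison in the performance report contrasts the *predicted*
groups — the clinically relevant question of whether the classifier's
calls separate survival. Cox regression is deliberately out of scope;
hazard-ratio results from any standard package can be attached to the
report externally.

## Synthetic cohorts

`generate_cohort` emulates the structure the pipeline consumes: a
signature-scale gene set (default 70 genes) in tens of samples per
class (default 40/40). Background genes are i.i.d. standard normal, so
every background pair is exchangeable with expected Δ = 0. A planted
pair occupies two reserved gene slots; per sample its ordering is drawn
Bernoulli(p_poor or p_good) and realised by swapping the two
background draws into the required order, leaving marginal value
distributions untouched — the signal lives purely in the ordering,
which is exactly what the classifier reads. Optional Gaussian jitter
(`noise_sd`, default 0) perturbs background genes only; it exists to
emulate extra measurement noise and cannot touch planted orderings.

`generate_survival` draws exponential event times with good-prognosis
hazard `baseline_rate` (default 0.006/month ≈ 10-year median time to
event, a realistic early-breast-cancer magnitude) and poor-prognosis
hazard multiplied by `hazard_ratio` (default 3), with independent
exponential censoring (default 0.003/month); `censor_rate = 0` yields
fully observed follow-up.

What the generator does **not** emulate: array intensity scales, probe
effects, gene–gene correlation, batch structure, or class-dependent
mean shifts. Green tests on these cohorts certify algorithmic
correctness (scoring, selection, thresholding, metrics), not clinical
performance on real cohorts, which additionally depends on assay
preprocessing upstream of this package.

## Numerical choices

* All pairwise comparisons are strict; ties vote good everywhere, for
  determinism and consistency (users who prefer randomised tie-breaking
  can jitter their data upstream).
* Rank sums are multiples of 0.5 and therefore exact in floating
  point; γ is computed as differences of exact sums divided once by
  class sizes, so its value is independent of summation order and the
  vectorised implementation agrees bit-for-bit with loop-based
  re-implementations.
* The ranked pair list is totally ordered (Δ desc, γ desc, gene ids);
  permuting samples or applying within-sample monotone transforms
  leaves it unchanged.
* Degenerate inputs fail loudly: empty classes, < 2 genes, 2·K
  exceeding the gene count, missing or non-finite expression values,
  misaligned phenotype tables. Nothing is imputed.

## Problem sizes used in the checked runs

The bundled verification script (`scripts/acceptance.py`) uses a
70-gene, 34 + 44-sample discovery cohort with eight planted pairs of
tapering strength (p_poor from 0.95 down to 0.60, p_good mirrored), a
307-sample validation cohort (153 poor / 154 good) from the same
process, a 2000-replicate bootstrap, and 200 replicates of the
planted-pair recovery experiment (one (0.95, 0.05) pair against 68
exchangeable background genes, 40 samples per class). These sizes match
the study design the synthetic generator emulates; the recovery
condition is the regime in which the top-scoring pair is expected to be
identifiable essentially always.

## Known limitations

* Binary endpoint only; no multi-class labels and no calibrated
  probabilities beyond the integer vote score.
* The published 8-pair signature ships as gene *lists*: the within-pair
  partner assignments were never published in machine-readable form,
  so `ktsp.published` marks the pairings unknown instead of guessing.
* Pair scoring is exhaustive over C(G, 2) pairs — appropriate for
  signature-scale gene sets (the intended use), quadratic in G for
  genome-wide matrices.
* The log-rank test assumes non-informative censoring and is reported
  without any multiple-testing correction.
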