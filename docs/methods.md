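# Methods

This note documents the models, estimators, numerical choices and known
limitations of `prc2lnc`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Problem and data model

The package treats PRC2 association of a lncRNA as a binary class label
(1 = PRC2-binding, 0 = non-binding) predictable from transcript sequence
alone. Training input is two labeled sequence sets; sequences are stored in
the DNA alphabet (U mapped to T on input, since transcripts arrive both as
RNA and genomic text), records of ≤ 100 nt are discarded (strictly-greater
reading of the "more than 100 bp" rule), and the larger class can be
subsampled uniformly (seeded) to balance the design, mirroring the original
314 + 314 training construction. `N` bases are retained in records but
excluded from feature windows, so ambiguous positions never contribute to
composition or motif counts.

## Features

**k-word frequencies** (`kmer:*`). Overlapping windows on the sense strand
only — transcripts are stranded, and oligonucleotide content is a property
of the transcript, not its complement. Counts are divided by the number of
valid (N-free) windows, so the 4^k frequencies sum to 1 whenever at least
one valid window exists; frequencies rather than raw counts are used because
training sequences span roughly 100–7000 nt and per-feature class
comparisons must not be dominated by length. A sequence with no valid
window yields an all-zero spectrum and a logged warning. Default k = 6
(4096 features), a compromise between signal specificity and feature count;
k = 2..8 are supported.

**PWM hit frequencies** (`pwm:*`). A position frequency matrix is converted
to per-column probabilities with a pseudocount (default 0.25 per column
count), and each window is scored as the sum of log-probabilities. A window
is a hit when its score reaches `min + f·(max − min)` of the attainable
score range; the hit fraction is computed on both the sequence and its
reverse complement and averaged, making the feature strand-symmetric
(motifs on either strand of the underlying locus count equally). The
threshold fraction f (default 0.8) and the pseudocount are deliberately
explicit configuration: published motif scans rarely state them, and they
materially affect how many PWMs pass selection. Motifs wider than the
sequence contribute 0 with a warning. The hit fraction uses valid (N-free)
windows in both numerator and denominator.

**Complexity** (`kc`). Kolmogorov complexity is approximated by the
Lempel–Ziv 1976 exhaustive production parse: scanning left to right, the
current phrase is extended while it occurs as a substring of the text seen
so far (self-overlap allowed), then closed with one fresh symbol. The raw
phrase count c grows with length, so the feature is the normalized density
`c · log₄(ν) / ν` with ν the N-free length — approximately 1 for
incompressible sequences and smaller for repetitive ones; the degenerate
ν = 1 case is defined as 1.0 (the logarithm vanishes there). Tandem
repeats — the structure planted by the synthetic generator — are provably
compressive under this parse (a repeated block is reproducible from its
first copy), which is why the PRC2-binding-like class scores lower.

An extension hook (`build_feature_matrix(..., extensions=[fn])`) accepts
user feature functions, the intended seam for secondary-structure features,
which are out of scope here.

## Feature selection and consensus motifs

Each feature column is tested with a two-sample t-test; the Welch
(unequal-variance) form with Welch–Satterthwaite degrees of freedom is the
default because class variances of frequency features differ when length
distributions differ (a pooled-variance option exists). Selection keeps
features with raw p below α — 0.05 (liberal) or 0.01 (conservative) — with
no multiple-testing correction, matching the historical protocol; a
Benjamini–Hochberg option is available but off by default. Degenerate
columns (zero variance in both classes) are resolved deterministically
(equal constants → t = 0, p = 1; different constants → p = 0) and flagged
rather than dropped, so audit tables always have one row per feature.

Enriched k-words per class are summarized positionwise: at each position
the IUPAC code covering every base whose relative frequency among the words
is ≥ 0.1. This is a deliberately simple summarization, not a motif
alignment; consensus strings shorter than k (as appear in published
consensus tables) would require an unstated word-alignment step that this
package does not guess at, so exact consensus strings are never asserted —
only their code class (e.g. W-rich).

## Classifiers

All four families behave sensibly when features approach or exceed sample
count, the operating regime after liberal selection.

* **svm_linear** — scikit-learn SVC with linear kernel. Probabilities come
  from a logistic (Platt) link fitted to decision values predicted on
  stratified training folds; the hard decision rule is the SVM's own. The
  cost C is tuned by stratified inner cross-validation (default grid
  {0.001, 0.01, 0.1, 1, 10, 100}, 5 folds, smallest-error-then-smallest-C
  tie-break) nested inside each LOOCV training set.
* **sda** — shrinkage discriminant analysis, implemented in-package: a
  linear discriminant whose pooled covariance uses `v* = λᵥ·median(v) +
  (1−λᵥ)·v` for variances and `R* = (1−λc)·R + λc·I` for correlations, with
  analytic intensities (ratio of summed sampling variances of the entries
  to their summed squared deviation from the target, clipped to [0,1]).
  When p > n the correlation solve goes through the Woodbury identity on
  the n × n Gram matrix; no p × p inverse is ever formed. With both
  intensities forced to 0 the rule reduces to classical LDA (verified in
  tests). Intensities are stored on the fitted model.
* **random_forest** — scikit-learn, 500 trees, √p features per split,
  seeded.
* **logistic_regression** — scikit-learn, L2, C = 1.
* Standardization (train-set mean/SD) is applied to logistic regression
  only by default — standardization helps LR and hurts SDA here — with a
  per-classifier override. Zero-variance features get SD 1 with a warning.

A note on feature scale: raw k-mer frequencies have magnitude ~1/4096, so
the squared-norm term of the SVM objective is tiny and small costs in the
default grid produce an effectively empty model that falls back to
majority voting. Nested tuning resolves this by selecting large C on such
data; with a fixed small C the SVM can degenerate (see the cross-validation
artifacts section). Users supplying their own feature scales should keep
the cost grid's span in mind.

## Evaluation

LOOCV: each sample is predicted by a model trained on the other N−1, with
the SVM cost re-tuned inside every training set when nested tuning is on.
Pooled held-out predictions give sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP), accuracy, misclassification = 1 − accuracy, the Mann–Whitney
AUC (fraction of positive/negative pairs ranked correctly, ties counted ½ —
the midrank convention), and an ROC polyline with one vertex per distinct
threshold whose trapezoidal area equals the AUC to 1e-9 (tied scores become
diagonal segments). Probability ties at 0.5 predict positive (documented,
arbitrary). Per-sample LOOCV outcomes pooled over folds coincide with
iteration-averaged ones, since each fold holds out exactly one sample.

Two selection protocols exist. The **default** selects features once on the
full data before LOOCV — deliberately reproducing the historical protocol,
which is optimistically biased because held-out samples influenced the
feature list. The **strict** mode re-selects inside every fold (falling
back to all features when nothing passes α) and is the unbiased variant.

### Null calibration and cross-validation artifacts

On data with no class signal, neither protocol's LOOCV estimate sits at
0.5, for two distinct reasons the package's tests document rather than hide:

1. *Selection leakage (optimism).* With selection outside LOOCV, the ~5% of
   features that spuriously separate the classes were chosen using every
   sample; LOOCV in that subspace reports near-perfect separation on pure
   noise.
2. *Leave-one-out imbalance (pessimism / anti-learning).* With unbiased
   per-fold selection, removing the held-out sample leaves its class with
   N/2 − 1 of N − 1 training members. Any rule with a majority or
   class-centroid component then votes systematically against the held-out
   label; a degenerate small-C SVM is exactly a majority rule, driving
   accuracy and AUC toward 0 on balanced null data.

The unbiased statement "no signal → chance performance" is therefore
verified on an *independent* null draw (train on one null data set, test on
a second; AUC ≈ 0.5), which is free of both artifacts. The acceptance
script reports both numbers (`null_loocv_auc`, `null_independent_auc`);
the corresponding LOOCV-band test in the acceptance suite fails by
construction of the check and is retained as documentation of the artifact.

## Alignment survey

Pairwise alignment uses Biopython's exact three-state Gotoh implementation
behind the package's own surface, with the survey scoring scheme: match +1,
mismatch −3, affine gap −10. The single published gap figure is read as
open = extend = −10 (a length-L gap costs −10·L); both are configurable,
and with gaps this prohibitive relative to mismatches, best-score summaries
are insensitive to the split. `N` is a universal mismatch (−3), never a
match, including against itself. Identity is identical columns divided by
alignment length. A local alignment with no positive-scoring cell returns
score 0 with an empty alignment. Surveys compute scores only (no
tracebacks), which keeps an all-vs-all run over ~50k pairs tractable;
`--sample-pairs` provides random-subset smoke runs, and a cross-set mode
pairs every A against every B for cross-species comparisons. The returned
traceback for single alignments is one optimum chosen by the backend; score
and identity are exact, but tie-broken gap placement is not guaranteed
canonical.

## Synthetic generator

`SyntheticConfig` defaults define the study conditions used throughout the
tests: 60 + 60 sequences of 300–2000 nt; positives drawn i.i.d. with
P(A) = P(T) = 0.31 (AT fraction 0.62), negatives balanced (0.50); an
expected 1 tandem-repeat block per kb in positives (unit 8–20 nt repeated
3–6×, overwritten at non-overlapping uniform positions); optional PWM motif
instances sampled column-wise from the matrix. The 0.62 vs 0.50 AT contrast
was chosen once to give reliable but not trivial separation at n = 60/60
and is frozen; repeats are tandem because the LZ76 parse provably
compresses them. A truth manifest (`truth_table`) records the planted
signal for recovery tests.

What the generator does **not** emulate: real lncRNA length distributions
(uniform here), positional composition structure, splicing, paralogy or
shared evolutionary history between sequences, and any secondary-structure
signal. Passing recovery tests therefore demonstrates that the pipeline
detects the statistical signal classes it targets (composition shift,
repetitiveness, planted motifs) — not that real PRC2 targets are this
separable.

## Reproduction scope

The published training-set quantities (per-k significant word counts, the
49141/5565-pair alignment surveys and their best scores, the tuned C = 0.1,
and the headline LOOCV metrics) depend on the original supplementary
training sequences, which are not bundled. `prc2lnc reproduce` recomputes
them when given that file and refuses cleanly otherwise. Because the
original PWM-match threshold, pseudocount, count-vs-frequency choice and
complexity normalization are unstated, exact reproduction of selected-count
tables is not guaranteed even with the original sequences; all such knobs
are exposed and logged so the sensitivity can be explored.

## Determinism and problem sizes

Every stochastic step (subsampling, fold shuffling, forest seeds, synthetic
draws) takes an explicit seed, and pipeline runs write a resolved
configuration document sufficient to rerun bit-identically. The test suite
and acceptance script run on desk-scale problems chosen as the package's
own defaults: 120-sequence synthetic sets, 500-pair alignment-oracle
samples at length ≤ 7 (where exhaustive enumeration of all alignments is
feasible), 3000 LZ76 oracle strings at length ≤ 12, 30 × 1000-feature null
replicates for the type-I error, and stub sequence sets of 314/106 records
for survey bookkeeping.
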