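# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the tests do and do not establish.

## The two-tier model

**Tier 1 (CDAI).** Cancer vs. normal is decided by an affine score
`y_score = x₀ + Σᵢ xᵢ·Iᵢ` over preprocessed metabolite intensities,
thresholded at 0. The score is fit as an L2-regularized logistic regression
(`regularization` is sklearn's inverse penalty `C`, default 1.0; the family
is the package's realization of a generic parametric linear scorer — the
score it exposes is exactly the affine form above). With `balance=True`
(default) classes are weighted inversely to frequency, compensating the
cancer-heavy composition typical of screening cohorts. A score of exactly 0
is called cancer: in a screening context the tie should favour sensitivity,
and the event has measure zero for continuous scores.

Internally the solver standardizes each feature and the standardization is
folded back into `(x₀, x₁…xₙ)`, so the published coefficients apply to the
input intensity scale; this is purely a conditioning device (quantile-
normalized raw intensities span several orders of magnitude) and does not
change the model class.

**Tier 2 (TOOAI).** Tissue of origin is scored by 15 one-vs-rest linear
models; each class score is the sigmoid of its affine score,
`P(k) = 1/(1 + exp(aₖ + Σ yₖᵢ Iᵢ))`, reported without renormalization
across classes — the decision uses only the ranking, which renormalization
cannot change. The default family is a linear max-margin (SVM) bank; a
logistic one-vs-rest family is available. A small regularization grid
(C ∈ {0.01, 0.1, 1}) is selected by top-1 accuracy on an internal
stratified hold-out (25%), then refit on the full training set. Ties in the
score ranking break lexicographically by class label, making top-1/top-2
deterministic.

**Tiered contract.** Tier 2 only ever sees samples tier 1 called positive;
a tier-1-rejected sample never appears in tissue-of-origin output. The
pipeline driver enforces this and the tests audit it.

**Double-class accuracy.** A sample counts as correct when its true class
is among its two highest scores; the per-class sensitivity is
correct/tested within the class, and the pooled ("net") figure is
Σ correct / Σ tested — not the mean of per-class values; both are reported
because they differ under unequal class sizes. In the double-class
confusion matrix a rescued sample (truth = second guess) is credited to the
diagonal; when neither guess is right the sample is counted at
(truth, top-1), so each row sums to the class's sample count.

## Preprocessing recipes

* **Detection (tier 1):** prevalence filter (default `min_prevalence=0.1`;
  a named filtering step with no canonical threshold) → quantile
  normalization → uniform KNN imputation (k = 5).
* **Tissue of origin (tier 2):** log10 transform (pseudocount = half the
  smallest nonzero training intensity, the standard guard for
  zero-inflated intensities) → quantile normalization → per-feature
  standardization → *selective* imputation: training rows are imputed using
  only donors of their own class; test rows stay non-imputed and their
  missing cells enter the linear scores at the training mean (0 on the
  standardized scale). This keeps single-sample inference honest: nothing
  about a test sample is filled in from other test samples.

**Quantile normalization, single-sample form.** The training reference is
the positionwise mean of each training sample's sorted intensities (rows
with missing cells are interpolated onto the full quantile grid, so missing
cells never enter the pooling). Applying to a sample replaces each observed
value by the reference quantile at its within-sample rank; ties share their
averaged rank, and with m < n observed values ranks interpolate linearly
over the reference. For a complete, tie-free training sample this
reproduces classic pooled quantile normalization exactly, and the map is
idempotent. The reference pools all training rows (cancers and normals
together); pooling only normals was the alternative, but a screening
normalizer must be applicable before the label is known.

**KNN imputation semantics.** Distance between rows is the root-mean-square
difference over mutually observed features (pairs with none are infinitely
far); a missing cell is the mean of that feature over the k nearest donor
rows that observed it, all available donors when fewer than k exist.
Observed cells are never altered. At apply time, new samples draw donors
exclusively from the (already imputed) training pool. The implementation is
hand-written because the selective per-class policy and these exact
semantics are the contract the tests pin down against brute-force oracles.

## PLS-DA and feature ranking

PLS-DA fits partial least squares (NIPALS) against one-hot class
indicators. R² is the explained-variation fraction of the indicators on the
training data; Q² is the cross-validated analogue `1 − PRESS/SS` from
5-fold stratified CV (fold count is a package choice). Per-feature
importance is the sum over components of squared loading weights — a
VIP-like statistic chosen because it is deterministic and monotone in each
component's contribution; `plsda_reduce` keeps the top n by this statistic.
The permutation null (`permutation_q2`) refits under shuffled labels and
should hover at or below zero on signal-free data.

RFE refits a linear trainer and drops the feature with the smallest
absolute weight, one per round by default (a `step` option exists for large
matrices); ties break toward the lexicographically first feature id, making
the ranking a reproducible total order. The last survivor ranks 1.

## The synthetic cohort generator

The generator emulates what the analysis assumes about serum cohorts, with
every draw seeded:

* **Reference table** standing in for an HMDB-style lookup: uniform masses
  inside the 66.7–1000 Da scan range; ~10% drug- and ~10% plant-flagged
  entries (exercising the trimming step); per-metabolite baseline log10
  abundance ~ Normal(5, 1) and a characteristic retention time. Baselines
  live in the reference because they are properties of the metabolites, not
  of a cohort draw — the robustness harness depends on regenerating the
  *same* biology under new batch conditions.
* **Intensity model** (log10 scale): baseline + class shift + batch shift +
  Normal(0, 0.2) sample noise. The log-normal form matches the log10
  transform the tissue-of-origin recipe applies.
* **Class signatures:** each cancer class shifts 30 endogenous metabolites
  by +0.5 log10 by default, half of them a component shared by all cancer
  classes, half class-specific and disjoint between classes. The shared
  half models common metabolic reprogramming and is what gives the pooled
  cancers-vs-normal contrast a linear axis; this is structurally necessary,
  not a tuning knob — quantile normalization keeps only within-sample
  ranks, which are zero-sum, so purely class-specific signatures cancel in
  every pooled linear direction and no binary tier could work, contradicting
  the clean two-cluster PLS-DA separation observed on real sera. The
  class-specific halves carry the tissue-of-origin signal.
* **Mass error:** multiplicative Gaussian in ppm (default sd 5 ppm, the
  instrument's stated accuracy), so absolute error grows with mass;
  perturbed m/z values are clipped to the scan range, keeping peak counts
  deterministic.
* **Batch drift:** one Normal(0, `batch_shift_sd`) log10 offset per
  (batch, metabolite), drawn from a *separate* seed stream (`batch_seed`)
  so the robustness harness can regenerate the identical cohort under fresh
  batch perturbations only; with `batch_shift_sd = 0` the cohort is
  bit-identical for every `batch_seed`.
* **Dropout:** independent per (sample, metabolite) at `dropout_rate`
  (default 0.10, a typical untargeted-metabolomics missingness level), with
  an optional logistic tilt that makes dim peaks drop more often.
* **One peak per metabolite per sample:** the analysis operates at the
  named-metabolite level; isotopes, adducts and chromatographic peak shapes
  are out of scope.

What the generator does **not** emulate: correlated metabolite modules,
heavy-tailed or heteroscedastic noise, retention-time drift, adduct/isotope
interference, co-eluting isobars, or comorbidity structure. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that it
recovers planted signal under idealized independence assumptions — not that
real sera would yield the published performance.

## VLM alignment choices

Boxes are mass-only; retention time is carried through but unused for
matching (the alignment contract is defined on masses, and the synthetic
peaks have no RT drift to correct). A peak inside several overlapping
windows goes to the window with the smallest absolute ppm deviation from
center, exact ties to the lower-mass box (a total order ⇒ reproducibility);
several peaks landing in one box keep the maximum intensity (robust to
split peaks; sum differs only at plumbing level). Cells left empty at
assembly stay missing — gap filling is deferred entirely to the imputation
stage so that KNN imputation is not biased by a second filling mechanism.
Overlapping window pairs are counted in the box-set report.

## Cross-validation and reported statistics

Repeated random splits are stratified by the full class label (mirroring
partitioning "in comparable proportion" per class), default split fraction
0.5; the *entire* preprocessing recipe is refit on each training half, so no
statistic of any test sample leaks into a fit. Confidence intervals are
percentile (2.5/97.5) rather than normal-approximation because the metric
distributions near 100% are skewed. Sensitivity/specificity/accuracy are
computed exactly from integer confusion counts (as rationals) and rounded to
one decimal with round-half-even only at report time. ROC-AUC is the
tie-corrected rank statistic (Mann–Whitney U over n₊·n₋), invariant under
monotone score transforms.

The robustness harness regenerates a fixed panel (default per-class sizes
25/25/23/25/24/24/15/12/15/12/10/12/15/15/15) ten times under fresh batch
drift, scores each run with a frozen model and preprocessing state, and
reports per-class sensitivities plus the CV (sd/mean, sample sd) of the
pooled net sensitivity.

## Problem sizes and determinism

Desk-scale defaults: 300 reference metabolites for pipeline runs (a
scaled-down stand-in for the study's thousands of features), 500 for
alignment stress tests, cohorts of 40 samples per class. The null control
pools 100 cross-validation splits over four independently generated null
cohorts: with a single cohort the chance correlation frozen into that one
draw dominates the spread of the mean accuracy, while pooling estimates
chance-level behaviour across cohorts. All randomness flows from explicit
integer seeds; rerunning any pipeline or script with the same seed
reproduces outputs byte-identically.

## Known limitations

* The linear score cannot represent "union of class signatures" structure
  without a shared component; real cohorts whose cancers share no metabolic
  axis would defeat tier 1 by construction.
* Selective imputation leaves a training cell missing when its entire class
  lacks donors for that feature; such cells score at the training mean.
* The one-feature-at-a-time RFE is O(n²) model fits and is intended for
  reduced feature sets; use `step > 1` at larger scales.
* mzML ingestion flattens MS1 centroids without merging; noisy centroid
  lists should be intensity-thresholded upstream.
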