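# Methods

This note documents the statistical machinery in `galambda`: the model
and search procedure, the defaults and why they are set where they are,
what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Problem setting

The package targets binary classification in the small-sample,
high-dimensional regime typical of radiomics: on the order of a hundred
labeled cases (e.g., lymph-node metastasis present/absent) against
thousands of quantitative image features, most of which are redundant or
uninformative.  The goal is not raw discrimination but a *small, linear,
interpretable* feature combination: a logistic model on a handful of
features whose coefficients a clinician can read.

## Pipeline

1. **Preselection** (training rows only): a two-sided Mann–Whitney U test
   per feature (keep p < α, default α = 0.05, no multiplicity
   correction — a deliberately permissive screen), then iterative Pearson
   pruning: while any surviving pair has |r| ≥ ρ (default 0.8), examine
   the pair with the largest |r| and drop the member with the higher mean
   absolute correlation to all current survivors.  Largest-|r|-first
   scheduling makes the procedure deterministic; the removal rule keeps
   the feature that is less entangled with everything else.
2. **Feature-combination search** over the candidates (three methods,
   below).
3. **Logistic model** on the selected features, maximum likelihood with a
   ridge guard of 1e-6 (so tiny separable subspaces still yield a finite,
   deterministic fit; solved by Newton–Cholesky, exact for the n ≫ p fits
   that occur here).
4. **Evaluation**: pooled out-of-fold CV metrics on the training set,
   single-model metrics on the held-out set; trapezoidal AUC (identical
   to the concordant-pair estimator with ties counted ½); accuracy at the
   threshold maximizing the Youden index TPR − FPR (ties resolve to the
   lowest threshold); percentile bootstrap CIs (B = 100, 95%, resampled
   with replacement stratified by class); decision-curve net benefit
   NB(p_t) = TP/N − FP/N · p_t/(1 − p_t) on a default grid
   p_t ∈ {0.01, …, 0.60}.

## The lasso engine

The within-subspace combination search is the Gaussian lasso on the 0/1
response,

    min_{b,β}  Σᵢ (yᵢ − b − xᵢᵀβ)² / (2N) + λ‖β‖₁,

on column-standardized features (statistics from the fitting rows only,
applied to held-out rows).  The path runs over a 100-point geometric grid
from λ_max = max_j |x_jᵀ(y − ȳ)|/N (where everything is zero) down to
λ_max·10⁻³, solved by coordinate descent with warm starts along the
descending grid (scikit-learn's solver, tolerance tight enough that the
KKT subgradient conditions hold to well below 1e-7).  The squared-error
form rather than a binomial deviance path is a deliberate two-stage
design: the lasso only *ranks and prunes* combinations; the logistic
model is fitted afterwards to the surviving features.

Two guards control complexity:

* **df cap**: the path is truncated at the first λ (walking downward)
  whose solution exceeds `df_max` nonzeros, with `df_max` = ⌊n/10⌋ by
  default, switchable to ⌊n/5⌋ — the usual events-per-variable floor for
  clinical prediction models.  The cap also stops computation early, so
  the slow saturated tail of a p > n path is never solved.
* **CV selection**: 5-fold stratified CV produces a mean-squared-error
  curve on the shared grid; the selected features are the nonzeros at the
  MSE-minimizing λ (ties resolve to the larger λ, i.e., the sparser
  model).  On pure-noise data this min-MSE rule occasionally lands on an
  interior λ and admits a handful of spurious features — a known property
  of the rule (the usual motivation for one-standard-error variants), and
  the tests assert the majority behavior rather than a guarantee.

## The genetic search

An individual is a binary gene vector over the candidate features; a 1
means the feature is in the individual's *subspace* (not yet selected).
Fitness is 1 − (pooled 5-fold CV AUC) of the logistic model on the
features the cross-validated lasso picks within that subspace; an empty
selection scores chance (0.5).

**Initialization.**  Gene probabilities come from univariate fit quality:
per-feature R² of the least-squares fit of the outcome on the feature
(equal to the squared Pearson correlation), rank-mapped affinely onto
[0.2, 0.8].  A hard greater/less-than-0.5 rule would make every
individual identical, so a stochastic map is required; [0.2, 0.8] keeps
every feature possible in the initial population while biasing toward
marginally informative ones.

**Crossover (the core operator).**  Before mixing parental genes, each
parent's lasso path is read from the high-penalty end: walking λ from the
largest value downward, the first column with at least n nonzero
coefficients yields the top-n features by |coefficient| — the parent's
*excellent genes*, the features that survive the strongest shrinkage the
subspace admits.  The quota n is set per parent from its own CV error via
a schedule (nums, mses): the smallest MSE breakpoint at or above the
parent's minimum CV MSE decides; above all breakpoints the quota is 1.
The default schedule grants MORE excellent genes to better-fitting
parents — nums = (3, 2, 1) against MSE breakpoints at the 0.2/0.4/0.6
quantiles of the first generation's minimum CV errors — on the rationale
that a well-fitting subspace has more worth preserving.  The union of
both parents' excellent genes is forced to 1 in the offspring; every
remaining locus is inherited from a parent, the loci randomly split
half/half between the two.  Preservation is unconditional, so
well-regularized partial solutions are heritable; diversity comes from
the inherited half-genomes and mutation.

**Other operators.**  Tournament selection of size 2; elitism of 1 (the
best individual survives unchanged, making the best-fitness trace
monotone); bit-flip mutation at rate 1/nvars per locus, with the
excellent loci of the same generation exempt (set the rate to 0 for a
mutation-free variant).  Population 50 for 100 generations by default,
stopping after 25 generations without improvement; the replicated
benchmark uses population 30 over at most 40 generations, which is where
the search has typically converged at these problem sizes.  Fitness
evaluations are memoized by gene vector — the lasso and fold assignments
are deterministic given the stage seeds, so identical subspaces are never
re-evaluated.

**Baselines.**  The *standard GA* shares the representation and fitness
but uses plain uniform crossover (no excellent-gene preservation); its
selected set is the best individual's full gene set, which is why it
tends to carry more features and generalize worse.  The *conventional
lasso* runs one cross-validated lasso over all candidates and selects the
nonzeros at the MSE-minimizing λ.

## Filtering front end and texture features

Feature extraction works on a masked ROI of a 2-D grayscale image, on LoG
responses (zero-sum sampled kernel, radius 3σ, reflect boundary — the
response to a constant image is exactly zero and an impulse reproduces
the kernel), and on the subbands of two multiscale transforms:

* **Wavelet**: 3-level separable DWT, orthogonal Daubechies-4,
  *periodized* boundaries.  Periodization (rather than symmetric
  extension) is the one mode in which the orthogonal transform conserves
  energy exactly and level-k bands have sides exactly side/2^k; both
  properties are asserted in tests.  Components are numbered 1–3
  (level-1 horizontal/vertical/diagonal), 4–6 (level 2), 7–9 (level 3).
* **Contourlet**: a Laplacian pyramid (binomial 5-tap kernel with a
  polyphase interpolator whose branches each sum to one, so constants are
  reproduced exactly and the pyramid inverts exactly) followed by a
  directional split of each bandpass image into angular frequency wedges
  (8 at level 1, 4 at levels 2–3; 16 directional subbands).  The wedge
  masks are binary, Hermitian-symmetric, and partition the plane, so the
  subbands of a level are real and sum exactly to the bandpass image.
  This frequency-domain directional filter bank replaces an iterated
  quincunx/fan filter tree: only the forward transform feeds feature
  extraction, so directional perfect reconstruction machinery would buy
  nothing here.  Numbering: 1–8, 9–12, 13–16 by level.

Texture families (first-order, GLCM, run-length, gray-level difference,
size-zone, Amadasun–King neighborhood difference, neighborhood
dependency) operate on intensities quantized to Ng = 32 equal-width bins
between the in-mask min and max; out-of-mask pixels never enter any
matrix.  Distances default to {1, 3} and co-occurrence/run-length
statistics average the four principal directions.  Degenerate (0/0)
features on constant ROIs return their defined limit where one exists
(GLCM correlation → 1) and 0 otherwise; the tests ship a table of these
cases.  The "difference matrix" and "neighborhood difference matrix" are
implemented as two distinct families (gray-level difference histogram
vs. Amadasun–King), separately named.  Shape features use the largest
connected component: pixel-count area, scikit-image's weighted-boundary
perimeter estimator, circularity 4πA/P² under that estimator, and
major/minor-axis statistics.

## Synthetic data

The generator emulates the statistical shape of a radiomic feature
table, not its physics: block-correlated standard normals (compound
symmetry within declared blocks via a shared latent factor) with a
logistic outcome on a small planted subset (default: 180 samples, 300
features, 10 informative features with log-odds effects of magnitude 1.5
and alternating sign, intercept 0 for ~50% prevalence).  Planted indices
are returned for recovery scoring.  What it does *not* emulate: heavy
tails and skew of real texture features, nonlinear feature–outcome
links, scanner/operator batch effects, and the extreme p ≈ 5000 of a
full extraction.  Passing the benchmark therefore shows the search
behaves correctly under a known sparse linear signal — not that it will
rank methods identically on any particular clinical dataset.

Texture image fixtures (constant, checkerboard, gradient, smoothed
noise) are 8-bit, matching conventional ultrasound exports.

## Replicated benchmark

`galambda.benchmark` runs the three selectors head-to-head on
independent synthetic cohorts (180 samples split 6:4 stratified; each
selector sees training rows only; endpoint = held-out AUC of the
logistic model on the selected features).  The df cap uses the ⌊n/5⌋
setting here: with a 10-feature planted signal, the ⌊n/10⌋ cap (10
features at n = 109) binds the recovery count itself and would measure
the cap, not the selector.  The null arm uses the same conditions with
zero informative features; its reference band is the 95% interval of the
null AUC from the Mann–Whitney variance (n₁+n₀+1)/(12 n₁n₀) at the
test-set class sizes.

## Reproducibility

One global integer seed fans out to fixed per-stage offsets (split,
preselection, lasso folds, GA, evaluation folds/bootstrap, synthesis),
so stages are independently reproducible and a full pipeline run is
byte-identical under a fixed seed.  The GA's fitness folds and the
evaluation's CV folds share a seed by construction, which makes the
reported CV AUC of the GA-selected model equal 1 − fitness exactly.

## Known limitations

* The Gaussian-lasso + logistic two-stage design is a ranking heuristic;
  it inherits min-MSE's occasional interior optima on noise.
* The excellent-gene schedule is a design choice; the procedure is
  robust to it in our tests, but the (3, 2, 1)/quantile default is not
  claimed optimal.
* The contourlet is forward-only; do not use it where directional
  synthesis is needed.
* Feature extraction is 2-D, single-channel, single-ROI; no harmonization
  across scanners.
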