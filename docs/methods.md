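# Methods

## The problem

Consensus molecular subtypes (CMS1–4) partition colorectal cancers into four
transcriptome-defined groups: CMS1 (MSI/immune), CMS2 (canonical epithelial,
WNT/MYC), CMS3 (metabolic) and CMS4 (mesenchymal/stromal).  The original
consortium classifier was built on whole-transcriptome data from fresh-frozen
(FF) tissue, but clinical archives hold formalin-fixed paraffin-embedded
(FFPE) blocks whose degraded RNA suits targeted probe-counting panels
(NanoString-style CodeSets) better than sequencing.  `cmskit` implements a
panel-based, fixation-specific, single-sample CMS classifier: a new sample is
normalized against a fixed reference distribution for its fixation type and
scored by a weighted elastic-net multinomial model, with an explicit
"unclassified" outcome for low-confidence samples.

## Single-sample reference-quantile normalization

A `ReferenceDistribution` stores, per fixation type, the vector of target
quantiles `t_1 ≤ … ≤ t_p` over the panel's `p` genes: `t_r` is the mean
across reference samples of each sample's r-th smallest log2 value (the
standard quantile-normalization target; a median variant is available).  To
normalize a sample, its value at within-sample ascending rank `r` is replaced
by `t_r`.  Ranks are computed inside the sample alone — nothing about a
cohort enters — and no mean or median centering is applied afterwards.

Consequences that the tests exercise directly:

* **multiset conservation** — a tie-free normalized sample's values are
  exactly the target quantiles;
* **rank preservation** — gene ordering within a sample is untouched;
* **idempotence** — normalizing twice equals normalizing once;
* **monotone-distortion invariance** — any strictly increasing per-sample
  transformation (library-size scaling, an affine platform shift, a
  saturating response curve) leaves the output bit-for-bit unchanged,
  which is why no centering step is needed and why RNA-seq/microarray
  cohorts can co-train a NanoString-anchored model after per-sample
  alignment ("domain adaptation").

Ties receive the mean of the target quantiles over the tied rank span,
keeping the operation deterministic.  Raw counts are brought to the log2
scale as `log2(v + 1)` (pseudocount configurable); callers with data already
on the log2 scale take the `perform_log2=False` path and are only
quantile-normalized.  Genes missing from an input sample are a hard error;
an explicit opt-in imputes the reference median target and re-grids the
remaining targets, because silent imputation can mask panel mismatches.

## Weighted elastic-net multinomial classifier

The model is 4-class multinomial logistic regression with the elastic-net
penalty, minimizing

    (1/n) Σ_i w_i · NLL_i(β, β0)  +  λ [ (1−α)/2 ‖β‖₂² + α ‖β‖₁ ]

with weights rescaled to mean 1 and intercepts unpenalized (the glmnet
objective convention, so λ values are comparable to that toolchain's).
NanoString samples carry weight 1.5, co-training samples weight 1 — the
weighting that lets a small platform-matched training set dominate a large
cross-platform one.  The mixing parameter defaults to α = 0.7 for FF models
and α = 0.8 for FFPE models.  Genes are standardized internally with
weighted mean/sd and coefficients are mapped back to the input scale;
constant genes standardize to zero so the penalty drives their coefficients
to zero without special-casing.

The solver is scikit-learn's saga (proximal, produces exact zeros under the
L1 part), warm-started along a descending λ grid: λ_max is the smallest λ
with an all-zero solution (computed from the null-model gradient), and the
grid spans 4 decades (2 when p ≥ n) over 40 points.  Below λ = 1e-8 the
penalty is numerically negligible and an unpenalized lbfgs fit is used
instead, which is also the exact λ→0 maximum-likelihood limit the tests
check against the statsmodels `MNLogit` oracle.  When tallying active sets,
standardized coefficients below 1e-5 (solver precision at the default
tolerance 1e-4) count as zero.

### λ selection

λ is chosen by stratified k-fold cross-validation (default 10 folds)
minimizing the weighted misclassification error.  The 0/1 loss is coarse:
whenever the classes are separable over a stretch of the path, the CV error
is exactly tied at its minimum across many λ values, and the tie must be
resolved.  Resolving it toward the sparsest model returns heavily shrunk
coefficients whose probabilities cluster near uniform, so that almost no
sample clears the 0.6 confidence threshold — an unusable classifier even
though its argmax is perfect.  `cmskit` therefore breaks exact ties by the
weighted multinomial deviance (among equally accurate models, the
best-calibrated probabilities win) and only then prefers the larger λ.  Both
CV curves are kept in `training_meta` for audit.

### Prediction, threshold and confidence

Prediction composes the single-sample pipeline: optional log2 transform →
quantile normalization against the model's embedded reference → linear
predictors η_k = β0_k + β_kᵀx → softmax.  A sample is labeled with its
argmax class only when the maximum probability is ≥ 0.6 (configurable within
(0.25, 1]; at 0.25 or below every 4-class sample would trivially pass);
otherwise it is reported as NA/unclassified.  The confidence score is the
difference between the two largest probabilities.  Argmax ties are broken by
the fixed class order CMS1 < CMS2 < CMS3 < CMS4 and flagged.

## Selection-frequency panel reduction

Panel reduction is stability selection: per round, `n_reps` (default 1000)
repetitions each draw a stratified 80% of the NanoString samples, pool them
with all co-training samples, fit the elastic net, and record which genes
have any nonzero class coefficient; the held-out 20% of NanoString samples
yields the repetition's accuracy.  Genes with selection frequency below 0.5
are pruned and the procedure repeats until the round accuracy drops more
than 1 percentage point below the best round so far (the prior panel is then
returned), nothing is prunable, or a round cap is reached.  Co-training
samples are never held out — they model fixed auxiliary cohorts.

λ inside the resampling loop is fixed per round by one CV on the full pool
and reused across repetitions; re-running CV inside each of 1000 repetitions
would multiply the cost ~30-fold without changing which genes are stable.
Note that when the classes are widely separated the selected λ is small, the
fits are dense, every gene is selected in every repetition and no pruning
occurs — the procedure then correctly reports that the panel cannot be
reduced without an accuracy criterion ever triggering.  Frequencies
differentiate (and pruning begins) exactly when the data are noisy enough
that sparsity pays in CV.

## Evaluation: jointly-confident accuracy and nMCC

Predicted and reference label vectors are cross-tabulated over the full 5×5
space (CMS1–4 plus NA).  Accuracy is reported over jointly-confident samples
(non-NA in both vectors), mirroring how single-sample classifiers are
compared when each may abstain; an all-sample accuracy (NA counted as
disagreement) is also exported.  Because CMS cohorts are imbalanced, the
headline metric is the normalized Matthews correlation coefficient
nMCC = (MCC + 1)/2 ∈ [0, 1]: per class via one-vs-rest binarization, overall
via the Gorodkin multiclass MCC

    (c·s − Σ_k p_k t_k) / sqrt((s² − Σ p_k²)(s² − Σ t_k²)),

where c is the trace, s the total, and p_k, t_k the predicted/true class
totals.  A zero factor in any denominator defines MCC = 0 (nMCC = 0.5), the
standard convention for uninformative tables.  The multiclass form equals
the Pearson correlation of one-hot encodings with per-column centering, the
oracle the tests use; on 2×2 tables it reduces to the binary MCC.

## Synthetic cohort generator

The simulator produces the block structure the classifier exploits: gene
baselines uniform on 4–12 log2 units (a realistic abundance span for a
curated panel), disjoint marker blocks of `n_informative_per_class` genes
elevated by `effect_size` (default 2.0 log2 units ≈ 4-fold) in their
subtype, i.i.d. Gaussian noise (default sd 1.0 log2 units) and, optionally,
extra Gaussian noise emulating FFPE degradation, an overlap parameter for
markers shared between neighboring subtypes, and per-sample platform
distortions.  The reference study configuration used by the acceptance
checks is 100 samples per subtype over a 134-gene candidate panel with 12
markers per subtype.

Platform distortions are monotone per sample, matching how real platform
changes act on expression measurements: `affine` draws per-sample slope
(0.7–1.3) and offset (−2 to 2); `monotone-nonlinear` applies the fixed
saturating map x → 6 + x − 0.95·softplus(x − 4), i.e. a platform whose
response compresses the measured range to roughly 3.4 log2 units around a
higher offset, the way hybridization-style readouts flatten a sequencing
dynamic range.  Note an important negative result the generator makes
visible: a monotone map with locally uniform slope (e.g. mild compression
confined to the extreme top of the range) barely harms an un-normalized
linear classifier, because signal and noise within each gene scale together;
the benefit of quantile normalization shows against whole-range
compressions, which is why that is the default nonlinear emulation.

A count-scale variant (Poisson around 2^log2-mean) exists to exercise the
`perform_log2=True` path; the core generator works on the log2 scale
throughout since the entire classification pipeline is post-log2.

What the generator does not emulate: tumor purity and microenvironment
composition, gene–gene correlation beyond block membership, heavy-tailed or
count-overdispersed noise, missing genes, and probe-level artifacts.
Passing tests therefore demonstrate correctness of the pipeline's
operations and its invariances — not clinical-grade performance on real
cohorts.

## Numerical and design choices

* saga tolerance 1e-4 (1e-3 inside the resampling selection loop, where
  only the active set and argmax accuracy matter), max 2000 iterations,
  seeded; identical seeds and inputs give byte-identical model files.
* Model files are canonical JSON (sorted keys, full-precision floats) with
  a format-version field; loading re-materializes C-contiguous arrays so a
  round-tripped model predicts bit-identically.
* Labels, panels, matrices are plain TSV/CSV; "NA" is parsed literally,
  never as a missing value.
* Problem sizes in the test-suite and acceptance script (400-sample
  cohorts, 100-repetition selection rounds, 10-fold CV) are scaled-down
  analogues of the training designs the package targets, chosen so the full
  pipeline runs end-to-end on a laptop-class single core in minutes.

## Known limitations

* The elastic-net path is fit per λ with warm starts rather than by exact
  coordinate descent; coefficients agree with the penalized-likelihood
  optimum to solver tolerance, not bitwise with any other toolchain.
* Selection frequencies depend on the per-round fixed λ; under strongly
  separable data the procedure (correctly) declines to prune.
* The confidence threshold semantics (≥ 0.6 on the maximum probability) are
  calibrated for 4-class problems; the code does not generalize to other
  class counts.
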