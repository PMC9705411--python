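# Methods

## Scope and data model

The toolkit operates on Illumina methylation-array beta values — per-CpG
methylation fractions in [0, 1] — organized as a probes × samples
`BetaMatrix` with per-sample platform tags (450k, EPIC or synthetic).
Raw IDAT decoding and array normalization are upstream concerns: the
contract starts at a normalized beta matrix, a probe manifest
(chromosome, position, SNP and cross-reactivity flags) and a sample
sheet (label, cohort, coarse category).

Quality control follows array practice:

* **Sample QC** removes a sample when the fraction of probes with
  detection p ≥ 0.05 exceeds 5% (`QCConfig`, both thresholds
  configurable). The boundary is strict — a sample failing exactly 5%
  is retained — because the cutoff convention is not fixed by the
  protocol and a strict rule is the conservative reading.
* **Probe filtering** removes CpGs on chrX/chrY, SNP-associated probes
  and probes with reported cross-reactivity, preserving input order.
* **Platform merging** restricts to the probe intersection of 450k and
  EPIC matrices and concatenates samples; it is idempotent and
  symmetric up to ordering.

Downstream feature selection keeps the k = 20,000 most variant CpGs
(sample variance, denominator n−1) of whatever matrix it is given; ties
break by input probe order so results are deterministic. Inside
cross-validation the selection is refit on each training part only —
this is load-bearing for honest validation scores and is verified by a
poisoning test (a probe whose variance is driven by a single held-out
sample must not enter that fold's feature set).

## Class discovery

The cohort is embedded into two dimensions with t-SNE (perplexity 20;
4000 gradient iterations by default) and clustered with DBSCAN
(minPts 6). Points assigned to no dense region are NOISE and are
excluded from the reference set, mirroring how unstable or atypical
profiles are kept out of a diagnostic reference cohort.

**Neighborhood radius.** DBSCAN's eps is the one genuinely open
parameter. The classical heuristic — the knee of the sorted
minPts-nearest-neighbor distance curve — is implemented
(`estimate_eps`, with a convexity and significance guard), but it is
unreliable on converged t-SNE output: within-cluster density decays
smoothly from core to rim, so the curve bends inside the within-cluster
distance range and the knee fragments clusters. The default `auto` rule
(`select_eps`) therefore treats eps as a model-selection problem:
candidate radii are taken from the upper quantiles of the k-distance
curve plus multiples of its maximum, each candidate is clustered, and
the radius maximizing the silhouette of the clustered points weighted
by the fraction of points clustered wins. Solutions clustering under
half the cohort or yielding a single cluster are ineligible; if nothing
is eligible the knee is used. eps remains directly settable everywhere.

**Stability statistic.** Robustness of a reference embedding is
quantified by repeated random downsampling to 80% of the cohort
(300 iterations by default): each retained subset is re-embedded and a
single Pearson r is computed between the concatenated (x, y) reference
coordinates and the concatenated re-embedded coordinates of the
retained samples. Because raw t-SNE output is only defined up to
rotation and sign, each re-embedding is **warm-started from the
reference coordinates** of its samples, fixing the frame so the
coordinate correlation is meaningful; warm restarts also run without
early exaggeration, since re-exaggerating a converged configuration
drives clusters apart instead of refining them. Under this scheme
downsampling at fraction 1.0 re-converges onto the reference
(r ≥ 0.999), the self-consistency limit the statistic should satisfy.
The correlation is invariant to global translation and scaling of
either coordinate set.

## Supervised classification with an Unknown class

The training set combines the discovered reference classes with an
"Unknown" class: from every coarse category of an out-of-scope tumor
pool, 5% of samples (at least one per non-empty category) are drawn
without replacement and labeled Unknown. Training a dedicated outlier
class on a *diverse* pool lets the classifier reject profiles outside
its reference spectrum — including tumor types never seen during
development — rather than force-assigning them.

Two model families are supported with their published grids:

* **SVM** (one-vs-one): linear and RBF kernels, cost C = 2⁰…2⁵, RBF
  gamma = 2⁻³…2³ / 20,000. Per-class scores come from Platt-scaled
  pairwise coupling (`SVC(probability=True)`, the same mechanism as the
  e1071 stack), so rows sum to 1 up to coupling tolerance.
* **Random forest**: ntree ∈ {500, 1000}, mtry = round(2⁻⁵…2⁵·√20,000)
  clipped to [1, p]. Scores are tree-vote fractions (with fully grown
  trees, per-tree class probabilities are one-hot, so the forest
  average is exactly the vote fraction) and sum to 1 exactly.

Hyperparameters minimize the **class-balanced multinomial
cross-entropy** over a stratified five-fold cross-validation:

    L = Σᵢ w_{yᵢ} · (−log max(p_{i,yᵢ}, 1e−15)) / Σᵢ w_{yᵢ},
    w_c = N / (K · n_c)

Inverse-frequency weights normalized to mean one make every class count
equally regardless of size; with equal class sizes L reduces to the
plain mean cross-entropy. Grid ties go to the first enumerated
combination (SVM: kernel → cost → gamma; RF: ntree → mtry). Fold
assignment is stratified by exact class label and keyed to *sample
ids*, not row positions — samples are also re-sorted canonically by id
before fitting, because Platt scaling's internal cross-validation is
order-sensitive — so the search result is invariant to input sample
order. The final model retrains on the full training set at the winning
combination, with feature selection refit on the full set.

## Calibration

Raw scores are mapped to probabilities by ridge-penalized multinomial
logistic regression fitted on the winner's **out-of-fold** scores
(resubstitution scores would be over-confident and miscalibrate). The
parameterization is the symmetric softmax (one penalized coefficient
vector per class, no reference class, intercepts unpenalized), so
permuting class columns permutes the calibrated output identically, and
in the infinite-penalty limit the model collapses to the empirical
class frequencies. λ is selected by internal 10-fold cross-validation
as the value with minimum mean multinomial deviance, over a descending
grid of 100 log-spaced values auto-scaled from the score–indicator
covariance (ridge has no finite null point, so the top of the grid is
inflated until effectively intercept-only — the same device glmnet uses
for α → 0). The sklearn↔glmnet penalty correspondence is C = 1/(N·λ).
The final prediction is the class with the highest calibrated score;
exact ties go to the first class in column order, with a warning.

## Evaluation protocol

Open-set performance is summarized by collapsing all in-scope class
predictions into one outcome versus Unknown:

* **sensitivity** — in-scope samples given any in-scope class;
* **specificity** — out-of-scope samples assigned Unknown, overall and
  per coarse category;
* **conditional accuracy** — class accuracy over in-scope samples not
  rejected as Unknown (the question a pathologist asks of the samples
  the tool actually classified);
* **ROC/AUC** of the continuous outlier score 1 − P(Unknown), the only
  monotone function of the calibrated output using all classes
  symmetrically. Threshold-swept ROC with trapezoid AUC equals the
  Mann–Whitney concordance probability with half-credit ties (verified
  against pair counting).

Reported proportions are rounded half-up to three decimals.

## Synthetic cohort model

The simulator generates cohorts whose structure matches what the
pipeline must handle, not the full complexity of real array data.

* **Background**: per-probe means drawn from a 50/50 mixture of
  Beta(2, 10) (low-methylated) and Beta(10, 2) (high-methylated)
  archetypes — the bimodal marginal of real arrays.
* **Classes**: each class flips its own `n_informative = 300` CpGs
  toward the opposite methylation state on the logit scale; the step is
  sized to shift the mean by `effect = 0.45` at the scale midpoint and
  the logistic squash keeps means inside (0, 1) without clipping.
  Informative sets are disjoint by default (`informative_overlap`
  raises difficulty).
* **Noise**: each value is Beta(μ·ν, (1−μ)·ν) around its sample-level
  mean with concentration ν = 50, the standard methylation noise model
  that respects [0, 1] by construction.
* **Purity**: every tumor profile is mixed with a shared normal profile
  at a per-sample tumor fraction uniform on [0.3, 1]; at purity 0 a
  sample is statistically indistinguishable from normal tissue.
* **Study design**: `simulate_split` produces a reference cohort
  (default 5 classes × 40 samples on 30,000 probes), held-out in-scope
  test samples (10 per class), and 4 out-of-scope categories
  (500 pool + 25 test samples each) of which 2 appear *only* in the
  test partition — the unseen-diagnosis condition for outlier
  detection. The pool size keeps the Unknown training class (5% per
  category, 50 samples) a substantial fraction of the reference set:
  outlier rejection by argmax needs an Unknown class comparable in
  scale to the in-scope classes, the proportion the original study
  design used. Platform tags and platform-private probe subsets
  (`platform_views`) exercise merging; manifest flags exercise probe
  filtering.

What the simulator does **not** emulate: genome-wide correlation
structure between CpGs, copy-number-induced beta shifts, batch and
chemistry effects, CpG-island hypermethylator phenotypes, or realistic
class imbalance. Passing recovery tests on this generator therefore
demonstrates that the machinery is correct and well-calibrated on
planted structure of realistic magnitude — not that real cohorts of
this size would yield equally clean classes.

## Numerical and scale choices

* Default seeds: embeddings 42; all stochastic operations take explicit
  seeds, and per-iteration seeds in the stability loop derive from one
  generator.
* t-SNE in tests and in the acceptance script runs at 1000 reference /
  250–300 warm-start gradient iterations: on cohorts of ~200 samples
  the optimization converges well before the 4000-iteration default,
  which remains the library default for full-scale use.
* Test/acceptance SVM grids are reduced (kernel × cost sweeps at fixed
  RBF gamma); the full published grids are the library defaults.
* ε = 1e−15 floors the log in the balanced loss; calibrated rows are
  softmax-normalized and checked to sum to 1 within 1e−9.
* Degenerate inputs: all-flagged manifests and all-noise assignments
  warn and return empty objects; single-sample variance, empty probe
  intersections, score/label mismatches and unseeable classes raise.

## Known limitations

* The discovery defaults (perplexity 20, minPts 6) target cohorts of a
  few hundred samples; much smaller cohorts violate the
  n > 3·perplexity precondition and need smaller perplexity.
* eps auto-selection assumes the embedding separates at least two
  groups; one-cluster data falls back to the k-distance knee.
* SVM probability coupling is order-sensitive at the 1e−3 level even
  with fixed seeds; canonical id-sorting makes results reproducible,
  but scores retain coupling tolerance (rows sum to 1 within 1e−6
  before calibration).
* The model archive stores the fitted sklearn estimator via joblib and
  is a runtime artifact, not a long-term interchange format; the
  feature list, calibration map and class order are plain text.
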