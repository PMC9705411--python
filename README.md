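# methylclass

A toolkit for DNA-methylation-array tumor classification, built around the
workflow used to resolve difficult sinonasal tumor diagnoses (including
sinonasal undifferentiated carcinoma, SNUC) from genome-wide beta-value
profiles:

1. **Class discovery** — probe filtering (sex chromosomes, SNP-associated
   and cross-reactive CpGs), 450k/EPIC merging, selection of the 20,000
   most variant CpG sites, t-SNE embedding (perplexity 20, 4000
   iterations), and DBSCAN clustering (minPts 6) with explicit noise
   points that are excluded from the reference set.
2. **Stability** — iterative random downsampling to 80% of the cohort
   with warm-started re-embedding; one Pearson r per iteration between
   reference and re-embedded coordinates quantifies how robust the
   discovered classes are.
3. **Supervised classification with an Unknown class** — an SVM or
   random-forest classifier over the discovered classes plus an
   "Unknown" outlier class trained on a 5% per-category draw from a
   diverse out-of-scope tumor pool. Hyperparameters are chosen by grid
   search under the class-balanced multinomial cross-entropy
   `L = Σᵢ w_{yᵢ}(−log p_{i,yᵢ}) / Σᵢ w_{yᵢ}`, `w_c = N/(K·n_c)`, in a
   stratified five-fold cross-validation with the top-20k variance
   selection refit inside every fold.
4. **Calibration** — ridge-penalized multinomial logistic regression
   fitted on the winner's out-of-fold scores (λ by minimum mean
   cross-validated deviance) maps raw scores to class probabilities;
   the final call is the class with the highest calibrated score.
5. **Open-set evaluation** — all in-scope class predictions collapse
   into one outcome against Unknown, giving outlier-detection
   sensitivity/specificity, per-category specificity, conditional
   (in-scope) accuracy, and the ROC/AUC of the outlier score
   `1 − P(Unknown)`.

Every stage runs on a built-in synthetic cohort simulator (planted
classes with class-specific differentially methylated CpGs, bimodal
background, Beta-distributed noise, tumor-purity dilution, platform
splits and held-out outlier categories), so the full pipeline is
testable without any external data.

## Worked example

```python
import methylclass as mc
from sklearn.metrics import adjusted_rand_score

split = mc.simulate_split(mc.SimConfig(seed=1))      # 5 classes x 40 samples + outliers
bm = mc.filter_probes(split.bm, split.manifest)

# discovery on the reference cohort
ref, _ = split.part("reference")
ref = mc.filter_probes(ref, split.manifest)
sub = mc.project(ref, mc.select_top_variant(ref, 20000))
emb = mc.tsne_embed(sub, perplexity=20, n_iter=1000, seed=42)
ca = mc.dbscan_cluster(emb, min_pts=6)
truth = split.truth.labels.loc[ref.sample_ids].to_numpy()
print(ca.n_clusters, adjusted_rand_score(truth, ca.labels.astype(str)))
# 5 1.0

rep = mc.stability_downsample(sub, emb, n_iterations=50, fraction=0.8,
                              seed=0, n_iter=300)
print(rep)
# stability over 50 iterations (fraction=0.8): median r = 0.999 (range: 0.998 to 0.999)
```

The discovered five classes match the planted ground truth exactly
(adjusted Rand index 1.0), and the downsampling statistic shows the
embedding is highly reproducible (median coordinate correlation 0.999).

Training and open-set evaluation:

```python
sheet = split.sheet.table
ref_ids  = sheet.index[sheet.cohort == "reference"]
pool_ids = sheet.index[sheet.cohort == "unknown_pool"]
test_ids = sheet.index[sheet.cohort == "test"]

ts = mc.assemble_training_set(
    bm.subset_samples(ref_ids), sheet.loc[ref_ids, "label"].to_numpy(object),
    bm.subset_samples(pool_ids), split.sheet, per_category_fraction=0.05, seed=1)
grid = mc.svm_grid(kernels=("linear", "rbf"), cost_exponents=(0, 5),
                   gamma_exponents=(0,), k_features=20000)
clf = mc.cv_grid_search(ts, grid, k_features=20000, folds=5, seed=1)

proba = mc.predict_beta_matrix(clf, bm.subset_samples(test_ids))
labels, conf = mc.predict_class(proba)
report = mc.evaluate_predictions(labels, proba, split.sheet.subset(test_ids))
print(report.summary())
# Evaluation report
#   outlier sensitivity : 1.000
#   outlier specificity : 1.000
#   conditional accuracy: 1.000
#   outlier-detection AUC: 1.0000
#   ...
```

On this strongly separated synthetic cohort the classifier assigns every
held-out in-scope sample to its true class and rejects every
out-of-scope sample — including the two outlier categories never seen in
training — as Unknown.

## Command line

```bash
methylclass simulate  --seed 1 --out-dir runs/sim
methylclass discover  --beta runs/sim/beta.tsv --manifest runs/sim/manifest.tsv \
                      --sheet runs/sim/samples.csv --out-dir runs/disc
methylclass train     --beta runs/sim/beta.tsv --manifest runs/sim/manifest.tsv \
                      --sheet runs/sim/samples.csv --small-grid --out-dir runs/train
methylclass predict   --model runs/train/model --beta test_beta.tsv --out-dir runs/pred
methylclass evaluate  --predictions runs/pred/predictions.tsv \
                      --sheet runs/sim/samples.csv --out-dir runs/eval
```

Each command echoes its full configuration (seeds included) into the
output directory and never mutates inputs. All artifacts are delimited
text (TSV/CSV).

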