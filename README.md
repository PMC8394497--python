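# t2asym

Contralateral T2-relaxometry radiomics for predicting progression from mild
cognitive impairment (MCI) to Alzheimer's disease.

## The problem

Subjects with MCI either remain stable (MCIs) or progress to Alzheimer's
disease (MCIp). Quantitative T2 maps of the brain carry tissue-level
information that conventional volumetry misses, and neurodegeneration is
often lateralised: the *difference* between a structure and its mirrored
counterpart can separate groups even when neither side does alone. This
package implements the full analysis chain for that hypothesis, for
researchers working with dual-echo spin-echo MRI and multi-region
segmentations:

1. **T2 mapping** — with two echoes Sa, Sb acquired at TE_a < TE_b under
   mono-exponential decay `S(TE) = S0 · exp(−TE/T2)`, the voxel-wise map is
   the closed form `T2 = (TE_b − TE_a) / (ln Sa − ln Sb)`.
2. **Atlas registration** — a rigid transform (Mattes mutual information,
   regular-step gradient descent, versor parameterisation) brings the
   anatomical-space segmentation into T2-map space; labels are resampled
   nearest-neighbour.
3. **Region features** — 38 per region: volume, 28 signal-distribution
   statistics (moments, percentile ladder, histogram entropy/energy,
   central-90% statistics, tail probabilities) and 9 texture features
   (intensity-weighted mass-scatter tensor, surface area, compactness,
   sphericity).
4. **Contralateral folding** — for each of 40 left/right pairs and each of
   the 37 signal/texture features: the pair mean `(f_L+f_R)/2` and the
   absolute difference `|f_L − f_R|`, giving 2960 derived columns, plus 83
   region volumes and 8 neuropsychological scores.
5. **Univariate screening** — two-sided Wilcoxon rank-sum per column with
   Benjamini–Hochberg q-values within each feature family; the lowest-p
   fractions per family (5% of signal/texture, 15% of volumes, all
   neuropsychological scores) form the multivariate selection pool.
6. **Classifier benchmark** — repeated stratified 80/20 holdout (default
   100 repeats) over pluggable feature-selection filters (Wilcoxon, t-test,
   Kendall τ-b, mRMR, L1-logistic path, forest/tree importance, IDI, NRI)
   and classifiers (KNN, L1-logistic, random forest, decision tree, linear
   SVM, naive Bayes, nearest-centroid, majority-vote ensemble, and a
   bootstrapped forward-stepwise logistic selector). Pooled out-of-sample
   accuracy, sensitivity, specificity, balanced error and ROC AUC are
   reported with percentile-bootstrap 95% CIs, alongside per-method feature
   selection frequencies.

Because clinical images cannot ship with the code, the package includes a
first-class **phantom cohort generator**: mirrored ellipsoidal regions with
known regional T2, known group effects and asymmetries, a known rigid
misalignment between echo and anatomical spaces, and group-shifted
neuropsychological scores. Every stage of the pipeline is validated against
this ground truth.

## Worked example

Simulate a 20-subject cohort with a strong planted asymmetry in the
hippocampus analog of the progressor group, build the analysis table, and
screen it:

```python
import numpy as np
from t2asym.phantom import PhantomSpec, simulate_cohort
from t2asym.t2map import compute_t2_map
from t2asym.features import extract_all
from t2asym.contralateral import assemble_table
from t2asym.stats import screen_features

spec = PhantomSpec(n_mcis=10, n_mcip=10, noise_sd=10.0,
                   effect_map={0: {"mean_shift": 20.0, "asym_shift": 30.0}},
                   seed=42)
subjects, cohort, atlas = simulate_cohort(spec)
features = {}
for s in subjects:
    t2 = compute_t2_map(s.echo_a, s.echo_b)
    features[s.subject_id] = extract_all(t2, s.labels_echo, atlas)
table = assemble_table(features, cohort, atlas)
print("table:", table.shape)
screen = screen_features(table)
print(screen.results.head(5)[["feature", "family", "p", "q"]].to_string(index=False))
```

prints

```
table: (20, 466)
                 feature         family        p        q
    hippocampus.mad.mean signal_texture 0.000011 0.000146
 hippocampus.max.absdiff signal_texture 0.000011 0.000146
    hippocampus.max.mean signal_texture 0.000011 0.000146
hippocampus.mean.absdiff signal_texture 0.000011 0.000146
   hippocampus.mean.mean signal_texture 0.000011 0.000146
```

The table has one `group` column plus 444 contralateral columns
(37 features × 2 modes × 6 pairs at phantom scale), 13 region volumes and
8 neuropsychological scores. The planted hippocampal effect dominates the
ranking — `hippocampus.*.absdiff` columns recover the planted left/right
asymmetry and `hippocampus.*.mean` the planted group shift, with
family-wise q-values far below the 0.05 significance threshold.

A command-line surface wraps each stage for shell use:

```bash
t2asym simulate --config spec.yaml --out cohort/ --seed 5
t2asym t2map --pd echo_a.nii.gz --t2w echo_b.nii.gz --te-a 10 --te-b 110 --out t2.nii.gz
t2asym register --fixed t2.nii.gz --moving anatomical.nii.gz --out transform.json
t2asym resample-labels --labels labels.nii.gz --transform transform.json \
    --reference t2.nii.gz --out labels_t2.nii.gz
t2asym features ... ; t2asym table ... ; t2asym univariate ... ; t2asym benchmark ...
```

## Layout

```
src/t2asym/
  phantom.py        synthetic dual-echo cohorts with ground truth
  t2map.py          two-point T2 estimation + fit quality
  registration.py   rigid registration and label resampling
  features.py       38-feature per-region registry and extraction
  contralateral.py  pair mean/absdiff folding, manifest, table assembly
  stats.py          Wilcoxon screening, Benjamini-Hochberg, demographics
  benchmark.py      repeated-holdout benchmark, filters, metrics
  cli.py            thin command-line surface
docs/methods.md     modelling assumptions, conventions, limitations
```
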