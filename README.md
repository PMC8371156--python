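# morphoscore

Single-cell morphological profiling for patient-derived fibroblasts:
multichannel feature extraction, per-cell logistic-regression probability
scoring, individual-level ROC biomarkers, and drug-rescue classification
by classifier transfer.

## The problem

High-content imaging of skin fibroblasts can reveal disease genotypes —
for example the Hereditary Spastic Paraplegia genes *SPAST* (spastin, a
microtubule-severing protein) and *SPG7* (paraplegin, mitochondrial) —
through subtle, distributed shifts in cell morphology. Single
hand-picked measurements (say, mitochondrial aspect ratio) capture only
a fraction of such a phenotype. This package implements the multivariate
alternative: measure many features per cell across several markers, let
a classifier combine them into one per-cell score, and do all inference
at the level of individuals.

## The method

Each segmented cell is described by **124 features**: 31 per marker
(nucleus stain, mitochondria/TOM20, acetylated α-tubulin, whole cell on
phase contrast), covering basic morphology (area, length, width,
roundness), intensity statistics, STAR intensity-distribution
descriptors (**S**ymmetry, **T**hreshold compactness, **A**xial,
**R**adial, plus a radial profile), and SER-style texture filters
(spots, holes, edges, valleys).

Cells of two groups coded y ∈ {0, 1} are scored by binary logistic
regression on standardized features x:

    p = σ(β₀ + βᵀ x),   σ(z) = 1 / (1 + e⁻ᶻ)

fitted by unpenalized maximum likelihood (tiny ridge fallback under
separation). The per-cell probability p ∈ [0, 1] is the cell's
resemblance to group 1. Each individual i is summarised by the mean
probability of their n_i cells,

    p̄_i = (1/n_i) Σ_c p_ic ,

and the group comparison (Student's t-test), the effect size
(fold = mean p̄ of group 1 / group 0) and the ROC/AUC are all computed
over individuals — the honest biomarker surface, since cells of one
person are not independent samples. A frozen case-vs-control model can
then be transferred to drug-treated patient cells: one-way ANOVA with
Tukey's HSD over {untreated control, untreated patient, treated patient}
individual means calls the treatment `rescued`, `partial` or
`not_rescued` per marker set.

Because real patient images are not redistributable, the package ships a
first-class synthetic generator: feature-table cohorts with planted
genotype shifts, per-individual random effects, correlated feature
families, batch offsets and a partially-reverting treatment — plus a
five-channel field-image renderer with ground-truth masks to exercise
segmentation and feature extraction end to end.

## Worked example

```python
from morphoscore import (CohortConfig, simulate_feature_table,
                         fit_cell_classifier, score_cells, marker_set_report)

cfg = CohortConfig(n_group0=9, n_group1=10, cells_per_individual=500,
                   effect_size=0.3, affected_count=40, individual_sd=0.3,
                   seed=1)
table = simulate_feature_table(cfg)                    # 9500 cells x 124 features
model = fit_cell_classifier(table, marker_set="combined")
report = marker_set_report(score_cells(model, table))
print(report)
```

prints (reformatted):

```
marker_set        combined
mean_probability  group0: 0.129   group1: 0.884
t                 -53.83          p: 1.96e-20
auc               1.0
fold              6.87
```

Controls average a probability of 0.13, patients 0.88: the planted
0.3-SD shift on 40 of 124 features, invisible to the eye feature by
feature, yields complete individual-level separation (AUC = 1.0) and a
6.9-fold group difference. The same cohort scored with the 31
mitochondrial features alone gives means 0.37 vs 0.66 (fold 1.8) —
combining markers amplifies the effect, which is the point of the
multivariate analysis.

The command line mirrors the library:

```sh
morphoscore simulate --seed 1 cohort.csv
morphoscore classify --marker combined cohort.csv model.json
morphoscore stats model.json cohort.csv report.json
morphoscore all --config pipeline.yaml runs/demo
```

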