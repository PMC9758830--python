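# hetgeo

Spatially informed intra-tumor heterogeneity (ITH) analysis for multi-region
tumor sequencing.

Multi-region sampling of a solid tumor answers two distinct questions: *how
heterogeneous is this patient's tumor overall?* (patient-wise ITH) and *how
variable is this gene, cell fraction, or protein across regions of the same
tumor?* (feature-wise ITH). Both answers are biased by where the samples were
taken: sites spread far apart look more different than sites drawn close
together. `hetgeo` implements an analysis framework that records 2D sampling
coordinates (in cm) alongside expression and mutation data and corrects for
sampling geometry, aimed at groups running multi-region RNA-seq / WES studies
of solid tumors (the framework was developed around hepatocellular carcinoma
cohorts but is tissue-agnostic).

## The scores

**Patient-wise.** Tumor samples are embedded with PCA (first `n = 15`
components, fit jointly on all tumor samples after `log2(TPM+1)`). For a tumor
with `m` regions and PC scores `x_i ∈ R^n`,

    Div(t) = (1/m) Σ_i √( Σ_j (x_ij − μ_j)² ),      μ = mean of the x_i

is the transcriptomic diversity, and with `Div(p)` the mean distance of the
sampling sites to their spatial centroid (physical diversity, cm),

    normalized diversity = Div(t) / Div(p)

is a per-cm heterogeneity rate that is no longer confounded by how dispersed
the sampling was. Tumors are classed low-/high-ITH at the cohort median. A
genomic analogue uses the median pairwise Jaccard distance between per-region
somatic variant sets.

**Feature-wise.** For each feature, a random-intercept variance-components
model (REML) splits variance into within-tumor `W` and between-patient `B`:

    ITVS = W / (W + B)

Hierarchical clustering of samples, cut into k = 1..P groups (P patients),
yields the PGOR curve — the fraction of patients whose samples co-cluster at
each cut — and

    CCS = 1 − AUC(PGOR) / (P − 1),     IHS = √(ITVS · CCS)

The integrated heterogeneity score IHS ∈ [0, 1] is binned at 0.25 / 0.50 /
0.75 into low / median / high / very-high ITH groups. Low-IHS features are
robust to single-region biopsy sampling.

**Downstream.** `subsample` quantifies estimator stability under restricted
sampling (CV and CD of diversity scores over all C(m, k) region subsets);
`signature` builds a prognostic gene signature restricted to low-ITH genes
(IHS < 0.25 → multi-cohort univariate Cox screen → bootstrap stability →
random-survival-forest combination search) and evaluates both its prognostic
power (median-split HR, log-rank, IPCW time-dependent AUC) and its ITH
robustness (median signature-gene IHS, discordant-tumor proportion, PGOR AUC).
A synthetic cohort generator (`synthio`) with known per-gene ground truth
makes every stage testable without any data download.

## Worked example

```python
from hetgeo import SimConfig, generate_cohort, DiversityModel, FeatureITHModel

cfg = SimConfig(n_patients=14, regions_per_patient=(3, 10), n_genes=300, seed=7)
cohort = generate_cohort(cfg)

div = DiversityModel(cohort.expression, cohort.meta, cohort.coords,
                     variants=cohort.mutations).fit()
print(div.summary())

ith = FeatureITHModel(cohort.expression, cohort.patients, log2_transform=True).fit()
print(ith.summary())
```

prints

```
Patient-wise ITH (diversity) results
========================================
tumors:            14
regions (total):   100
PCs used:          15
median Div(t):     2.102
median Div(p):     1.470 cm
median normalized: 1.576 per cm
high-ITH tumors:   7
low-ITH tumors:    7

Feature-wise ITH (IHS) results
==================================
features scored:      300 / 300
patients:             14
median IHS:           0.380
clustering:           complete linkage, euclidean
variance components:  reml

ITH bins:
  low        5
  median     273
  high       22
  very-high  0
```

The 14 tumors split 7/7 at the median normalized score; the median Div(p) of
1.47 cm says the typical sampling site sat ~1.5 cm from its tumor's sampling
centroid, and the normalized score of ~1.6 per cm is the transcriptomic
divergence rate after that geometry is divided out. On the same cohort,
`div.distance_correlations("transcriptomic", scope="pooled")` gives a pooled
within-tumor Spearman correlation of 0.67 between physical and transcriptomic
distance — nearby regions really are molecularly more alike, which is exactly
why the normalization matters. The per-gene IHS distribution (median 0.380)
places most genes in the median-ITH bin; the 5 low-ITH genes are the ones a
single biopsy measures reliably.

The same scoring runs from the shell:

```bash
hetgeo simulate --seed 7 --out cohort/
hetgeo diversity --expr cohort/expression.tsv --meta cohort/metadata.tsv \
    --coords cohort/coordinates.tsv --out div/
hetgeo ihs --features cohort/expression.tsv --meta cohort/metadata.tsv --out ihs/
```

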