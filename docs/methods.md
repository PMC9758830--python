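# Methods

This note records the models behind `hetgeo`, the defaults that matter, what
the synthetic generator does and does not emulate, and the numerical choices
made where the design was genuinely open.

## Patient-wise diversity

All tumor samples of a cohort are transformed `log2(TPM+1)`, filtered to
genes with TPM ≥ 1 in ≥ 20% of tumor samples, per-gene centered (no scaling),
and embedded by PCA. The first 15 components are used by default; when a
cohort cannot support 15 (`n_samples < 16`), `DiversityModel` clips the count
with a warning while the lower-level `fit_pca` raises unless asked to clip.
Transcriptomic diversity `Div(t)` is the mean Euclidean distance of a tumor's
PC score vectors to their within-tumor centroid; physical diversity `Div(p)`
is the same statistic on the sampling coordinates (cm). The "center point" is
the arithmetic centroid of the sampled points in both cases — tumors have no
other well-defined center once only sampled sites are known. The normalized
score `Div(t)/Div(p)` has units of 1/cm and is deliberately unit-sensitive;
coordinates are cm everywhere and readers reject non-numeric values rather
than coercing. A tumor whose sampling points coincide (`Div(p) = 0`) has an
undefined normalized score and raises rather than returning infinity.

The normalization presumes that molecular divergence grows roughly linearly
with physical distance over the sampled range — the regime in which dividing
by `Div(p)` leaves a dispersion-free rate. On real data this approximate
linearity is an empirical observation; the generator's gradient kernel (below)
reproduces it exactly, and the test suite uses that regime when checking that
the normalized score decorrelates from `Div(p)`.

Median splits assign `score > median → high`, ties to low. Per-sample scores
use the same rule for the concordance classification (uniformly low /
uniformly high / discordant tumors).

## Feature-wise ITH

`ITVS = W/(W+B)` comes from the random-intercept model
`value ~ 1 + (1|patient)` fit by REML (statsmodels MixedLM, BFGS with
`gtol = 1e-12`; with that tolerance interior REML solutions agree with the
balanced one-way ANOVA estimator to ~1e-12, and the method-of-moments ANOVA
estimator is the fallback for singular or failed fits). Variance estimates
are clipped at zero; a feature with zero total variance has no defined ITVS
and is excluded from IHS and the bins.

The clustering arm uses complete-linkage agglomerative clustering on
Euclidean dissimilarities (a single feature reduces to absolute differences;
multi-feature signatures are z-scored per feature first so no feature
dominates). Both linkage and metric are configurable and recorded in output
metadata; the defaults match the common `hclust` default. The tree is cut
into k = 1..P clusters; PGOR(k) is the fraction of patients whose samples all
share one label (PGOR(1) = 1 by construction, and the curve need not be
monotone). AUC(PGOR) uses the trapezoidal rule over unit steps in k, which
reproduces the perfect-signature value P − 1 exactly; `CCS = 1 − AUC/(P−1)`
and `IHS = √(ITVS·CCS)`. Patients contributing a single sample are dropped
from both the clustering and the PGOR accounting with a warning — concordance
is undefined for them — and they cannot enter ITVS either (every patient
needs ≥ 2 samples for a within-variance). IHS bins are half-open on the left
(`[0, 0.25), [0.25, 0.50), [0.50, 0.75), [0.75, 1.00]`).

Expression is scored on `log2(TPM+1)` (set `log2_transform=True` in
`FeatureITHModel`); bounded features such as immune-cell fractions are scored
as given. Per-feature results are independent of feature order and batch
partitioning.

The structure-free null (`nb_null_ihs`) draws counts i.i.d. per sample from a
negative binomial (mean and size parameterization, variance `m + m²/r`) with
no patient structure, then scores them like real features. Because such genes
have `B ≈ 0`, their IHS concentrates near 1; the gap between this null and
real genes is what justifies reading low IHS as genuine patient structure.
The NB parameters are explicit arguments (mean 50, size 2 in the tests) —
they are a reference condition, not a fit to any particular dataset.

Enrichment of a query set in an IHS ranking uses a weighted
Kolmogorov–Smirnov running sum with the low-IHS end at the head, hit weights
decaying linearly with rank position, and a permutation null over random
same-size query sets (one-sided toward the observed sign, `(hits+1)/(n+1)`).

## Subsampling (CV / CD)

For each subset size k, all C(m, k) region subsets are enumerated
lexicographically (or a seeded, deduplicated random draw when C(m, k) exceeds
the cap; the two modes agree when the draw saturates). The PCA basis is fit
once on the full cohort and held fixed for every subset: re-fitting per
subset would conflate basis rotation with sampling effects. The gold standard
α uses all m regions in the same basis. CV is the population (1/N) standard
deviation over the mean, CD the RMS deviation from α over the mean, both
exactly as defined; the single k = m subset has CD = 0 and no defined CV.

## Signature construction

Candidates are genes with IHS strictly below 0.25. The univariate Cox screen
requires p < 0.05 in *every* training cohort with a consistent hazard
direction; per-cohort expression is z-scored within cohort before fitting
(training cohorts mix platforms, so pooling raw scales would be meaningless).
The default screen fits each gene with lifelines; a vectorized efficient-score
test (Breslow ties, one-step HR `exp(U/V)`) is available and is the default
inside the bootstrap, where thousands of per-gene fits would otherwise
dominate the runtime. The score test's null calibration is itself under test.

Bootstrap stability resamples patients with replacement within each cohort;
a gene passes an iteration when significant with its reference direction in
every cohort, and survives with ≥ 80% passes of `n_boot = 2500` by default
(both configurable; the desk-scale tests use far smaller counts). The
combination search ranks stable genes by permutation variable importance
(drop in concordance when a column is shuffled) averaged over replicate
random survival forests, then compares nested top-j subsets (j up to 25) by
mean out-of-bag concordance, smaller subsets winning ties; a best OOB
concordance below 0.55 flags the selection as low-confidence. Exhaustive
search over all subsets of ~100 genes is combinatorially impossible;
importance-ranked nesting is the standard practice for forest-based signature
derivation.

The risk score is the multivariate Cox linear predictor
`Σ_g w_g · z(expr_g)` with weights from a penalized (ridge, 0.1) Cox fit on
pooled z-scored training data — chosen over forest-predicted risk for
portability and auditability; the rule is recorded in the serialized model so
alternatives stay pluggable. Evaluation median-splits the score within each
evaluation cohort (cut points are never carried over from training), reports
the high-vs-low HR with CI and log-rank p, and IPCW cumulative/dynamic
time-dependent AUC on a yearly grid to 5 years (clipped to each cohort's
follow-up range; cohorts declare their time unit). ITH robustness on
multi-region data reports the median signature-gene IHS, the discordant-tumor
proportion under a cohort-median split of per-region scores, and the PGOR
AUC of clustering samples on the z-scored signature sub-matrix.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
every parameter explicit and all randomness flowing through one seed with
named substreams (layout / coordinates / expression / mutations / survival),
so each component is independently reproducible and identical (config, seed)
pairs serialize bit-identically.

*Expression.* Log2-scale values are
`mu_g + b_pg + s_prg + eps_prg` with `b ~ N(0, σ²_between,g)` and within-tumor
variance `σ²_within,g` split by `spatial_fraction` between a spatially
structured field and white noise. Two field types are available:

- `exponential` (default): a Gaussian field with covariance
  `σ²_w · f · exp(−d/ℓ)` over the region coordinates. Its variogram is
  concave in distance, so diversity grows *sub-linearly* with sampling
  spread — under this kernel a purely spatial tumor has `Div(t) ∝ √Div(p)`
  and the normalized score still carries (inverse) dispersion dependence.
- `gradient`: a smooth linear field `g·r` with gradient SD
  `σ_w√f / ℓ` per cm, *shared across tumors* per gene. Divergence grows
  linearly with distance, which is the regime the normalization assumes, and
  sharing the gradient programs across tumors keeps the within-tumor
  variation in a low-dimensional subspace the 15-PC embedding can represent
  (biologically: macro-scale gradients such as core-to-edge oxygenation
  drive the same gene programs in every tumor). With per-tumor gradients the
  embedding preferentially captures the most dispersed tumors and re-biases
  the normalized score.

Emitted expression is `2^x − 1` clipped at 0, so the downstream
`log2(TPM+1)` re-transform is exact (the clip only bites for log2 values
below 0, rare at the default baseline of 4).

*Geometry.* Regions are placed uniformly in a disc (`tumor_radius` 3 cm) with
a minimum spacing of 0.5 cm enforced by rejection (bounded retries, then an
error), then scaled by a per-tumor dispersion multiplier drawn from
`dispersion_range` so tumors differ in physical diversity; spacing is checked
before scaling, so a zero multiplier legitimately collapses a tumor's sites.
Defaults (14 patients, 3–10 regions per tumor) mirror a realistic
spatially annotated multi-region study.

*Mutations.* Each tumor carries a trunk (100 variants) shared by all regions
plus private variants (30 per region on average) anchored at one region and
shared with region r at probability `exp(−d/ℓ_share)`, so Jaccard distance
grows with physical distance; a share range of 0 makes private sets disjoint.

*Survival.* Event times are exponential proportional hazards with linear
predictor `Σ β_g · z(mean tumor log-expression of g)` across patients and
baseline hazard 0.02 per month (median survival around 3 years with no
effects). Censoring is modeled as: each patient is independently censored
with probability `censoring_rate` (default 0.3), a censored patient's
observed time uniform on (0, T). This hits the configured rate exactly in
expectation without calibration loops. An all-censored draw warns and
regenerates with a fresh sub-seed a bounded number of times. No genes carry
survival effects unless `survival_effects` names them.

*What is not emulated:* library-size/technical noise, read-level data,
copy-number structure, subclonal phylogenies, multi-nodule (multi-focal)
architecture, and non-stationary between-patient covariance. Tests passing on
these cohorts demonstrate that the estimators recover the structure they
target under the stated model — not that real tumors satisfy that model.

## Problem sizes in the test suite

The suite runs everything at desk scale as a deliberate design choice:
variance-component recovery uses 250 patients × 5 regions; IHS parameter
recovery uses 300 genes spanning within-ratios 0.05–0.95 over 10 patients × 5
regions (Spearman ≥ 0.7 against truth); Cox calibration uses one 300-patient
cohort; the signature pipeline trains on three 150-patient cohorts with
reduced bootstrap and forest replicate counts. The full-scale defaults
(2500 bootstrap iterations, 10 forest replicates of 200 trees) remain the
library defaults.

## Known limitations

- Coordinates are 2D by contract; sampling outside one plane biases `Div(p)`
  downward and the normalized score upward.
- The efficient-score screen uses a one-step HR; genes with extreme effects
  have their HR magnitude (not direction or p-value validity) approximated.
- REML on severely unbalanced or near-singular designs falls back to the
  ANOVA estimator with a logged flag; ITVS for such features is
  method-of-moments, not REML.
- The PGOR curve depends on the linkage/metric choice in edge cases; results
  record both, and conclusions should avoid configurations where the linkage
  flips the answer.
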