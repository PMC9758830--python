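"""Feature-wise intra-tumor heterogeneity: ITVS, PGOR, CCS and the IHS.

For a feature measured across multi-region samples of several patients,
two complementary views of its intra-tumor heterogeneity are combined:

* **ITVS** (intra-tumor variability score) — the within-tumor share of the
  feature's variance, ``W / (W + B)``, from a random-intercept variance
  components model (``value ~ 1 + (1 | patient)``, REML). ``W`` is the
  residual (within-tumor) variance and ``B`` the between-patient variance.
  Low ITVS means the feature varies little across regions of a tumor
  relative to its variation between patients.

* **CCS** (clustering concordance score) — how well the feature co-clusters
  each patient's regions. Samples are hierarchically clustered and the tree
  is cut into k = 1..P groups (P = number of patients). At each cut the
  **PGOR** (patient group overall ratio) is the fraction of patients whose
  samples all fall in a single cluster. CCS = 1 − AUC(PGOR)/(P − 1), with
  the AUC taken by trapezoidal integration over unit steps in k. A feature
  that keeps every patient intact at every cut has AUC = P − 1 and CCS = 0.

* **IHS** (integrated heterogeneity score) — the geometric mean
  ``sqrt(ITVS * CCS)``, in [0, 1]. Low IHS marks features that are stable
  across regions of the same tumor; such features are robust to
  single-region biopsy sampling. Genes are conventionally binned at
  0.25 / 0.50 / 0.75 into low / median / high / very-high ITH groups.

The machinery is feature-agnostic: gene expression, immune-cell fractions,
or inferred protein activities all work, as long as each patient
contributes at least two samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

__all__ = [
    "itvs",
    "pgor_curve",
    "auc_pgor",
    "ccs",
    "ihs",
    "bin_ihs",
    "feature_ith_table",
    "nb_null_ihs",
    "ihs_enrichment_rank",
    "FeatureITHModel",
    "FeatureITHResults",
    "IHS_BIN_EDGES",
    "IHS_BIN_LABELS",
]

IHS_BIN_EDGES = (0.0, 0.25, 0.50, 0.75, 1.0)
IHS_BIN_LABELS = ("low", "median", "high", "very-high")


# ---------------------------------------------------------------------------
# variance components


def _moments_variance_components(values: np.ndarray, groups: np.ndarray):
    """One-way ANOVA method-of-moments estimator (unbalanced-safe).

    B = max(0, (MSB - MSW) / n0) with n0 = (N - sum n_i^2 / N) / (k - 1);
    W = MSW. Coincides with REML on balanced data with interior estimates.
    """
    labels, inverse = np.unique(groups, return_inverse=True)
    k = len(labels)
    n = np.bincount(inverse)
    N = int(n.sum())
    group_means = np.bincount(inverse, weights=values) / n
    grand = values.mean()
    ssw = float(((values - group_means[inverse]) ** 2).sum())
    ssb = float((n * (group_means - grand) ** 2).sum())
    msw = ssw / (N - k)
    msb = ssb / (k - 1)
    n0 = (N - (n**2).sum() / N) / (k - 1)
    b = max(0.0, (msb - msw) / n0)
    return msw, b


def itvs(values, patients, method: str = "reml"):
    """Within-tumor variance share of a feature: ``(W, B, itvs)``.

    Parameters
    ----------
    values
        Per-sample feature values (1-D, finite).
    patients
        Patient label per sample, aligned with ``values``.
    method
        ``"reml"`` fits a random-intercept model by REML (statsmodels
        MixedLM) and falls back to the method-of-moments ANOVA estimator on
        a singular or failed fit; ``"moments"`` uses the ANOVA estimator
        directly.

    Returns
    -------
    (W, B, itvs) : tuple of floats
        ``itvs`` is ``nan`` when the total variance W + B is zero
        (the score is undefined for a constant feature).
    """
    values = np.asarray(values, dtype=float)
    patients = np.asarray(patients)
    if values.ndim != 1 or values.shape != patients.shape:
        raise ValueError("values and patients must be aligned 1-D arrays")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    labels, counts = np.unique(patients, return_counts=True)
    if len(labels) < 2:
        raise ValueError("at least 2 patients required")
    if (counts < 2).any():
        raise ValueError(
            "every patient needs >= 2 samples for variance decomposition; "
            f"offending: {list(labels[counts < 2])}"
        )
    if np.ptp(values) == 0.0:
        return 0.0, 0.0, float("nan")

    w = b = None
    if method == "reml":
        try:
            import statsmodels.api as sm

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(values, np.ones((len(values), 1)), groups=patients)
                try:
                    # tight gradient tolerance: interior REML solutions then
                    # agree with the balanced ANOVA estimator to ~1e-12
                    res = model.fit(reml=True, method="bfgs", gtol=1e-12)
                except Exception:
                    res = model.fit(reml=True)
            w = float(res.scale)
            b = float(np.asarray(res.cov_re)[0, 0])
            if not (np.isfinite(w) and np.isfinite(b)):
                raise ValueError("non-finite variance estimates")
        except Exception:
            warnings.warn("REML fit failed or singular; falling back to method of moments")
            w = b = None
    elif method != "moments":
        raise ValueError(f"unknown method {method!r}")
    if w is None:
        w, b = _moments_variance_components(values, patients)

    w = max(0.0, w)
    b = max(0.0, b)
    total = w + b
    score = w / total if total > 0 else float("nan")
    return w, b, score


# ---------------------------------------------------------------------------
# clustering concordance


def _prepare_cluster_input(values, patients):
    """Drop single-sample patients; return (obs matrix, patient labels)."""
    patients = pd.Series(np.asarray(patients), name="patient")
    if isinstance(values, pd.DataFrame):
        mat = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        mat = arr[:, None] if arr.ndim == 1 else arr
    if mat.shape[0] != len(patients):
        raise ValueError("values and patients disagree on sample count")
    counts = patients.value_counts()
    singletons = counts.index[counts < 2]
    if len(singletons):
        warnings.warn(
            f"excluding {len(singletons)} patient(s) with a single sample "
            "from PGOR accounting"
        )
        keep = ~patients.isin(singletons).to_numpy()
        mat = mat[keep]
        patients = patients[keep].reset_index(drop=True)
    if patients.nunique() < 2:
        raise ValueError("PGOR needs >= 2 patients with >= 2 samples each")
    return mat, patients.to_numpy()


def pgor_curve(
    values,
    patients,
    linkage: str = "complete",
    metric: str = "euclidean",
    zscore: bool | None = None,
) -> np.ndarray:
    """Patient group overall ratio at every cut level k = 1..P.

    Samples are clustered by hierarchical agglomerative clustering
    (``linkage`` on ``metric`` dissimilarities; for a single feature the
    Euclidean metric reduces to absolute difference). For each k the tree
    is cut into k clusters; a patient counts as grouped iff all its samples
    share one cluster label. PGOR(1) = 1 by construction.

    ``values`` may be a 1-D vector (one feature) or a samples x features
    matrix (a signature); matrix columns are z-scored by default so no
    single feature dominates the metric (``zscore=False`` disables this).
    """
    mat, pats = _prepare_cluster_input(values, patients)
    if zscore is None:
        zscore = mat.shape[1] > 1
    if zscore and mat.shape[1] > 1:
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    P = len(np.unique(pats))
    Z = scipy_linkage(mat, method=linkage, metric=metric)
    out = np.empty(P, dtype=float)
    out[0] = 1.0
    for k in range(2, P + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        grouped = 0
        for pat in np.unique(pats):
            if len(np.unique(labels[pats == pat])) == 1:
                grouped += 1
        out[k - 1] = grouped / P
    return out


def auc_pgor(pgor) -> float:
    """Trapezoidal area under the PGOR curve over unit steps in k."""
    pgor = np.asarray(pgor, dtype=float)
    if len(pgor) < 2:
        raise ValueError("PGOR curve needs at least 2 cut levels")
    return float(np.trapezoid(pgor))


def ccs(pgor, n_patients: int) -> float:
    """Clustering concordance score: 1 − AUC(PGOR)/(P − 1), in [0, 1]."""
    if n_patients < 2:
        raise ValueError("CCS undefined for fewer than 2 patients")
    pgor = np.asarray(pgor, dtype=float)
    if len(pgor) != n_patients:
        raise ValueError("PGOR curve must cover k = 1..P")
    value = 1.0 - auc_pgor(pgor) / (n_patients - 1)
    return float(min(1.0, max(0.0, value)))


def ihs(itvs_value: float, ccs_value: float) -> float:
    """Integrated heterogeneity score: geometric mean of ITVS and CCS."""
    for name, v in (("itvs", itvs_value), ("ccs", ccs_value)):
        if not np.isfinite(v) or not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be finite and in [0, 1], got {v}")
    return float(np.sqrt(itvs_value * ccs_value))


def bin_ihs(value: float) -> str:
    """Four ITH groups with half-open bins [0,.25), [.25,.5), [.5,.75), [.75,1]."""
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"IHS must be in [0, 1], got {value}")
    for hi, label in zip(IHS_BIN_EDGES[1:-1], IHS_BIN_LABELS[:-1]):
        if value < hi:
            return label
    return IHS_BIN_LABELS[-1]


# ---------------------------------------------------------------------------
# tables and null distributions


def feature_ith_table(
    features: pd.DataFrame,
    patients: pd.Series,
    method: str = "reml",
    linkage: str = "complete",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Per-feature ITH table: W, B, ITVS, AUC(PGOR), CCS, IHS, bin.

    ``features`` is features x samples; ``patients`` maps sample id to
    patient. Values are scored as given — apply any variance-stabilizing
    transform (e.g. log2(TPM+1) for expression) beforehand. Features with
    zero total variance get ITVS/IHS = NaN and no bin. Results are
    independent of feature order and of how feature batches are split.
    """
    patients = patients.loc[features.columns]
    rows = []
    P = patients.nunique()
    for feat, vals in features.iterrows():
        v = vals.to_numpy(dtype=float)
        w, b, tv = itvs(v, patients.to_numpy(), method=method)
        if np.isfinite(tv):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curve = pgor_curve(v, patients.to_numpy(), linkage=linkage, metric=metric)
            auc = auc_pgor(curve)
            cc = ccs(curve, P)
            score = ihs(tv, cc)
            label = bin_ihs(score)
        else:
            auc = cc = score = float("nan")
            label = None
        rows.append((feat, w, b, tv, auc, cc, score, label))
    return pd.DataFrame(
        rows,
        columns=["feature", "W", "B", "ITVS", "AUC_PGOR", "CCS", "IHS", "bin"],
    ).set_index("feature")


def nb_null_ihs(
    n_genes: int,
    nb_mean: float,
    nb_dispersion: float,
    n_patients: int,
    regions_per_patient: int,
    seed: int,
    log2_transform: bool = True,
    method: str = "reml",
) -> pd.DataFrame:
    """IHS null distribution for structure-free negative-binomial genes.

    Counts are drawn i.i.d. per sample from NB(mean, dispersion) with no
    patient structure; patient labels are then assigned arbitrarily and IHS
    computed per gene. Because between-patient variance is zero by
    construction, these genes concentrate near IHS = 1; the distribution
    serves as a reference against which real (patient-structured) genes are
    judged heterogeneous or stable.

    ``nb_dispersion`` is the NB size parameter r (variance = m + m^2/r).
    """
    if nb_mean <= 0 or nb_dispersion <= 0:
        raise ValueError("NB mean and dispersion must be positive")
    rng = np.random.default_rng(seed)
    n_samples = n_patients * regions_per_patient
    p = nb_dispersion / (nb_dispersion + nb_mean)
    counts = rng.negative_binomial(nb_dispersion, p, size=(n_genes, n_samples)).astype(float)
    values = np.log2(counts + 1.0) if log2_transform else counts
    samples = [f"s{i:04d}" for i in range(n_samples)]
    features = pd.DataFrame(values, index=[f"null{i:05d}" for i in range(n_genes)], columns=samples)
    patients = pd.Series(
        np.repeat([f"p{i:03d}" for i in range(n_patients)], regions_per_patient),
        index=samples,
    )
    return feature_ith_table(features, patients, method=method)


# ---------------------------------------------------------------------------
# enrichment of a feature set in an IHS ranking


def ihs_enrichment_rank(
    query,
    reference: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
):
    """Weighted KS running-sum enrichment of ``query`` in an IHS ranking.

    ``reference`` maps feature id -> IHS; features are ranked ascending
    (ties broken by feature id) so the low-IHS end is the head of the list.
    Positive enrichment scores mean the query concentrates among low-ITH
    features. Significance is assessed by permuting the query membership
    (``n_perm`` random same-size feature sets), one-sided toward the
    observed sign.

    Returns ``(es, p_value)``.
    """
    query = list(dict.fromkeys(query))
    ref = reference.reset_index()
    ref.columns = ["feature", "score"]
    ref = ref.sort_values(["score", "feature"], kind="mergesort").reset_index(drop=True)
    features = ref["feature"].to_numpy()
    missing = set(query) - set(features)
    if missing:
        raise ValueError(f"query features absent from reference: {sorted(missing)[:5]} ...")
    if len(query) < 5:
        warnings.warn("query has fewer than 5 features; enrichment is unstable")

    N = len(features)
    # head-weighted position scores: hits near the low-IHS end contribute more
    pos_weight = (N - np.arange(N)).astype(float) ** weight_exponent
    is_hit = np.isin(features, query)

    def _es(hit_mask: np.ndarray) -> float:
        w = pos_weight * hit_mask
        hit_step = w / w.sum()
        miss_step = (~hit_mask) / float(N - hit_mask.sum())
        running = np.cumsum(hit_step - miss_step)
        i = int(np.argmax(np.abs(running)))
        return float(running[i])

    es = _es(is_hit)
    rng = np.random.default_rng(seed)
    nq = int(is_hit.sum())
    hits = 0
    for _ in range(n_perm):
        mask = np.zeros(N, dtype=bool)
        mask[rng.choice(N, size=nq, replace=False)] = True
        e = _es(mask)
        if (es >= 0 and e >= es) or (es < 0 and e <= es):
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return es, float(p)


# ---------------------------------------------------------------------------
# model / results wrappers


@dataclass
class FeatureITHModel:
    """Feature-wise ITH model over a multi-region cohort.

    Parameters
    ----------
    features
        Features x samples matrix (genes, cell fractions, protein
        activities, ...).
    patients
        Sample id -> patient id mapping covering every column.
    log2_transform
        Apply log2(x + 1) before scoring; use for TPM-scale expression,
        leave off for already-bounded features such as fractions.
    """

    features: pd.DataFrame
    patients: pd.Series
    log2_transform: bool = False
    method: str = "reml"
    linkage: str = "complete"
    metric: str = "euclidean"

    def __post_init__(self):
        missing = [c for c in self.features.columns if c not in self.patients.index]
        if missing:
            raise ValueError(f"samples without patient mapping: {missing[:5]} ...")
        if self.log2_transform and (self.features.to_numpy() < 0).any():
            raise ValueError("negative values are incompatible with log2(x+1)")

    def fit(self) -> "FeatureITHResults":
        values = self.features
        if self.log2_transform:
            values = np.log2(values + 1.0)
        table = feature_ith_table(
            values,
            self.patients,
            method=self.method,
            linkage=self.linkage,
            metric=self.metric,
        )
        return FeatureITHResults(model=self, table=table)


@dataclass
class FeatureITHResults:
    """Fitted feature-wise ITH scores with the usual accessors."""

    model: FeatureITHModel
    table: pd.DataFrame = field(repr=False)

    @property
    def median_ihs(self) -> float:
        return float(self.table["IHS"].median())

    def bin_counts(self) -> pd.Series:
        return self.table["bin"].value_counts().reindex(IHS_BIN_LABELS, fill_value=0)

    def low_ith_features(self, threshold: float = 0.25) -> list:
        sub = self.table[self.table["IHS"] < threshold]
        return list(sub.index)

    def summary(self) -> str:
        n = len(self.table)
        n_scored = int(self.table["IHS"].notna().sum())
        lines = [
            "Feature-wise ITH (IHS) results",
            "=" * 34,
            f"features scored:      {n_scored} / {n}",
            f"patients:             {self.model.patients.nunique()}",
            f"median IHS:           {self.median_ihs:.3f}",
            f"clustering:           {self.model.linkage} linkage, {self.model.metric}",
            f"variance components:  {self.model.method}",
            "",
            "ITH bins:",
        ]
        for label, count in self.bin_counts().items():
            lines.append(f"  {label:<10} {count}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
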