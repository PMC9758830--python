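"""Patient-wise intra-tumor heterogeneity from multi-region expression.

The patient-wise view asks "how heterogeneous is this tumor overall?".
Multi-region samples are embedded by PCA (fit jointly on all tumor samples
of the cohort, first 15 components by default), and each tumor's
**transcriptomic diversity** is

    Div(t) = (1/m) * sum_i sqrt( sum_j (x_ij - mu_j)^2 )

— the mean Euclidean distance of its m region score vectors to their
within-tumor centroid. Because more dispersed sampling inflates Div(t)
(expression similarity decays with physical distance), the score is
normalized by the **physical diversity** Div(p) of the sampling sites:

    normalized diversity = Div(t) / Div(p)

which removes the sampling-dispersion bias and leaves a per-cm measure of
molecular heterogeneity. Tumors are split into low-/high-ITH classes at
the cohort median. A parallel genomic view uses Jaccard distances between
per-region somatic variant sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from . import spatial

__all__ = [
    "filter_expressed_genes",
    "fit_pca",
    "PCAEmbedding",
    "transcriptomic_diversity",
    "dispersion_from_scores",
    "transcriptomic_distance",
    "transcriptomic_distance_matrix",
    "genomic_distance",
    "genomic_diversity",
    "distance_correlation",
    "normalized_diversity",
    "classify_ith",
    "concordance_classify",
    "DiversityModel",
    "DiversityResults",
]


def filter_expressed_genes(
    expr: pd.DataFrame, min_tpm: float = 1.0, min_fraction: float = 0.2
) -> pd.DataFrame:
    """Keep genes with TPM >= ``min_tpm`` in >= ``min_fraction`` of samples."""
    keep = (expr >= min_tpm).mean(axis=1) >= min_fraction
    return expr.loc[keep]


@dataclass
class PCAEmbedding:
    """Per-sample scores on the first ``n_pcs`` principal components.

    ``scores`` is samples x components; ``explained_variance`` is
    non-increasing. The embedding remembers the samples it was fitted on so
    downstream code can detect mismatches.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    n_pcs: int

    @property
    def samples(self) -> list:
        return list(self.scores.index)


def fit_pca(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    n_pcs: int = 15,
    log2_transform: bool = True,
    gene_filter: bool = True,
    min_tpm: float = 1.0,
    min_fraction: float = 0.2,
    clip_n_pcs: bool = False,
) -> PCAEmbedding:
    """PCA on all tumor samples of a cohort (centering only, no scaling).

    ``expr`` is genes x samples on TPM scale; ``meta`` is indexed by sample
    id with a ``tissue`` column — only ``tumor`` samples enter the fit.
    Values are log2(TPM+1)-transformed and per-gene centered before the
    decomposition. Requires ``n_pcs + 1`` samples; ``clip_n_pcs=True``
    instead clips ``n_pcs`` with a warning when the cohort is small.
    """
    tumor_samples = [
        s for s in expr.columns if s in meta.index and meta.loc[s, "tissue"] == "tumor"
    ]
    if not tumor_samples:
        raise ValueError("no tumor samples found in expression/metadata")
    values = expr[tumor_samples]
    if gene_filter:
        values = filter_expressed_genes(values, min_tpm, min_fraction)
    if log2_transform:
        values = np.log2(values + 1.0)
    n_samples, n_genes = len(tumor_samples), len(values)
    max_pcs = min(n_samples - 1, n_genes)
    if n_pcs > max_pcs:
        if clip_n_pcs:
            warnings.warn(f"clipping n_pcs from {n_pcs} to {max_pcs} (small cohort)")
            n_pcs = max_pcs
        else:
            raise ValueError(
                f"{n_samples} samples support at most {max_pcs} components; "
                f"requested {n_pcs} — use a smaller n_pcs"
            )
    mat = values.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(mat)
    return PCAEmbedding(
        scores=pd.DataFrame(
            scores, index=tumor_samples, columns=[f"PC{i+1}" for i in range(n_pcs)]
        ),
        explained_variance=pca.explained_variance_,
        n_pcs=n_pcs,
    )


def dispersion_from_scores(scores: np.ndarray) -> float:
    """Mean Euclidean distance of row vectors to their arithmetic mean."""
    scores = np.asarray(scores, dtype=float)
    centroid = scores.mean(axis=0)
    return float(np.linalg.norm(scores - centroid, axis=1).mean())


def transcriptomic_diversity(
    emb: PCAEmbedding, patients: pd.Series, patient: str
) -> float:
    """Div(t) for one tumor: mean distance of its PC scores to their centroid."""
    members = [s for s in emb.samples if patients.get(s) == patient]
    if len(members) < 2:
        raise ValueError(f"patient {patient!r} has {len(members)} embedded sample(s); need >= 2")
    return dispersion_from_scores(emb.scores.loc[members].to_numpy())


def transcriptomic_distance(a: pd.Series, b: pd.Series, log2_transform: bool = True) -> float:
    """1 − Spearman correlation between two expression profiles.

    Profiles are aligned on their shared genes (>= 3 required) and
    log2(TPM+1)-transformed; ties get average ranks. Identical profiles
    give 0, perfectly rank-reversed ones give 2.
    """
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("profiles share fewer than 3 genes")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if log2_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile: rank correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(1.0 - rho)


def transcriptomic_distance_matrix(
    expr: pd.DataFrame, samples, log2_transform: bool = True
) -> pd.DataFrame:
    """Pairwise 1 − Spearman distances between the given sample columns."""
    sub = expr[list(samples)]
    if log2_transform:
        sub = np.log2(sub + 1.0)
    rho = sub.corr(method="spearman")
    return 1.0 - rho


def genomic_distance(variants_a, variants_b) -> float:
    """Jaccard distance 1 − |A∩B|/|A∪B| between two variant-key sets."""
    a, b = set(variants_a), set(variants_b)
    union = a | b
    if not union:
        warnings.warn("both variant sets empty; defining Jaccard distance as 0")
        return 0.0
    return 1.0 - len(a & b) / len(union)


def genomic_diversity(variant_sets: Mapping[str, set]) -> float:
    """Median pairwise Jaccard distance across a tumor's regions."""
    regions = sorted(variant_sets)
    if len(regions) < 2:
        raise ValueError("genomic diversity needs >= 2 regions with variant sets")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = [
            genomic_distance(variant_sets[r1], variant_sets[r2])
            for i, r1 in enumerate(regions)
            for r2 in regions[i + 1 :]
        ]
    return float(np.median(d))


def _upper_triangle_pairs(phys: pd.DataFrame, mol: pd.DataFrame):
    shared = phys.index.intersection(mol.index)
    p = phys.loc[shared, shared].to_numpy(dtype=float)
    m = mol.loc[shared, shared].to_numpy(dtype=float)
    iu = np.triu_indices(len(shared), k=1)
    return p[iu], m[iu]


def distance_correlation(
    phys: Mapping[str, pd.DataFrame],
    mol: Mapping[str, pd.DataFrame],
    scope: str = "per-tumor",
    strong_trend_threshold: float = 0.30,
):
    """Spearman correlation between physical and molecular distances.

    ``phys`` and ``mol`` map patient id -> symmetric within-tumor distance
    matrix (matched sample indexing). ``scope="per-tumor"`` returns a
    per-patient table (rho, p, n_pairs, strong_trend when rho exceeds the
    threshold); tumors with fewer than 3 pairs get NaN. ``scope="pooled"``
    concatenates within-tumor pairs across tumors — never between-tumor
    pairs — and returns ``(rho, p, n_pairs)``.
    """
    if scope == "pooled":
        xs, ys = [], []
        for patient in sorted(set(phys) & set(mol)):
            x, y = _upper_triangle_pairs(phys[patient], mol[patient])
            xs.append(x)
            ys.append(y)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if len(x) < 3:
            raise ValueError("pooled correlation needs >= 3 pairs")
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue), int(len(x))
    if scope != "per-tumor":
        raise ValueError(f"unknown scope {scope!r}")
    rows = []
    for patient in sorted(set(phys) & set(mol)):
        x, y = _upper_triangle_pairs(phys[patient], mol[patient])
        if len(x) < 3:
            rows.append((patient, np.nan, np.nan, len(x), None))
            continue
        res = stats.spearmanr(x, y)
        rho = float(res.statistic)
        rows.append((patient, rho, float(res.pvalue), len(x), rho > strong_trend_threshold))
    return pd.DataFrame(
        rows, columns=["patient_id", "rho", "p", "n_pairs", "strong_trend"]
    ).set_index("patient_id")


def normalized_diversity(div_t: float, div_p: float) -> float:
    """Normalized diversity score Div(t)/Div(p); Div(p) must be positive."""
    if not div_p > 0:
        raise ValueError(
            "physical diversity is zero (coincident sampling points); "
            "the normalized score is undefined"
        )
    return float(div_t) / float(div_p)


def classify_ith(scores: pd.Series) -> pd.Series:
    """Median split of per-patient scores into {low, high}; ties go low."""
    if len(scores) < 2:
        raise ValueError("classification needs >= 2 patients")
    med = scores.median()
    if scores.nunique() == 1:
        warnings.warn("all scores identical; assigning every patient to 'low'")
    return pd.Series(np.where(scores > med, "high", "low"), index=scores.index, name="ith_class")


def concordance_classify(sample_scores: pd.Series, patients: pd.Series):
    """Per-tumor concordance of a per-sample score under a median split.

    Samples are labeled high/low at the cohort median (ties low). A tumor
    whose regions all fall on one side is uniformly low/high; a tumor with
    regions on both sides is discordant. Returns ``(labels, discordant
    proportion)``.
    """
    patients = patients.loc[sample_scores.index]
    med = sample_scores.median()
    sample_class = sample_scores > med  # True = high
    rows = {}
    for patient, idx in sample_scores.groupby(patients).groups.items():
        flags = sample_class.loc[idx]
        if flags.all():
            rows[patient] = "uniformly_high"
        elif not flags.any():
            rows[patient] = "uniformly_low"
        else:
            rows[patient] = "discordant"
    labels = pd.Series(rows, name="concordance")
    prop = float((labels == "discordant").mean())
    return labels, prop


# ---------------------------------------------------------------------------
# model / results


@dataclass
class DiversityModel:
    """Patient-wise ITH model for a spatially annotated multi-region cohort.

    Parameters
    ----------
    expr
        Genes x samples TPM-scale matrix.
    meta
        Sample metadata indexed by sample id (``patient_id``, ``tissue``).
    coords
        Coordinate table indexed by sample id (``x_cm``, ``y_cm``,
        ``patient_id``); must cover every tumor sample used.
    variants
        Optional per-sample variant-key sets for the genomic view.
    """

    expr: pd.DataFrame
    meta: pd.DataFrame
    coords: pd.DataFrame
    variants: Mapping[str, set] | None = None
    n_pcs: int = 15
    log2_transform: bool = True
    gene_filter: bool = True
    clip_n_pcs: bool = True

    def fit(self) -> "DiversityResults":
        emb = fit_pca(
            self.expr,
            self.meta,
            n_pcs=self.n_pcs,
            log2_transform=self.log2_transform,
            gene_filter=self.gene_filter,
            clip_n_pcs=self.clip_n_pcs,
        )
        patients = self.meta["patient_id"]
        rows = []
        for patient in sorted(patients.loc[emb.samples].unique()):
            members = [s for s in emb.samples if patients[s] == patient]
            if len(members) < 2:
                warnings.warn(f"patient {patient!r} has a single region; skipped")
                continue
            div_t = transcriptomic_diversity(emb, patients, patient)
            div_p = spatial.physical_diversity(self.coords, patient)
            norm = normalized_diversity(div_t, div_p)
            gdiv = np.nan
            if self.variants is not None:
                sets = {s: self.variants[s] for s in members if s in self.variants}
                if len(sets) >= 2:
                    gdiv = genomic_diversity(sets)
            rows.append((patient, len(members), div_t, div_p, norm, gdiv))
        table = pd.DataFrame(
            rows,
            columns=["patient_id", "m", "div_t", "div_p", "normalized", "genomic_div"],
        ).set_index("patient_id")
        table["ith_class"] = classify_ith(table["normalized"])
        return DiversityResults(model=self, table=table, embedding=emb)


@dataclass
class DiversityResults:
    """Per-tumor diversity scores, ITH classes, and correlation diagnostics."""

    model: DiversityModel
    table: pd.DataFrame = field(repr=False)
    embedding: PCAEmbedding = field(repr=False)

    def distance_correlations(self, kind: str = "transcriptomic", scope: str = "per-tumor"):
        """Spatial vs molecular distance correlation (per tumor or pooled)."""
        patients = self.model.meta["patient_id"]
        phys, mol = {}, {}
        for patient in self.table.index:
            members = [s for s in self.embedding.samples if patients[s] == patient]
            if len(members) < 2:
                continue
            phys[patient] = spatial.pairwise_physical_distance(self.model.coords, patient)
            if kind == "transcriptomic":
                mol[patient] = transcriptomic_distance_matrix(
                    self.model.expr, members, log2_transform=self.model.log2_transform
                )
            elif kind == "genomic":
                if self.model.variants is None:
                    raise ValueError("no variant sets supplied to the model")
                sets = {s: self.model.variants.get(s, set()) for s in members}
                mat = pd.DataFrame(0.0, index=members, columns=members)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for i, a in enumerate(members):
                        for b in members[i + 1 :]:
                            d = genomic_distance(sets[a], sets[b])
                            mat.loc[a, b] = mat.loc[b, a] = d
                mol[patient] = mat
            else:
                raise ValueError(f"unknown kind {kind!r}")
        return distance_correlation(phys, mol, scope=scope)

    def diversity_correlation(self, which: str = "raw"):
        """Pearson correlation of (raw or normalized) diversity with Div(p)."""
        col = {"raw": "div_t", "normalized": "normalized"}[which]
        res = stats.pearsonr(self.table[col], self.table["div_p"])
        return float(res.statistic), float(res.pvalue)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Patient-wise ITH (diversity) results",
            "=" * 40,
            f"tumors:            {len(t)}",
            f"regions (total):   {int(t['m'].sum())}",
            f"PCs used:          {self.embedding.n_pcs}",
            f"median Div(t):     {t['div_t'].median():.3f}",
            f"median Div(p):     {t['div_p'].median():.3f} cm",
            f"median normalized: {t['normalized'].median():.3f} per cm",
            f"high-ITH tumors:   {int((t['ith_class'] == 'high').sum())}",
            f"low-ITH tumors:    {int((t['ith_class'] == 'low').sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
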