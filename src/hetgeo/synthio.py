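"""Synthetic multi-region tumor cohorts with known ground truth.

Emulates the statistical structure of a spatially annotated multi-region
RNA-seq study so that every downstream stage (diversity, IHS, subsampling,
signature building) can be exercised without any external download:

* **Patient-clustered expression.** The log2-scale value for gene g,
  patient p, region r is ``mu_g + b_pg + s_prg + eps_prg`` with
  ``b ~ N(0, sigma_between_g^2)`` (between-patient) and a within-tumor
  term split into a spatially correlated Gaussian field s — covariance
  ``sigma_within_g^2 * spatial_fraction * exp(-d / spatial_range)`` over
  the region coordinates — plus white noise with the remaining
  within-tumor variance. Emitted expression is ``2^x - 1`` clipped at 0
  (TPM scale), so a log2(TPM+1) re-transform downstream is exact.

* **Sampling geometry.** Regions are placed uniformly in a disc of radius
  ``tumor_radius`` with a minimum spacing enforced by rejection, then
  scaled by a per-tumor dispersion multiplier so tumors differ in physical
  diversity (mirroring real cohorts where sampling spread varies).

* **Clonal mutations.** Each tumor carries trunk mutations shared by all
  regions plus private mutations anchored at one region and shared with
  neighbours under a distance-decay kernel, so Jaccard distance grows with
  physical distance.

* **Survival.** Exponential proportional-hazards event times with linear
  predictor ``sum_g beta_g * z(mean tumor expression of g)`` and
  independent censoring at a configured rate.

All randomness flows through one seed with named substreams per component
(layout/coordinates/expression/mutations/survival), so each component is
independently reproducible and identical (config, seed) pairs give
bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SyntheticCohort", "generate_coordinates",
           "generate_expression", "generate_mutations", "generate_survival",
           "generate_cohort"]

_SUBSTREAMS = {"layout": 0, "coords": 1, "expression": 2, "mutations": 3, "survival": 4}


def _rng(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _SUBSTREAMS[name], extra]))


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror a 14-patient HCC-like study.

    ``sigma_between`` / ``sigma_within`` are per-gene SDs on the log2 scale
    (scalar broadcasts to all genes). ``spatial_range`` (cm) is the
    distance-decay length of the within-tumor covariance kernel and
    ``spatial_fraction`` the share of within-tumor variance that is
    spatially structured. ``dispersion_range`` bounds the per-tumor
    multiplier applied to sampled coordinates. ``survival_effects`` maps
    gene name -> log-hazard coefficient per SD of mean tumor expression.
    """

    n_patients: int = 14
    regions_per_patient: int | tuple[int, int] = (3, 10)
    n_genes: int = 500
    baseline_log_mean: float = 4.0
    sigma_between: float | np.ndarray = 1.0
    sigma_within: float | np.ndarray = 0.5
    spatial_range: float = 2.0
    spatial_fraction: float = 0.5
    spatial_kernel: str = "exponential"
    tumor_radius: float = 3.0
    min_spacing: float = 0.5
    dispersion_range: tuple[float, float] = (0.5, 1.0)
    n_trunk_mutations: int = 100
    n_private_mutations: int = 30
    mutation_share_range: float | None = None
    baseline_hazard: float = 0.02
    survival_effects: Mapping[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("patient and gene counts must be positive")
        lo, hi = self.region_bounds()
        if lo < 2:
            raise ValueError("regions_per_patient must be >= 2")
        if hi < lo:
            raise ValueError("invalid regions_per_patient range")
        for name in ("sigma_between", "sigma_within"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.spatial_fraction <= 1.0:
            raise ValueError("spatial_fraction must be in [0, 1]")
        if self.spatial_range <= 0 or self.tumor_radius <= 0:
            raise ValueError("spatial_range and tumor_radius must be positive")
        if self.spatial_kernel not in ("exponential", "gradient"):
            raise ValueError(f"unknown spatial_kernel {self.spatial_kernel!r}")
        if self.n_trunk_mutations < 0 or self.n_private_mutations < 0:
            raise ValueError("mutation counts must be >= 0")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    def region_bounds(self) -> tuple[int, int]:
        r = self.regions_per_patient
        return (r, r) if isinstance(r, int) else (int(r[0]), int(r[1]))

    def gene_names(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def sigma_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        sb = np.broadcast_to(np.asarray(self.sigma_between, dtype=float), (self.n_genes,))
        sw = np.broadcast_to(np.asarray(self.sigma_within, dtype=float), (self.n_genes,))
        return np.array(sb), np.array(sw)


def _region_counts(config: SimConfig) -> list[int]:
    lo, hi = config.region_bounds()
    if lo == hi:
        return [lo] * config.n_patients
    rng = _rng(config.seed, "layout")
    return list(rng.integers(lo, hi + 1, size=config.n_patients))


def _patient_ids(config: SimConfig) -> list[str]:
    return [f"P{i+1:02d}" for i in range(config.n_patients)]


def generate_coordinates(config: SimConfig) -> pd.DataFrame:
    """Sampling-site coordinates per tumor (sample id -> x_cm, y_cm, patient_id).

    Points are drawn uniformly in a disc of radius ``tumor_radius``; a
    minimum pairwise spacing is enforced by rejection (bounded retries,
    then an error). Accepted points are then scaled by a per-tumor
    dispersion multiplier drawn from ``dispersion_range``, giving tumors
    with different physical diversity. Spacing is checked before scaling,
    so a multiplier of 0 legitimately collapses all points to the center.
    """
    rng = _rng(config.seed, "coords")
    counts = _region_counts(config)
    rows = []
    for patient, m in zip(_patient_ids(config), counts):
        mult = rng.uniform(*config.dispersion_range)
        pts = None
        for _restart in range(50):
            acc: list[np.ndarray] = []
            ok = True
            for _ in range(m):
                for _try in range(200):
                    r = config.tumor_radius * np.sqrt(rng.uniform())
                    th = rng.uniform(0, 2 * np.pi)
                    p = np.array([r * np.cos(th), r * np.sin(th)])
                    if all(np.linalg.norm(p - q) >= config.min_spacing for q in acc):
                        acc.append(p)
                        break
                else:
                    ok = False
                    break
            if ok:
                pts = np.array(acc)
                break
        if pts is None:
            raise RuntimeError(
                f"could not place {m} points with spacing {config.min_spacing} cm "
                f"in a disc of radius {config.tumor_radius} cm"
            )
        pts = pts * mult
        for i, (x, y) in enumerate(pts):
            rows.append((f"{patient}_R{i+1}", float(x), float(y), patient, mult))
    coords = pd.DataFrame(rows, columns=["sample_id", "x_cm", "y_cm", "patient_id", "dispersion"])
    return coords.set_index("sample_id")


def generate_expression(config: SimConfig, coords: pd.DataFrame | None = None):
    """TPM-scale expression plus the per-gene truth table.

    Returns ``(expression, truth)``: genes x samples DataFrame and a truth
    table with each gene's between/within SDs, the true within-ratio
    ``r_g = sigma_w^2 / (sigma_w^2 + sigma_b^2)``, and its survival effect.
    """
    if coords is None:
        coords = generate_coordinates(config)
    rng = _rng(config.seed, "expression")
    genes = config.gene_names()
    sb, sw = config.sigma_arrays()
    f = config.spatial_fraction
    # gradient programs are shared across tumors: macro-scale spatial
    # effects (e.g. core-to-edge oxygenation) drive the same gene programs
    # in every tumor, so the within-tumor subspace stays low-dimensional
    grads = rng.standard_normal((2, config.n_genes)) if config.spatial_kernel == "gradient" else None
    cols, blocks = [], []
    for patient in _patient_ids(config):
        members = [s for s in coords.index if coords.loc[s, "patient_id"] == patient]
        m = len(members)
        xy = coords.loc[members, ["x_cm", "y_cm"]].to_numpy(dtype=float)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        b = rng.normal(0.0, 1.0, size=config.n_genes) * sb
        z_spatial = rng.standard_normal((m, config.n_genes))
        eps = rng.standard_normal((m, config.n_genes)) * (sw * np.sqrt(1.0 - f))
        if f > 0 and config.spatial_kernel == "exponential":
            kernel = np.exp(-d / config.spatial_range)
            chol = np.linalg.cholesky(kernel + 1e-8 * np.eye(m))
            s = (chol @ z_spatial) * (sw * np.sqrt(f))
        elif f > 0 and config.spatial_kernel == "gradient":
            # smooth linear-gradient field: expression changes at a constant
            # rate per cm, so molecular divergence scales linearly with
            # physical distance (the regime the Div(t)/Div(p) normalization
            # assumes); gradient SD per cm is sigma_w*sqrt(f)/spatial_range
            s = (xy @ grads) * (sw * np.sqrt(f) / config.spatial_range)
        else:
            s = np.zeros((m, config.n_genes))
        log2_vals = config.baseline_log_mean + b[None, :] + s + eps
        blocks.append(log2_vals.T)  # genes x regions
        cols.extend(members)
    log2_mat = np.concatenate(blocks, axis=1)
    tpm = np.clip(np.exp2(log2_mat) - 1.0, 0.0, None)
    expression = pd.DataFrame(tpm, index=genes, columns=cols)
    var_b, var_w = sb**2, sw**2
    total = var_b + var_w
    with np.errstate(invalid="ignore"):
        r_g = np.where(total > 0, var_w / np.where(total > 0, total, 1.0), np.nan)
    truth = pd.DataFrame(
        {
            "sigma_between": sb,
            "sigma_within": sw,
            "r_g": r_g,
            "beta": [config.survival_effects.get(g, 0.0) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return expression, truth


def generate_mutations(config: SimConfig, coords: pd.DataFrame | None = None) -> dict[str, set]:
    """Per-sample somatic variant-key sets with a clonal trunk structure.

    Every region of a tumor carries its ``n_trunk_mutations`` trunk
    variants. Private variants (``n_private_mutations`` per region on
    average) are anchored at one region and shared with region r at
    probability ``exp(-d(anchor, r) / share_range)``, so nearby regions
    share more private variants and Jaccard distance grows with physical
    distance. A share range of 0 makes private sets disjoint.
    """
    if coords is None:
        coords = generate_coordinates(config)
    rng = _rng(config.seed, "mutations")
    share = config.mutation_share_range
    share = config.spatial_range if share is None else share
    bases = np.array(list("ACGT"))
    mutations: dict[str, set] = {}

    def _keys(n: int) -> list[str]:
        chrom = rng.integers(1, 23, size=n)
        pos = rng.integers(1, 10**8, size=n)
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        return [
            f"chr{c}:{p}:{bases[r]}:{bases[a]}"
            for c, p, r, a in zip(chrom, pos, ref_i, alt_i)
        ]

    for patient in _patient_ids(config):
        members = [s for s in coords.index if coords.loc[s, "patient_id"] == patient]
        m = len(members)
        xy = coords.loc[members, ["x_cm", "y_cm"]].to_numpy(dtype=float)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        trunk = set(_keys(config.n_trunk_mutations))
        sets = {s: set(trunk) for s in members}
        pool = _keys(config.n_private_mutations * m)
        for j, key in enumerate(pool):
            anchor = j % m
            sets[members[anchor]].add(key)
            if share > 0:
                p_share = np.exp(-d[anchor] / share)
                carry = rng.uniform(size=m) < p_share
                for i in np.flatnonzero(carry):
                    if i != anchor:
                        sets[members[i]].add(key)
        mutations.update(sets)
    return mutations


def generate_survival(
    config: SimConfig,
    expression: pd.DataFrame,
    patients: pd.Series,
    max_tries: int = 5,
) -> pd.DataFrame:
    """Per-patient (time, event) from an exponential proportional-hazards model.

    The linear predictor is ``sum_g beta_g * z(mean tumor log-expression of
    g)`` with z-scores taken across patients. Each patient is independently
    censored with probability ``censoring_rate``; a censored patient's
    observed time is uniform on (0, T_event). An all-censored draw triggers
    a warning and a bounded number of regenerations with fresh sub-seeds.
    """
    ids = sorted(patients.unique())
    effects = {g: b for g, b in config.survival_effects.items() if b != 0.0}
    missing = [g for g in effects if g not in expression.index]
    if missing:
        raise ValueError(f"survival effect genes absent from expression: {missing}")
    lp = np.zeros(len(ids))
    if effects:
        log_expr = np.log2(expression.loc[list(effects)] + 1.0)
        per_patient = log_expr.T.groupby(patients).mean().loc[ids]
        z = (per_patient - per_patient.mean()) / per_patient.std(ddof=0).replace(0, 1.0)
        lp = z.to_numpy() @ np.array([effects[g] for g in per_patient.columns])

    for attempt in range(max_tries):
        rng = _rng(config.seed, "survival", extra=attempt)
        rate = config.baseline_hazard * np.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        censored = rng.uniform(size=len(ids)) < config.censoring_rate
        time = np.where(censored, rng.uniform(size=len(ids)) * t_event, t_event)
        event = (~censored).astype(int)
        if event.sum() > 0:
            break
        warnings.warn("all patients censored; regenerating with a fresh sub-seed")
    else:
        warnings.warn("all-censored survival table returned after bounded retries")
    return pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(ids, name="patient_id")
    )


@dataclass
class SyntheticCohort:
    """A generated multi-region cohort with its ground truth."""

    config: SimConfig
    expression: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    coords: pd.DataFrame = field(repr=False)
    mutations: dict[str, set] = field(repr=False)
    survival: pd.DataFrame = field(repr=False)
    truth: pd.DataFrame = field(repr=False)

    @property
    def patients(self) -> pd.Series:
        return self.meta["patient_id"]

    def write(self, outdir) -> None:
        """Serialize every table as TSV (deterministic, diff-stable)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.expression.round(6).to_csv(out / "expression.tsv", sep="\t")
        self.meta.to_csv(out / "metadata.tsv", sep="\t")
        self.coords.round(6).to_csv(out / "coordinates.tsv", sep="\t")
        self.survival.round(6).to_csv(out / "survival.tsv", sep="\t")
        self.truth.round(6).to_csv(out / "truth.tsv", sep="\t")
        rows = [
            (s, *key.split(":"))
            for s in sorted(self.mutations)
            for key in sorted(self.mutations[s])
        ]
        pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]).to_csv(
            out / "variants.tsv", sep="\t", index=False
        )


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (expression, space, DNA, survival)."""
    coords_full = generate_coordinates(config)
    coords = coords_full[["x_cm", "y_cm", "patient_id"]]
    expression, truth = generate_expression(config, coords)
    mutations = generate_mutations(config, coords)
    meta = pd.DataFrame(
        {"patient_id": coords["patient_id"], "tissue": "tumor"}, index=coords.index
    )
    survival = generate_survival(config, expression, meta["patient_id"])
    return SyntheticCohort(
        config=config,
        expression=expression,
        meta=meta,
        coords=coords_full,
        mutations=mutations,
        survival=survival,
        truth=truth,
    )
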