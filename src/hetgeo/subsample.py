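"""Estimator stability under restricted sampling: CV and CD.

How many regions must be sampled before a tumor's diversity score becomes
trustworthy? For each subsample size k, every (or a seeded random draw of)
k-subsets of a tumor's regions is scored — raw Div(t) and the normalized
Div(t)/Div(p) — and two summaries are computed over the C(m, k) scores:

    CV = sqrt((1/N) * sum (x_i - mu)^2)  / mu     (representativeness)
    CD = sqrt((1/N) * sum (x_i - alpha)^2) / mu   (accuracy)

where alpha is the "gold standard" score from all m regions. Both use the
population (1/N) standard deviation as written. The PCA basis is fit once
on the full cohort and held fixed for every subset, so only within-tumor
membership changes — re-fitting per subset would conflate basis rotation
with sampling effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from . import spatial
from .diversity import PCAEmbedding, dispersion_from_scores, normalized_diversity

__all__ = ["enumerate_subsets", "cv", "cd", "subsample_experiment", "SubsampleReport"]


def enumerate_subsets(m: int, k: int) -> list[tuple[int, ...]]:
    """All k-subsets of range(m), in deterministic lexicographic order."""
    if k < 2:
        raise ValueError("subset size must be >= 2")
    if k > m:
        raise ValueError(f"cannot draw {k} regions from {m}")
    return list(combinations(range(m), k))


def cv(scores) -> float:
    """Coefficient of variation: population SD over the mean."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("CV needs >= 2 scores")
    mu = x.mean()
    if mu == 0:
        raise ValueError("CV undefined for zero-mean scores")
    return float(np.sqrt(np.mean((x - mu) ** 2)) / mu)


def cd(scores, alpha: float) -> float:
    """Coefficient of deviation: RMS deviation from the gold standard, over the mean."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 2:
        raise ValueError("CD needs >= 2 scores")
    mu = x.mean()
    if mu == 0:
        raise ValueError("CD undefined for zero-mean scores")
    return float(np.sqrt(np.mean((x - alpha) ** 2)) / mu)


@dataclass
class SubsampleReport:
    """Subsampling summary for one tumor at one subsample size k."""

    patient_id: str
    k: int
    n_combos: int
    scores: pd.DataFrame = field(repr=False)  # columns: raw, normalized
    cv_raw: float
    cv_norm: float
    cd_raw: float
    cd_norm: float
    alpha_raw: float
    alpha_norm: float


def subsample_experiment(
    emb: PCAEmbedding,
    coords: pd.DataFrame,
    patient: str,
    k_range,
    mode: str = "exhaustive",
    n_random: int = 500,
    seed: int | None = None,
    max_exhaustive: int = 100_000,
) -> list[SubsampleReport]:
    """CV/CD of raw and normalized diversity over region subsamples.

    ``emb`` is the full-cohort PCA embedding (held fixed); ``coords`` the
    coordinate table. For each k in ``k_range`` the tumor's regions are
    subsampled exhaustively when C(m, k) <= ``max_exhaustive`` (or always
    in ``mode="exhaustive"``), otherwise ``n_random`` distinct seeded
    subsets are drawn. The gold standard alpha uses all m regions.
    """
    members = sorted(
        s for s in emb.samples if coords["patient_id"].get(s) == patient
    )
    m = len(members)
    ks = list(k_range)
    if not ks or max(ks) > m:
        raise ValueError(f"k range exceeds the {m} available regions")
    missing = [s for s in members if s not in coords.index]
    if missing:
        raise ValueError(f"regions without coordinates: {missing}")

    scores_all = emb.scores.loc[members].to_numpy()
    xy_all = coords.loc[members, ["x_cm", "y_cm"]].to_numpy(dtype=float)
    alpha_raw = dispersion_from_scores(scores_all)
    alpha_norm = normalized_diversity(
        alpha_raw, spatial.physical_diversity(coords, patient)
    )

    rng = np.random.default_rng(seed)
    reports = []
    for k in ks:
        n_total = math.comb(m, k)
        if mode == "exhaustive" or (mode.startswith("random") and n_random >= n_total):
            if n_total > max_exhaustive:
                raise ValueError(
                    f"C({m},{k}) = {n_total} exceeds max_exhaustive; use random mode"
                )
            subsets = enumerate_subsets(m, k)
        elif mode.startswith("random"):
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < n_random:
                chosen.add(tuple(sorted(rng.choice(m, size=k, replace=False))))
            subsets = sorted(chosen)
        else:
            raise ValueError(f"unknown mode {mode!r}")

        raw = np.empty(len(subsets))
        norm = np.empty(len(subsets))
        for i, idx in enumerate(subsets):
            sel = list(idx)
            raw[i] = dispersion_from_scores(scores_all[sel])
            xy = xy_all[sel]
            div_p = float(np.linalg.norm(xy - xy.mean(axis=0), axis=1).mean())
            norm[i] = normalized_diversity(raw[i], div_p)

        if len(subsets) == 1:
            # k = m: the single subset IS the gold standard
            cv_raw = cv_norm = float("nan")
            cd_raw = cd_norm = 0.0
        else:
            cv_raw, cv_norm = cv(raw), cv(norm)
            cd_raw, cd_norm = cd(raw, alpha_raw), cd(norm, alpha_norm)
        reports.append(
            SubsampleReport(
                patient_id=patient,
                k=k,
                n_combos=len(subsets),
                scores=pd.DataFrame({"raw": raw, "normalized": norm}),
                cv_raw=cv_raw,
                cv_norm=cv_norm,
                cd_raw=cd_raw,
                cd_norm=cd_norm,
                alpha_raw=alpha_raw,
                alpha_norm=alpha_norm,
            )
        )
    return reports
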