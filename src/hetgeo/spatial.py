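"""Sampling-site geometry: pairwise physical distances and physical diversity.

Multi-region sampling records, for every tumor sector, 2D coordinates (x, y)
in centimeters on a fixed per-tumor coordinate frame. Two summaries are
derived from them:

* pairwise Euclidean distances between sampling sites within a tumor, and
* physical diversity Div(p), the mean distance of the sampling points to
  their arithmetic centroid — a measure of how dispersed the sampling was.

Coordinate frames are per tumor, so distances between samples of different
patients are never computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "pairwise_physical_distance",
    "physical_diversity",
    "pooled_within_tumor_distances",
    "distance_summary",
]

REQUIRED_COLUMNS = ("x_cm", "y_cm", "patient_id")


def _patient_coords(coords: pd.DataFrame, patient: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in coords.columns:
            raise ValueError(f"coordinate table lacks required column {col!r}")
    sub = coords.loc[coords["patient_id"] == patient]
    if len(sub) < 2:
        raise ValueError(
            f"patient {patient!r} has {len(sub)} sample(s) with coordinates; "
            "at least 2 are required"
        )
    bad = sub.index[~np.isfinite(sub[["x_cm", "y_cm"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"non-finite coordinates for sample(s): {list(bad)}")
    return sub


def pairwise_physical_distance(coords: pd.DataFrame, patient: str) -> pd.DataFrame:
    """Symmetric matrix of Euclidean distances (cm) between a tumor's sites.

    Parameters
    ----------
    coords
        Coordinate table indexed by sample id with columns
        ``x_cm``, ``y_cm``, ``patient_id``.
    patient
        Patient whose tumor sites to compare; at least two samples required.
    """
    sub = _patient_coords(coords, patient)
    mat = squareform(pdist(sub[["x_cm", "y_cm"]].to_numpy(dtype=float)))
    return pd.DataFrame(mat, index=sub.index, columns=sub.index)


def physical_diversity(coords: pd.DataFrame, patient: str) -> float:
    """Div(p): mean distance from each sampling point to the centroid (cm).

    The "center point" is the arithmetic centroid of the sampled points.
    A single point has undefined dispersion, so >= 2 samples are required.
    """
    sub = _patient_coords(coords, patient)
    xy = sub[["x_cm", "y_cm"]].to_numpy(dtype=float)
    centroid = xy.mean(axis=0)
    return float(np.linalg.norm(xy - centroid, axis=1).mean())


def pooled_within_tumor_distances(coords: pd.DataFrame) -> pd.Series:
    """All within-tumor pairwise distances, concatenated across tumors.

    Between-tumor pairs are excluded: coordinate frames are per tumor and
    cross-tumor distances are physically meaningless.
    """
    pieces = []
    for patient, sub in coords.groupby("patient_id", sort=True):
        if len(sub) < 2:
            continue
        d = pdist(sub[["x_cm", "y_cm"]].to_numpy(dtype=float))
        pieces.append(pd.Series(d, name="distance_cm"))
    if not pieces:
        raise ValueError("no tumor with >= 2 coordinate records")
    return pd.concat(pieces, ignore_index=True)


def distance_summary(coords: pd.DataFrame) -> dict:
    """Median / min / max of pooled within-tumor pairwise distances (cm)."""
    d = pooled_within_tumor_distances(coords)
    return {
        "n_pairs": int(len(d)),
        "median_cm": float(d.median()),
        "min_cm": float(d.min()),
        "max_cm": float(d.max()),
    }
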