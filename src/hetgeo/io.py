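"""Table readers/writers, bundle validation, and run manifests.

On-disk conventions: expression as genes x samples TSV/CSV (TPM scale) or
a MatrixMarket triplet with gene/sample index files; metadata, coordinate,
variant and survival tables as TSV keyed by sample or patient id. All
tables are ID-keyed so internal 0-based indexing never leaks to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("hetgeo")

__all__ = [
    "read_expression",
    "read_metadata",
    "read_coordinates",
    "read_variants_tsv",
    "read_vcf",
    "read_survival",
    "CohortBundle",
    "ValidationReport",
    "validate_bundle",
    "write_manifest",
]


def _read_table(path: Path, sep: str) -> pd.DataFrame:
    # check the raw header: pandas silently mangles duplicate column names
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicated sample IDs: {dupes} (header line 1)")
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a genes x samples expression matrix (tsv, csv, or mtx triplet).

    For ``fmt="mtx"`` ``path`` is the directory holding ``matrix.mtx``,
    ``genes.tsv`` and ``samples.tsv`` (one ID per line). Values must be
    nonnegative; duplicate gene IDs are collapsed by max (logged).
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.is_dir() else path.suffix.lstrip(".").lower()
    if fmt in ("tsv", "txt"):
        df = _read_table(path, "\t")
    elif fmt == "csv":
        df = _read_table(path, ",")
    elif fmt == "mtx":
        from scipy.io import mmread

        mat = mmread(path / "matrix.mtx").toarray()
        genes = (path / "genes.tsv").read_text().split()
        samples = (path / "samples.tsv").read_text().split()
        if mat.shape != (len(genes), len(samples)):
            raise ValueError(f"{path}: matrix shape {mat.shape} disagrees with index files")
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric expression values")
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative expression value at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} (data line {r + 2})"
        )
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicated gene IDs by max", n)
        df = df.groupby(level=0, sort=False).max()
    return df


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample_id, patient_id, tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("patient_id", "tissue"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def read_coordinates(path, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Coordinates TSV (sample_id, x_cm, y_cm[, patient_id]) in cm.

    Non-numeric coordinates are rejected, not coerced. When patient_id is
    absent it is joined in from ``meta``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("x_cm", "y_cm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"{path}: non-numeric values in {col!r}")
    if "patient_id" not in df.columns:
        if meta is None:
            raise ValueError(f"{path}: no patient_id column and no metadata to join")
        df = df.join(meta["patient_id"], how="left")
        if df["patient_id"].isna().any():
            orphans = list(df.index[df["patient_id"].isna()])
            raise ValueError(f"{path}: samples without metadata: {orphans}")
    return df[["x_cm", "y_cm", "patient_id"]]


def _variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def read_variants_tsv(path) -> dict[str, set]:
    """Long-form variant TSV (sample_id, chrom, pos, ref, alt) -> keyed sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "chrom", "pos", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample_id, set()).add(
            _variant_key(row.chrom, row.pos, row.ref, row.alt)
        )
    return out


def read_vcf(path, sample_id: str | None = None) -> set:
    """Minimal-field VCF read: one sample's variant keys (chrom:pos:ref:alt)."""
    from cyvcf2 import VCF

    keys = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            keys.add(_variant_key(rec.CHROM, rec.POS, rec.REF, alt))
    return keys


def read_survival(path) -> pd.DataFrame:
    """Survival TSV (patient_id, time, event) with positive times, 0/1 events."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: non-positive survival times")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError(f"{path}: events must be 0/1")
    return df


@dataclass
class CohortBundle:
    """Expression + metadata with optional coordinates, variants, survival."""

    expression: pd.DataFrame = field(repr=False)
    meta: pd.DataFrame = field(repr=False)
    coords: pd.DataFrame | None = field(default=None, repr=False)
    variants: Mapping[str, set] | None = field(default=None, repr=False)
    survival: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_on_error(self) -> None:
        if self.errors:
            raise ValueError("bundle validation failed:\n" + "\n".join(self.errors))


def validate_bundle(bundle: CohortBundle, spatial_required: bool = False) -> ValidationReport:
    """Cross-check the bundle's tables; enumerate every inconsistency.

    Hard failures: expression samples without metadata, tissue labels
    outside {tumor, normal}, and (when spatial analyses are requested)
    tumor samples without coordinates. Patients with fewer than 3 regions
    draw a warning — diversity estimates sharpen noticeably up to three
    samples per tumor.
    """
    report = ValidationReport()
    samples = list(bundle.expression.columns)
    missing_meta = [s for s in samples if s not in bundle.meta.index]
    if missing_meta:
        report.errors.append(f"samples without metadata: {missing_meta}")
    known = [s for s in samples if s in bundle.meta.index]
    bad_tissue = bundle.meta.loc[known, "tissue"][
        ~bundle.meta.loc[known, "tissue"].isin(["tumor", "normal"])
    ]
    if len(bad_tissue):
        report.errors.append(
            f"tissue labels outside {{tumor, normal}}: {sorted(bad_tissue.unique())}"
        )
    tumor = [s for s in known if bundle.meta.loc[s, "tissue"] == "tumor"]
    if spatial_required:
        if bundle.coords is None:
            report.errors.append("spatial analysis requested but no coordinates supplied")
        else:
            orphan = [s for s in tumor if s not in bundle.coords.index]
            if orphan:
                report.errors.append(f"tumor samples without coordinates: {orphan}")
    counts = bundle.meta.loc[tumor, "patient_id"].value_counts()
    for patient, n in counts.items():
        if n < 3:
            report.warnings.append(
                f"patient {patient} has only {n} region(s); at least 3 are recommended"
            )
    if bundle.survival is not None:
        missing_surv = [
            p for p in counts.index if p not in bundle.survival.index
        ]
        if missing_surv:
            report.warnings.append(f"patients without survival records: {missing_surv}")
    return report


def write_manifest(outdir, config: dict, seed: int | None, inputs: dict | None = None) -> Path:
    """Machine-readable run manifest: inputs, config hash, seed, versions."""
    import hetgeo

    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "inputs": inputs or {},
        "versions": {
            "hetgeo": hetgeo.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    out = Path(outdir) / "run_manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
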