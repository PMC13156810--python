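"""NIfTI and tabular I/O plus cohort bookkeeping.

The package reads and writes NIfTI-1 volumes through nibabel.  Only
axis-aligned (diagonal-affine) images are accepted: the study data were
converted to NIfTI and resampled onto a common grid before any processing,
so oblique affines are out of scope and rejected with a clear message.
Arrays are stored (slice, row, col) with the affine diagonal carrying the
spacing in the same order.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import LumenLabel, VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_label",
    "write_label",
    "read_manifest",
    "write_manifest",
    "summarize_cohort",
    "CohortSummary",
]

GRADES = ("mild", "moderate", "severe")


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _check_affine(aff: np.ndarray, path) -> tuple[tuple, tuple]:
    rot = aff[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.abs(off).max() > 1e-4 * max(1.0, np.abs(np.diag(rot)).max()):
        raise ValueError(
            f"{path}: oblique or rotated affine is not supported; resample the "
            "image to an axis-aligned grid first"
        )
    spacing = tuple(float(abs(v)) for v in np.diag(rot))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: affine has a zero-length axis")
    origin = tuple(float(v) for v in aff[:3, 3])
    return spacing, origin


def _write_nifti(arr: np.ndarray, spacing, origin, path) -> None:
    """Write deterministically: gzip mtime forced to 0 for .gz outputs."""
    img = nib.Nifti1Image(arr, _affine(spacing, origin))
    img.header.set_zooms(spacing)
    path = Path(path)
    if path.name.endswith(".gz"):
        buf = _io.BytesIO()
        fmap = img.make_file_map({"image": buf, "header": buf})
        img.to_file_map(fmap)
        with open(path, "wb") as f:
            # filename="" and mtime=0: bitwise-identical output across runs
            with gzip.GzipFile(filename="", fileobj=f, mode="wb", mtime=0) as gz:
                gz.write(buf.getvalue())
    else:
        nib.save(img, str(path))


def _load(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    spacing, origin = _check_affine(img.affine, path)
    return data, spacing, origin


def read_volume(path) -> VolumeImage:
    """Read a 3D NIfTI scalar volume; spacing/origin come from the affine."""
    data, spacing, origin = _load(path)
    return VolumeImage(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(vol: VolumeImage, path) -> None:
    _write_nifti(np.asarray(vol.values, dtype=np.float32), vol.spacing, vol.origin, path)


def read_label(path) -> LumenLabel:
    """Read a binary lumen mask; any nonzero voxel counts as foreground."""
    data, spacing, origin = _load(path)
    return LumenLabel((np.asarray(data) > 0).astype(np.uint8), spacing, origin)


def write_label(label: LumenLabel, path) -> None:
    _write_nifti(np.asarray(label.mask, dtype=np.uint8), label.spacing, label.origin, path)


# ---------------------------------------------------------------------------
# Cohort manifests

MANIFEST_COLUMNS = [
    "lesion_id",
    "image_path",
    "label_path",
    "grade",
    "true_percent",
    "scanner_tag",
    "seed",
]


def read_manifest(path, check_paths: bool = True) -> pd.DataFrame:
    """Load a cohort manifest CSV and validate its basic invariants."""
    df = pd.read_csv(path)
    missing = {"lesion_id", "grade"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {sorted(missing)}")
    if df["lesion_id"].duplicated().any():
        dup = df.loc[df["lesion_id"].duplicated(), "lesion_id"].iloc[0]
        raise ValueError(f"duplicate lesion_id {dup!r} in {path}")
    bad = set(df["grade"]) - set(GRADES)
    if bad:
        raise ValueError(f"invalid grades in {path}: {sorted(bad)}")
    if check_paths:
        for col in ("image_path", "label_path"):
            if col in df.columns:
                for p in df[col].dropna():
                    if p and not Path(p).exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


class CohortSummary(dict):
    """Nested per-cohort counts with grand totals (plain dict subclass)."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cohort, d in self.items():
            if cohort == "total":
                continue
            rows.append({"cohort": cohort, **d})
        rows.append({"cohort": "total", **self["total"]})
        return pd.DataFrame(rows)


def summarize_cohort(manifests: dict[str, pd.DataFrame]) -> CohortSummary:
    """Summarize per-cohort patient/lesion counts and per-grade counts.

    ``manifests`` maps a cohort name (e.g. train_val / test / external) to
    its manifest.  Patient counts use the ``patient_id`` column when present
    (several lesions can share a patient), otherwise each lesion counts as
    one patient.  Duplicate lesion ids across cohorts are rejected.
    """
    seen: dict[str, str] = {}
    out = CohortSummary()
    totals = {"patients": 0, "lesions": 0, **{g: 0 for g in GRADES}}
    for name, df in manifests.items():
        for lid in df["lesion_id"]:
            if lid in seen:
                raise ValueError(
                    f"lesion_id {lid!r} appears in both {seen[lid]!r} and {name!r}"
                )
            seen[lid] = name
        if "patient_id" in df.columns:
            n_pat = int(df["patient_id"].nunique())
        else:
            n_pat = int(len(df))
        entry = {"patients": n_pat, "lesions": int(len(df))}
        for g in GRADES:
            entry[g] = int((df["grade"] == g).sum())
        out[name] = entry
        for k in totals:
            totals[k] += entry[k]
    out["total"] = totals
    return out
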