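"""Standard-format I/O: TCK tractograms, NIfTI-1 scalar maps and DWI,
FSL-style bvals/bvecs, CSV tables.

All on-disk formats are the field's conventional ones so outputs drop into
existing tractography/tractometry toolchains.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import streamlines as nibs

from cstmotor.cohort import PatientRecord
from cstmotor.tensor import GradientScheme
from cstmotor.tractometry import ScalarMap, Tractogram, TractometryError


class FormatError(ValueError):
    """Raised on malformed or unreadable files."""


# ---------------------------------------------------------------------------
# Tractograms (TCK)


def save_tractogram(t: Tractogram, path: str | Path) -> None:
    sl = nibs.Tractogram([s.astype(np.float32) for s in t.streamlines],
                         affine_to_rasmm=np.eye(4))
    nibs.save(sl, str(path))


def load_tractogram(path: str | Path, hemisphere: str = "left") -> Tractogram:
    """Load a TCK file; streamlines come back in mm (RAS) coordinates."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: empty file (byte offset 0)")
    try:
        tck = nibs.load(str(path))
    except Exception as exc:  # malformed header / truncated stream
        raise FormatError(f"{path}: unreadable tractogram ({exc})") from exc
    sls = [np.asarray(s, dtype=float) for s in tck.streamlines]
    if not sls:
        raise FormatError(f"{path}: tractogram contains no streamlines")
    return Tractogram(sls, hemisphere=hemisphere)


# ---------------------------------------------------------------------------
# Scalar maps and DWI (NIfTI-1)


def save_scalar_map(m: ScalarMap, path: str | Path) -> None:
    img = nib.Nifti1Image(m.values.astype(np.float64), m.affine)
    img.header.set_intent("estimate", name=m.metric)
    nib.save(img, str(path))


def load_scalar_map(path: str | Path, metric: str | None = None) -> ScalarMap:
    """Load a NIfTI volume; the metric is taken from the filename suffix
    (e.g. ``sub-01_FA.nii``) unless given explicitly."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if metric is None:
        stem = path.name.split(".")[0]
        metric = stem.rsplit("_", 1)[-1] if "_" in stem else stem
    try:
        return ScalarMap(data, img.affine, metric=metric)
    except TractometryError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def save_dwi(dwi: np.ndarray, affine: np.ndarray, scheme: GradientScheme,
             path: str | Path) -> None:
    """Write a 4D DWI NIfTI plus sidecar ``.bval``/``.bvec`` text files."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(dwi, dtype=np.float64), affine), str(path))
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    np.savetxt(str(stem) + ".bval", scheme.bvals[None, :], fmt="%g")
    np.savetxt(str(stem) + ".bvec", scheme.bvecs.T, fmt="%.8f")


def load_dwi(path: str | Path) -> tuple[np.ndarray, np.ndarray, GradientScheme]:
    path = Path(path)
    img = nib.load(str(path))
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") \
        else path.with_suffix("")
    bvals = np.loadtxt(str(stem) + ".bval").ravel()
    bvecs = np.loadtxt(str(stem) + ".bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return (np.asanyarray(img.dataobj, dtype=float), img.affine,
            GradientScheme(bvals, bvecs))


# ---------------------------------------------------------------------------
# Tables


def save_patient_table(patients: list[PatientRecord], path: str | Path) -> None:
    pd.DataFrame([vars(p) for p in patients]).to_csv(path, index=False)


def load_patient_table(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    return [PatientRecord(**{k: row[k] for k in (
        "id", "age", "gender", "who_grade", "tumour_location",
        "ipsilesional_hemisphere", "rmt_ipsi", "rmt_contra",
        "mrc_score", "mrc_class")}) for _, row in df.iterrows()]


def save_profiles(profiles: dict, path: str | Path) -> None:
    """Write profiles as tidy CSV: patient, hemisphere, metric, method,
    segment, value (missing segments as empty cells)."""
    rows = []
    for (pid, hemi, metric, method), vals in sorted(profiles.items()):
        for seg, v in enumerate(vals):
            rows.append({"patient": pid, "hemisphere": hemi, "metric": metric,
                         "method": method, "segment": seg,
                         "value": v if np.isfinite(v) else ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_profiles(path: str | Path) -> dict:
    df = pd.read_csv(path)
    out: dict = {}
    for (pid, hemi, metric, method), grp in df.groupby(
            ["patient", "hemisphere", "metric", "method"]):
        vals = np.full(int(grp["segment"].max()) + 1, np.nan)
        v = pd.to_numeric(grp["value"], errors="coerce").to_numpy()
        vals[grp["segment"].to_numpy()] = v
        out[(pid, hemi, metric, method)] = vals
    return out
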