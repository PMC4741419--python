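"""Volume and table containers plus NIfTI/CSV input-output.

All spatial inputs to a run — the quantitative T1 map, the region label
volume, and optional lesion masks — must live on one common voxel grid
(same shape, same affine).  Nothing here resamples or registers; grid
mismatches are reported, never repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical deep gray matter nuclei and their default integer labels
DGMN_LABELS: dict[int, str] = {1: "thalamus", 2: "caudate", 3: "putamen", 4: "pallidum"}

#: accepted spellings of the two cohort groups, mapped to canonical names
_GROUP_ALIASES = {
    "hc": "HC", "control": "HC", "controls": "HC", "healthy": "HC",
    "patient": "PATIENT", "patients": "PATIENT", "ms": "PATIENT",
    "rrms": "PATIENT",
}

AFFINE_TOL = 1e-3


class GridMismatchError(ValueError):
    """Two volumes do not share a common voxel grid."""


@dataclass
class QuantitativeT1Volume:
    """A 3D longitudinal-relaxation-time map, voxel values in milliseconds."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if min(self.values.shape) < 1:
            raise ValueError("volume has an empty axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel dimensions in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class LabelVolume:
    """Integer region labels on the T1 grid; label 0 is background."""

    labels: np.ndarray
    dictionary: dict[int, str] = field(default_factory=lambda: dict(DGMN_LABELS))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.labels.ndim}D")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.dictionary)
        if missing:
            raise ValueError(f"labels {sorted(missing)} not in the label dictionary")

    def region_mask(self, region: str) -> "BinaryMask":
        codes = [k for k, v in self.dictionary.items() if v == region]
        if not codes:
            raise KeyError(f"region {region!r} not in label dictionary")
        return BinaryMask(np.isin(self.labels, codes), affine=self.affine)

    @property
    def regions(self) -> list[str]:
        present = set(np.unique(self.labels)) - {0}
        return [self.dictionary[k] for k in sorted(present)]


@dataclass
class BinaryMask:
    """A boolean voxel set on the shared grid (region or lesion mask)."""

    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.mask.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _grid_array(x) -> np.ndarray:
    for attr in ("values", "labels", "mask"):
        arr = getattr(x, attr, None)
        if arr is not None:
            return arr
    raise TypeError(f"{type(x).__name__} is not a volume-like object")


def check_grid_compatibility(a, b, tol: float = AFFINE_TOL) -> bool:
    """True iff two volume-like objects share shape and affine (within tol)."""
    if _grid_array(a).shape != _grid_array(b).shape:
        return False
    return bool(np.allclose(a.affine, b.affine, atol=tol, rtol=0))


def require_same_grid(a, b, what: str = "volumes") -> None:
    if not check_grid_compatibility(a, b):
        raise GridMismatchError(f"{what} are not on the same voxel grid")


# ---------------------------------------------------------------------------
# NIfTI input / output
# ---------------------------------------------------------------------------

def _load_3d(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path.name}")
    return data, np.asarray(img.affine)


def read_t1_volume(path, subject_id: str | None = None,
                   scale: float = 1.0,
                   brain_mask: "BinaryMask | None" = None) -> QuantitativeT1Volume:
    """Read a quantitative T1 map (NIfTI, values in ms).

    ``scale`` converts on-disk units to ms (e.g. 1000.0 for maps stored in
    seconds).  If a brain mask is given, non-positive or non-finite values
    inside it are counted and logged as a validation warning.
    """
    data, affine = _load_3d(path)
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"non-scalar datatype {data.dtype} in {path}")
    vol = QuantitativeT1Volume(data.astype(np.float64) * scale, affine,
                               subject_id=subject_id)
    if brain_mask is not None:
        inside = vol.values[brain_mask.mask]
        n_bad = int(np.sum(~np.isfinite(inside) | (inside <= 0)))
        if n_bad:
            log.warning("%s: %d non-positive/non-finite voxels inside the brain mask",
                        path, n_bad)
    return vol


def write_t1_volume(vol: QuantitativeT1Volume, path) -> None:
    """Write a T1 map as gzipped NIfTI-1, 32-bit float, values in ms."""
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_label_volume(path, dictionary: dict[int, str] | None = None) -> LabelVolume:
    data, affine = _load_3d(path)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"label volume {path} has non-integer values")
        data = rounded
    return LabelVolume(data.astype(np.int32),
                       dictionary or dict(DGMN_LABELS), affine)


def write_label_volume(labels: LabelVolume, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    data, affine = _load_3d(path)
    return BinaryMask(data > 0, affine)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def write_concentration_map(c_map: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a GM concentration map (values in [0, 1], background 0)."""
    img = nib.Nifti1Image(c_map.astype(np.float32), affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "age", "sex")


def normalize_group(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _GROUP_ALIASES:
        raise ValueError(f"unknown group label {label!r} "
                         f"(expected one of {sorted(set(_GROUP_ALIASES))})")
    return _GROUP_ALIASES[key]


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Type, normalize, and validate a cohort table in place contract.

    Required columns: subject_id, group, age, sex.  Extra columns are kept
    (and logged).  Raises on duplicated subject ids, unknown group labels,
    non-positive ages, or unknown sex codes.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in REQUIRED_COHORT_COLUMNS]
    if extra:
        log.info("cohort table: keeping extra column(s) %s", extra)
    out = df.copy()
    out["subject_id"] = out["subject_id"].astype(str)
    dupes = out["subject_id"][out["subject_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicated subject_id(s): {sorted(set(dupes))}")
    out["group"] = out["group"].map(normalize_group)
    out["age"] = out["age"].astype(float)
    if (out["age"] <= 0).any():
        bad = out.loc[out["age"] <= 0, "subject_id"].tolist()
        raise ValueError(f"non-positive age for subject(s): {bad}")
    out["sex"] = out["sex"].astype(str).str.strip().str.upper().str[0]
    unknown_sex = sorted(set(out["sex"]) - {"F", "M"})
    if unknown_sex:
        raise ValueError(f"unknown sex code(s): {unknown_sex}")
    return out.reset_index(drop=True)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (subject_id, group, age, sex, ...)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return validate_cohort_table(pd.read_csv(path))


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
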