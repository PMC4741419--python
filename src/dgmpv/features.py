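"""Per-subject, per-region feature extraction.

Each subject contributes, for every deep gray matter region, the triple of
partial-volume features compared across groups — the characteristic GM and
WM T1 values and the GM/WM concentration ratio — plus the baseline
global-averaging feature (mean T1 over the same normal-appearing voxels)
and bookkeeping counts.  Regions that fail to fit are recorded as missing
values, never as a crash, so one bad ROI does not cost the subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pve import NonIdentifiableError, PVEOptions, fit_region
from .volumes import (BinaryMask, LabelVolume, QuantitativeT1Volume,
                      DGMN_LABELS, require_same_grid)

log = logging.getLogger(__name__)

DEFAULT_REGIONS = tuple(DGMN_LABELS.values())

#: per-region feature columns, in feature-table order
FEATURE_NAMES = ("mu_gm", "mu_wm", "ratio", "mean_t1", "sigma", "n_voxels")
#: the multivariate (MANOVA) feature triple
PV_FEATURES = ("mu_gm", "mu_wm", "ratio")


def exclude_lesions(region_mask: BinaryMask, lesion_mask: BinaryMask) -> BinaryMask:
    """Normal-appearing voxels: region minus lesions (set difference)."""
    require_same_grid(region_mask, lesion_mask, "region and lesion masks")
    return BinaryMask(region_mask.mask & ~lesion_mask.mask, region_mask.affine)


def concentration_ratio(c_gm) -> float:
    """Scalar GM/WM concentration ratio of a region: mean(C_GM)/mean(C_WM).

    Defined on the ROI-mean concentrations (one scalar per region per
    subject), not voxelwise, because voxelwise ratios blow up wherever the
    WM fraction vanishes.
    """
    c = np.asarray(getattr(c_gm, "c_gm", c_gm), dtype=np.float64).ravel()
    if c.size == 0:
        raise ValueError("empty concentration field")
    mean_gm = float(c.mean())
    mean_wm = 1.0 - mean_gm
    if mean_wm == 0.0:
        raise ZeroDivisionError(
            "mean GM concentration is exactly 1: the GM/WM ratio is undefined")
    return mean_gm / mean_wm


def global_mean_t1(volume: QuantitativeT1Volume, mask: BinaryMask) -> float:
    """Arithmetic mean T1 (ms) over the masked voxels."""
    require_same_grid(volume, mask, "T1 map and mask")
    if not mask.mask.any():
        raise ValueError("empty mask: mean T1 undefined")
    return float(volume.values[mask.mask].mean())


@dataclass
class SubjectFeatures:
    """One subject's per-region feature vectors (missing regions are NaN)."""

    subject_id: str
    regions: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject_id": self.subject_id}
        for region, feats in self.regions.items():
            for name in FEATURE_NAMES:
                row[f"{region}_{name}"] = feats.get(name, np.nan)
        return row


def extract_subject_features(volume: QuantitativeT1Volume,
                             labels: LabelVolume,
                             lesions: BinaryMask | None = None,
                             regions: tuple[str, ...] = DEFAULT_REGIONS,
                             options: PVEOptions | None = None) -> SubjectFeatures:
    """Fit every requested region and assemble the subject's feature row.

    The global-averaging feature uses the same lesion-excluded voxel set as
    the partial-volume fit, so the two analysis arms differ only in the
    statistic computed from identical data.
    """
    available = set(labels.regions)
    found = [r for r in regions if r in available]
    if not found:
        raise ValueError(f"none of the requested regions {list(regions)} "
                         "are present in the label volume")
    feats = SubjectFeatures(subject_id=volume.subject_id or "unknown")
    for region in regions:
        entry: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}
        if region not in available:
            log.info("subject %s: region %s absent from labels, recorded as "
                     "missing", feats.subject_id, region)
            feats.regions[region] = entry
            continue
        try:
            fit = fit_region(volume, labels, region, lesions, options)
            mask = labels.region_mask(region)
            if lesions is not None:
                mask = exclude_lesions(mask, lesions)
            entry["mu_gm"] = fit.intensities.mu_gm
            entry["mu_wm"] = fit.intensities.mu_wm
            entry["ratio"] = concentration_ratio(fit.concentrations)
            entry["mean_t1"] = global_mean_t1(volume, mask)
            entry["sigma"] = fit.intensities.sigma
            entry["n_voxels"] = float(fit.n_voxels)
        except (NonIdentifiableError, ValueError, ZeroDivisionError) as exc:
            log.warning("subject %s: region %s failed (%s); recorded as "
                        "missing", feats.subject_id, region, exc)
        feats.regions[region] = entry
    return feats


def features_to_table(rows: list[SubjectFeatures]) -> pd.DataFrame:
    """Stack subject feature rows into the interchange feature table."""
    return pd.DataFrame([r.to_row() for r in rows])


def relative_change_percent(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``.

    Used e.g. to express a patient-group mean characteristic T1 against the
    control-group mean.
    """
    if reference == 0:
        raise ZeroDivisionError("reference value is zero")
    return 100.0 * (value - reference) / reference
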