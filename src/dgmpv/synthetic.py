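"""Synthetic phantoms and cohorts with known partial-volume ground truth.

The generator emulates the study's data layer end to end: per-subject 3D T1
maps built from the forward mixture model ``y = mu_gm*c + mu_wm*(1-c) +
N(0, sigma)`` over four ellipsoidal deep gray matter regions, patient
lesion masks, and a cohort table with group, age and sex.  Group structure
enters through the characteristic intensities and the concentration ratio,
whose per-group thalamic distributions default to reference values for an
early relapsing-remitting MS cohort vs healthy controls (controls mu_gm
1389+-47 ms, mu_wm 912+-18 ms,
ratio 0.62+-0.08; patients 1427+-40, 918+-14, 0.61+-0.07; 19 vs 43
subjects).

The thalamus concentration field follows a center-bright radial gradient
spanning the full [0, 1] range (near-pure voxels at center and border keep
the characteristic intensities identifiable); its radial power profile is
calibrated per subject so the region-mean GM fraction matches the drawn
concentration ratio.  The remaining regions are (near-)homogeneous and
carry no group effect by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .volumes import (BinaryMask, LabelVolume, QuantitativeT1Volume,
                      DGMN_LABELS, write_cohort_table, write_label_volume,
                      write_mask, write_t1_volume)

log = logging.getLogger(__name__)

REFERENCE_GRID = 64  # geometry below is defined on a 64^3, 1 mm grid


@dataclass(frozen=True)
class RegionGeometry:
    name: str
    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


DEFAULT_GEOMETRY: tuple[RegionGeometry, ...] = (
    RegionGeometry("thalamus", 1, (20.0, 20.0, 32.0), (9.0, 7.0, 6.0)),
    RegionGeometry("caudate", 2, (20.0, 46.0, 32.0), (4.0, 4.0, 7.0)),
    RegionGeometry("putamen", 3, (46.0, 20.0, 32.0), (6.0, 5.0, 5.0)),
    RegionGeometry("pallidum", 4, (46.0, 46.0, 32.0), (4.0, 3.5, 3.5)),
)


@dataclass(frozen=True)
class ConcentrationPattern:
    """Spatial GM-concentration model of one region.

    ``radial``: a center-bright profile in the ellipsoidal volume fraction,
    ``c ~ (1 - r^3)**gamma`` with ``r`` the normalized radius (0 center,
    1 border), affinely rescaled so the border/center anchor values are
    attained exactly on the voxel lattice.  With ``gamma == 1`` the
    voxelwise concentration distribution is uniform over the span.
    ``constant``: ``c = c0`` everywhere.
    """

    kind: str = "radial"
    c_center: float = 1.0
    c_border: float = 0.0
    gamma: float = 1.0
    c0: float = 0.5

    def evaluate(self, r: np.ndarray) -> np.ndarray:
        if self.kind == "constant":
            return np.full_like(r, self.c0)
        if self.kind == "radial":
            # profile in ellipsoidal volume fraction r^3: for gamma == 1 the
            # voxelwise concentration distribution is uniform on the span
            v = np.clip(1.0 - r ** 3, 0.0, 1.0)
            raw = np.power(v, self.gamma)
            lo, hi = float(raw.min()), float(raw.max())
            if hi - lo < 1e-12:
                return np.full_like(r, 0.5 * (self.c_border + self.c_center))
            # affine rescale so border/center anchors are attained exactly
            # on the voxel lattice
            return self.c_border + (self.c_center - self.c_border) \
                * (raw - lo) / (hi - lo)
        raise ValueError(f"unknown pattern kind {self.kind!r}")


@dataclass
class RegionTruth:
    mu_gm: float
    mu_wm: float
    pattern: ConcentrationPattern = field(default_factory=ConcentrationPattern)

    def __post_init__(self) -> None:
        if not self.mu_gm > self.mu_wm:
            raise ValueError(f"mu_gm must exceed mu_wm "
                             f"({self.mu_gm} <= {self.mu_wm})")


@dataclass
class PhantomTruth:
    """Ground truth of one phantom volume."""

    regions: dict[str, RegionTruth]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_phantom_truth(noise_sd: float = 0.0, seed: int = 0) -> PhantomTruth:
    """Four-region truth with a center-bright thalamic gradient."""
    return PhantomTruth(
        regions={
            "thalamus": RegionTruth(1389.0, 912.0, ConcentrationPattern("radial")),
            "caudate": RegionTruth(1400.0, 910.0, ConcentrationPattern("constant", c0=0.58)),
            "putamen": RegionTruth(1390.0, 915.0, ConcentrationPattern("constant", c0=0.47)),
            "pallidum": RegionTruth(1340.0, 880.0, ConcentrationPattern("constant", c0=0.31)),
        },
        noise_sd=noise_sd, seed=seed)


@dataclass
class Phantom:
    """A generated phantom: T1 map, labels, brain mask, true concentrations."""

    t1: QuantitativeT1Volume
    labels: LabelVolume
    mask: BinaryMask
    c_true: np.ndarray

    def __iter__(self):
        return iter((self.t1, self.labels, self.mask))


def _scaled_geometry(grid_shape, geometry) -> tuple[RegionGeometry, ...]:
    s = np.asarray(grid_shape, dtype=float) / REFERENCE_GRID
    out = []
    for g in geometry:
        out.append(RegionGeometry(
            g.name, g.label,
            tuple(np.asarray(g.center) * s),
            tuple(np.asarray(g.semi_axes) * s)))
    return tuple(out)


def _region_voxels(geom: RegionGeometry, grid_shape):
    """Voxel indices and normalized radii of one ellipsoidal region."""
    c = np.asarray(geom.center)
    ax = np.asarray(geom.semi_axes)
    lo = np.maximum(np.floor(c - ax).astype(int), 0)
    hi = np.minimum(np.ceil(c + ax).astype(int) + 1, np.asarray(grid_shape))
    if (lo >= hi).any():
        raise ValueError(f"region {geom.name!r} does not fit inside the grid")
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    r = np.sqrt(sum(((g - ci) / ai) ** 2
                    for g, ci, ai in zip(grids, c, ax)))
    inside = r <= 1.0
    idx = tuple(g[inside] for g in grids)
    return idx, r[inside]


def generate_phantom(truth: PhantomTruth,
                     grid_shape: tuple[int, int, int] = (64, 64, 64),
                     geometry: tuple[RegionGeometry, ...] = DEFAULT_GEOMETRY,
                     rng: np.random.Generator | None = None) -> Phantom:
    """Build one phantom volume from the forward mixture model.

    Regions are painted as ellipsoids (scaled from the reference 64^3
    layout to ``grid_shape``); voxel values are
    ``mu_gm*c + mu_wm*(1-c) + N(0, noise_sd)``.  Raises if two regions
    overlap or a region does not fit in the grid.
    """
    rng = rng or np.random.default_rng(truth.seed)
    geoms = {g.name: g for g in _scaled_geometry(grid_shape, geometry)}
    unknown = set(truth.regions) - set(geoms)
    if unknown:
        raise ValueError(f"no geometry for region(s) {sorted(unknown)}")
    labels = np.zeros(grid_shape, dtype=np.int32)
    values = np.zeros(grid_shape, dtype=np.float64)
    c_map = np.zeros(grid_shape, dtype=np.float64)
    dictionary = {}
    for name, rt in truth.regions.items():
        geom = geoms[name]
        idx, r = _region_voxels(geom, grid_shape)
        if (labels[idx] != 0).any():
            raise ValueError(f"region {name!r} overlaps a previously placed "
                             "region")
        labels[idx] = geom.label
        dictionary[geom.label] = name
        c = np.clip(rt.pattern.evaluate(r), 0.0, 1.0)
        y = rt.mu_gm * c + rt.mu_wm * (1.0 - c)
        if truth.noise_sd > 0:
            y = y + rng.normal(0.0, truth.noise_sd, size=y.shape)
        values[idx] = y
        c_map[idx] = c
    affine = np.eye(4)
    return Phantom(
        t1=QuantitativeT1Volume(values, affine),
        labels=LabelVolume(labels, dictionary, affine),
        mask=BinaryMask(labels > 0, affine),
        c_true=c_map,
    )


# ---------------------------------------------------------------------------
# cohort layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueDistribution:
    """Per-group sampling distribution of one region's true parameters (ms)."""

    mu_gm_mean: float
    mu_gm_sd: float
    mu_wm_mean: float
    mu_wm_sd: float
    ratio_mean: float
    ratio_sd: float

    def __post_init__(self) -> None:
        for sd in (self.mu_gm_sd, self.mu_wm_sd, self.ratio_sd):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")


@dataclass(frozen=True)
class RegionPopulation:
    control: TissueDistribution
    patient: TissueDistribution
    #: concentration span of the radial pattern; (0, 1) anchors pure voxels
    c_border: float = 0.0
    c_center: float = 1.0


def default_region_populations() -> dict[str, RegionPopulation]:
    """Study-condition defaults.

    Thalamus group distributions are the reported control/patient values;
    the other nuclei get region-typical parameters with no group effect
    (their per-group distributions are identical) and near-homogeneous
    concentration fields.
    """
    return {
        "thalamus": RegionPopulation(
            control=TissueDistribution(1389.0, 47.0, 912.0, 18.0, 0.62, 0.08),
            patient=TissueDistribution(1427.0, 40.0, 918.0, 14.0, 0.61, 0.07),
        ),
        "caudate": RegionPopulation(
            control=TissueDistribution(1400.0, 45.0, 910.0, 16.0, 1.40, 0.15),
            patient=TissueDistribution(1400.0, 45.0, 910.0, 16.0, 1.40, 0.15),
            c_border=0.45, c_center=0.75),
        "putamen": RegionPopulation(
            control=TissueDistribution(1390.0, 45.0, 915.0, 16.0, 0.90, 0.10),
            patient=TissueDistribution(1390.0, 45.0, 915.0, 16.0, 0.90, 0.10),
            c_border=0.32, c_center=0.62),
        "pallidum": RegionPopulation(
            control=TissueDistribution(1340.0, 45.0, 880.0, 16.0, 0.45, 0.06),
            patient=TissueDistribution(1340.0, 45.0, 880.0, 16.0, 0.45, 0.06),
            c_border=0.17, c_center=0.47),
    }


@dataclass
class CohortSpec:
    """Population-level description of a simulated two-group study."""

    n_control: int = 19
    n_patient: int = 43
    regions: dict[str, RegionPopulation] = field(
        default_factory=default_region_populations)
    noise_sd: float = 50.0                    # voxel noise, ms
    lesion_count_mean: float = 3.0            # Poisson mean, patients only
    lesion_radius: float = 2.0                # voxels
    age_control: tuple[float, float] = (33.0, 9.3)     # mean, SD years
    age_patient: tuple[float, float] = (35.2, 10.0)
    female_fraction_control: float = 11.0 / 19.0
    female_fraction_patient: float = 27.0 / 43.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    min_mu_separation: float = 100.0          # redraw floor for mu_gm - mu_wm, ms

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_patient) < 1:
            raise ValueError("both group sizes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _solve_gamma(r: np.ndarray, c_border: float, c_center: float,
                 target_mean: float) -> float:
    """Radial exponent giving the requested region-mean concentration."""
    span_lo, span_hi = min(c_border, c_center), max(c_border, c_center)
    target = float(np.clip(target_mean, span_lo + 0.02, span_hi - 0.02))

    def mean_minus_target(gamma: float) -> float:
        pat = ConcentrationPattern("radial", c_center=c_center,
                                   c_border=c_border, gamma=gamma)
        return float(pat.evaluate(r).mean()) - target

    lo, hi = 5e-2, 40.0
    f_lo, f_hi = mean_minus_target(lo), mean_minus_target(hi)
    if f_lo * f_hi > 0:   # target outside the achievable range; take the closer end
        return lo if abs(f_lo) < abs(f_hi) else hi
    return float(brentq(mean_minus_target, lo, hi, xtol=1e-6))


def _draw_subject_truth(spec: CohortSpec, group: str,
                        rng: np.random.Generator) -> dict[str, dict[str, float]]:
    out = {}
    for name, pop in spec.regions.items():
        dist = pop.control if group == "HC" else pop.patient
        for _ in range(200):
            mu_gm = rng.normal(dist.mu_gm_mean, dist.mu_gm_sd)
            mu_wm = rng.normal(dist.mu_wm_mean, dist.mu_wm_sd)
            if mu_gm - mu_wm >= spec.min_mu_separation and mu_wm > 0:
                break
        else:
            raise ValueError(f"cannot draw ordered intensities for {name}")
        ratio = max(rng.normal(dist.ratio_mean, dist.ratio_sd), 0.05)
        out[name] = dict(mu_gm=float(mu_gm), mu_wm=float(mu_wm),
                         ratio=float(ratio))
    return out


@dataclass
class SubjectArrays:
    """In-memory per-region voxel data of one simulated subject.

    ``keep`` flags each region voxel surviving lesion removal; ``voxels``
    and ``c_true`` cover all region voxels (lesioned included), so the
    normal-appearing set is ``voxels[region][keep[region]]``.
    """

    subject_id: str
    group: str
    age: float
    sex: str
    truth: dict[str, dict[str, float]]
    voxels: dict[str, np.ndarray]
    c_true: dict[str, np.ndarray]
    keep: dict[str, np.ndarray]

    def clean_voxels(self, region: str) -> np.ndarray:
        return self.voxels[region][self.keep[region]]

    @property
    def n_lesion_voxels(self) -> int:
        return int(sum((~k).sum() for k in self.keep.values()))


def _simulate_subject_arrays(spec: CohortSpec, subject_id: str, group: str,
                             rng: np.random.Generator,
                             region_cache: dict,
                             regions: tuple[str, ...]) -> SubjectArrays:
    age_mean, age_sd = spec.age_control if group == "HC" else spec.age_patient
    age = float(np.clip(rng.normal(age_mean, age_sd), 18.0, 80.0))
    p_f = (spec.female_fraction_control if group == "HC"
           else spec.female_fraction_patient)
    sex = "F" if rng.uniform() < p_f else "M"
    truth = _draw_subject_truth(spec, group, rng)

    voxels, c_fields, keeps = {}, {}, {}
    for name in regions:
        idx, r = region_cache[name]
        pop = spec.regions[name]
        t = truth[name]
        target_mean = t["ratio"] / (1.0 + t["ratio"])
        gamma = _solve_gamma(r, pop.c_border, pop.c_center, target_mean)
        t["gamma"] = gamma
        c = ConcentrationPattern("radial", c_center=pop.c_center,
                                 c_border=pop.c_border,
                                 gamma=gamma).evaluate(r)
        keep = np.ones(r.size, dtype=bool)
        if group == "PATIENT" and spec.lesion_count_mean > 0:
            coords = np.column_stack(idx).astype(float)
            n_les = rng.poisson(spec.lesion_count_mean / max(len(regions), 1))
            for _ in range(n_les):
                center = coords[rng.integers(coords.shape[0])]
                d = np.sqrt(((coords - center) ** 2).sum(axis=1))
                keep &= d > spec.lesion_radius
        y = t["mu_gm"] * c + t["mu_wm"] * (1.0 - c)
        if spec.noise_sd > 0:
            y = y + rng.normal(0.0, spec.noise_sd, size=y.size)
        # lesional tissue is T1-hyperintense; exclusion keeps it out of fits
        y[~keep] *= 1.25
        voxels[name] = y
        c_fields[name] = c
        keeps[name] = keep
    return SubjectArrays(subject_id, group, age, sex, truth, voxels,
                         c_fields, keeps)


def simulate_cohort_arrays(spec: CohortSpec, seed: int,
                           regions: tuple[str, ...] | None = None,
                           geometry: tuple[RegionGeometry, ...] = DEFAULT_GEOMETRY,
                           ) -> list[SubjectArrays]:
    """Fast in-memory cohort: per-subject region voxel vectors, no volumes.

    All randomness flows from ``seed`` through per-subject child streams;
    identical seeds reproduce the cohort exactly.
    """
    regions = tuple(regions) if regions else tuple(spec.regions)
    missing = set(regions) - set(spec.regions)
    if missing:
        raise ValueError(f"spec has no population for region(s) {sorted(missing)}")
    geoms = {g.name: g for g in _scaled_geometry(spec.grid_shape, geometry)}
    cache = {}
    for name in regions:
        if name not in geoms:
            raise ValueError(f"no geometry for region {name!r}")
        geom = geoms[name]
        if spec.lesion_radius >= min(geom.semi_axes):
            raise ValueError(
                f"lesion radius {spec.lesion_radius} does not fit inside "
                f"region {name!r} (smallest semi-axis "
                f"{min(geom.semi_axes):.2f})")
        cache[name] = _region_voxels(geom, spec.grid_shape)

    n_total = spec.n_control + spec.n_patient
    streams = np.random.SeedSequence(seed).spawn(n_total)
    subjects = []
    for i, ss in enumerate(streams):
        group = "HC" if i < spec.n_control else "PATIENT"
        sid = f"sub-{i + 1:03d}"
        subjects.append(_simulate_subject_arrays(
            spec, sid, group, np.random.default_rng(ss), cache, regions))
    return subjects


def cohort_table_from_arrays(subjects: list[SubjectArrays]) -> pd.DataFrame:
    return pd.DataFrame([
        dict(subject_id=s.subject_id, group=s.group, age=s.age, sex=s.sex)
        for s in subjects])


def truth_manifest(subjects: list[SubjectArrays]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        for region, t in s.truth.items():
            rows.append(dict(subject_id=s.subject_id, group=s.group,
                             region=region, **t))
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, out_dir, seed: int,
                    geometry: tuple[RegionGeometry, ...] = DEFAULT_GEOMETRY,
                    ) -> pd.DataFrame:
    """Write a full simulated cohort to disk: volumes, masks, tables.

    Produces ``t1_<id>.nii.gz`` per subject, ``lesions_<id>.nii.gz`` where
    lesions were drawn, one shared ``labels.nii.gz``, a ``cohort.csv`` with
    file paths, and a ``truth.json`` manifest recording every drawn value
    and the seed.  Returns the cohort table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate_cohort_arrays(spec, seed, geometry=geometry)
    geoms = {g.name: g for g in _scaled_geometry(spec.grid_shape, geometry)}
    cache = {name: _region_voxels(geoms[name], spec.grid_shape)
             for name in spec.regions}

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    dictionary = {}
    for name in spec.regions:
        geom = geoms[name]
        idx, _ = cache[name]
        if (labels[idx] != 0).any():
            raise ValueError(f"region {name!r} overlaps a previously placed region")
        labels[idx] = geom.label
        dictionary[geom.label] = name
    label_vol = LabelVolume(labels, dictionary)
    labels_path = out / "labels.nii.gz"
    write_label_volume(label_vol, labels_path)

    rows = []
    for s in subjects:
        values = np.zeros(spec.grid_shape, dtype=np.float64)
        lesion = np.zeros(spec.grid_shape, dtype=bool)
        for name in spec.regions:
            idx, _ = cache[name]
            values[idx] = s.voxels[name]
            bad = ~s.keep[name]
            if bad.any():
                lesion[tuple(ax[bad] for ax in idx)] = True
        t1 = QuantitativeT1Volume(values, subject_id=s.subject_id)
        t1_path = out / f"t1_{s.subject_id}.nii.gz"
        write_t1_volume(t1, t1_path)
        row = dict(subject_id=s.subject_id, group=s.group, age=s.age,
                   sex=s.sex, t1_path=str(t1_path),
                   labels_path=str(labels_path), lesions_path="")
        if lesion.any():
            les_path = out / f"lesions_{s.subject_id}.nii.gz"
            write_mask(BinaryMask(lesion), les_path)
            row["lesions_path"] = str(les_path)
        rows.append(row)

    cohort = pd.DataFrame(rows)
    write_cohort_table(cohort, out / "cohort.csv")
    manifest = dict(seed=seed, spec=_spec_to_jsonable(spec),
                    subjects=truth_manifest(subjects).to_dict(orient="records"))
    (out / "truth.json").write_text(json.dumps(manifest, indent=1))
    return cohort


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["regions"] = {k: asdict(v) for k, v in spec.regions.items()}
    return d
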