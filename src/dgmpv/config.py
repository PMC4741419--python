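"""Run configuration: YAML/JSON parsing into the typed spec objects."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .synthetic import CohortSpec, RegionPopulation, TissueDistribution

_DIST_KEYS = ("mu_gm_mean", "mu_gm_sd", "mu_wm_mean", "mu_wm_sd",
              "ratio_mean", "ratio_sd")


def _distribution_from_dict(d: dict) -> TissueDistribution:
    unknown = set(d) - set(_DIST_KEYS)
    if unknown:
        raise ValueError(f"unknown tissue-distribution key(s) {sorted(unknown)}")
    return TissueDistribution(**{k: float(d[k]) for k in _DIST_KEYS})


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a parsed YAML/JSON mapping.

    Any omitted field keeps the study-condition default; regions may be
    overridden individually.
    """
    spec = CohortSpec()
    d = dict(d or {})
    regions = d.pop("regions", None)
    if regions is not None:
        # the listed regions REPLACE the default set; omitted fields of a
        # listed region keep that region's default parameters
        defaults = dict(spec.regions)
        new = {}
        for name, rd in regions.items():
            rd = rd or {}
            base = defaults.get(name)
            ctl = (_distribution_from_dict(rd["control"]) if "control" in rd
                   else (base.control if base else None))
            pat = (_distribution_from_dict(rd["patient"]) if "patient" in rd
                   else (base.patient if base else None))
            if ctl is None or pat is None:
                raise ValueError(f"region {name!r} needs control and patient "
                                 "distributions")
            new[name] = RegionPopulation(
                control=ctl, patient=pat,
                c_border=float(rd.get("c_border",
                                      base.c_border if base else 0.0)),
                c_center=float(rd.get("c_center",
                                      base.c_center if base else 1.0)))
        spec.regions = new
    grid = d.pop("grid", None)
    if grid is not None:
        spec.grid_shape = ((int(grid),) * 3 if isinstance(grid, (int, float))
                           else tuple(int(g) for g in grid))
    for key, value in d.items():
        if not hasattr(spec, key):
            raise ValueError(f"unknown cohort-spec key {key!r}")
        current = getattr(spec, key)
        if isinstance(current, tuple):
            value = tuple(type(c)(v) for c, v in zip(current, value))
        elif isinstance(current, (int, float)):
            value = type(current)(value)
        setattr(spec, key, value)
    spec.__post_init__()
    return spec


def load_cohort_spec(path) -> CohortSpec:
    text = Path(path).read_text()
    return cohort_spec_from_dict(yaml.safe_load(text) or {})


def config_hash(payload: dict) -> str:
    """Stable short hash of a run configuration, for the run log."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
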