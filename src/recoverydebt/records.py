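"""Outcome-measure records: schema, canonical category labels, validation.

One record is a single reference-vs-recovery comparison: the value of an
ecosystem attribute at the start of recovery (``x_start``), at the end of the
observed recovery period (``x_end``), the reference value in an undisturbed or
pre-disturbance system (``x_ref``), and the elapsed recovery time in years.
Records carry the categorical context (recovery metric, ecosystem, disturbance)
used downstream as meta-analytic moderators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

METRICS = ("abundance", "diversity", "carbon", "nitrogen")
SUBMETRICS = ("richness", "diversity_index", "pool", "flux", "none")
ECOSYSTEMS = ("forest", "grassland", "wetland", "river", "lake", "marine")
DISTURBANCES = (
    "agriculture",
    "logging",
    "mining",
    "invasive",
    "eutrophication",
    "hydrologic",
    "overfishing",
    "oil_spill",
    "hurricane",
    "multiple",
)

#: submetrics that are only meaningful under a given metric
_SUBMETRIC_PARENTS = {
    "richness": {"diversity"},
    "diversity_index": {"diversity"},
    "pool": {"carbon", "nitrogen"},
    "flux": {"carbon", "nitrogen"},
    "none": set(METRICS),
}

# Free-text labels seen in ecological databases mapped onto canonical enums.
# Lookup happens after lower-casing and collapsing spaces/hyphens to "_";
# labels that still miss are rejected, never silently coerced.
ENUM_SYNONYMS: dict[str, str] = {
    # metrics
    "organism_abundance": "abundance",
    "species_diversity": "diversity",
    "carbon_cycling": "carbon",
    "nitrogen_cycling": "nitrogen",
    "c": "carbon",
    "n": "nitrogen",
    # submetrics
    "species_richness": "richness",
    "diversity_indexes": "diversity_index",
    "diversity_indices": "diversity_index",
    "pools": "pool",
    "stock": "pool",
    "stocks": "pool",
    "fluxes": "flux",
    "pulse": "flux",
    "": "none",
    "na": "none",
    # ecosystems
    "forests": "forest",
    "grasslands": "grassland",
    "wetlands": "wetland",
    "rivers": "river",
    "lakes": "lake",
    "marine_ecosystem": "marine",
    "marine_ecosystems": "marine",
    # disturbances
    "agricultural_transformation": "agriculture",
    "invasive_species": "invasive",
    "hydrological_disruption": "hydrologic",
    "hydrologic_disruption": "hydrologic",
    "damming": "hydrologic",
    "oil_spills": "oil_spill",
    "hurricanes": "hurricane",
}

_ENUM_DOMAIN = {
    "metric": METRICS,
    "submetric": SUBMETRICS,
    "ecosystem": ECOSYSTEMS,
    "disturbance": DISTURBANCES,
}


class EnumLabelError(ValueError):
    """A categorical label could not be mapped onto a canonical value."""


def normalize_label(field_name: str, raw: object, synonyms: Optional[dict[str, str]] = None) -> str:
    """Map a free-text categorical label to its canonical enum value.

    Matching is case-insensitive and treats spaces and hyphens as
    underscores; ``synonyms`` (defaulting to :data:`ENUM_SYNONYMS`) may add
    project-specific spellings. Raises :class:`EnumLabelError` if the label
    cannot be mapped.
    """
    table = ENUM_SYNONYMS if synonyms is None else {**ENUM_SYNONYMS, **synonyms}
    key = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
    domain = _ENUM_DOMAIN[field_name]
    if key in domain:
        return key
    if key in table and table[key] in domain:
        return table[key]
    raise EnumLabelError(f"{field_name}: unrecognized label {raw!r}")


@dataclass
class OutcomeMeasure:
    """A single outcome measure: one (start, end, reference) comparison."""

    study_id: str
    outcome_id: str
    metric: str
    x_start: float
    x_end: float
    x_ref: float
    t_years: float
    submetric: str = "none"
    ecosystem: Optional[str] = None
    disturbance: Optional[str] = None
    variance: Optional[float] = None  # sampling variance of the debt ratio; None = unreported
    organism: Optional[str] = None
    koppen: Optional[str] = None
    n_recovery_sites: Optional[int] = None
    n_reference_sites: Optional[int] = None
    area_km2: Optional[float] = None
    disturbance_duration_years: Optional[float] = None
    source_line: Optional[int] = None
    extras: dict = field(default_factory=dict)


def validate_record(r: OutcomeMeasure) -> list[str]:
    """Return a list of invariant violations for ``r`` (empty iff valid).

    Violations are data, not exceptions: each entry names the offending field
    and the broken rule so they can be collected into a rejects report.
    """
    out: list[str] = []
    for name in ("x_start", "x_end", "x_ref"):
        v = getattr(r, name)
        if not isinstance(v, (int, float)) or not math.isfinite(v):
            out.append(f"{name}: must be finite, got {v!r}")
    if not isinstance(r.t_years, (int, float)) or not math.isfinite(r.t_years) or r.t_years <= 0:
        out.append(f"t_years: must be > 0, got {r.t_years!r}")
    if r.variance is not None and (not math.isfinite(r.variance) or r.variance < 0):
        out.append(f"variance: must be >= 0 when present, got {r.variance!r}")
    if r.metric not in METRICS:
        out.append(f"metric: {r.metric!r} not in {METRICS}")
    if r.submetric not in SUBMETRICS:
        out.append(f"submetric: {r.submetric!r} not in {SUBMETRICS}")
    elif r.metric in METRICS and r.metric not in _SUBMETRIC_PARENTS[r.submetric]:
        out.append(
            f"submetric: {r.submetric!r} incompatible with metric {r.metric!r}"
        )
    if r.ecosystem is not None and r.ecosystem not in ECOSYSTEMS:
        out.append(f"ecosystem: {r.ecosystem!r} not in {ECOSYSTEMS}")
    if r.disturbance is not None and r.disturbance not in DISTURBANCES:
        out.append(f"disturbance: {r.disturbance!r} not in {DISTURBANCES}")
    for name in ("n_recovery_sites", "n_reference_sites"):
        v = getattr(r, name)
        if v is not None and (int(v) != v or v < 1):
            out.append(f"{name}: must be an integer >= 1, got {v!r}")
    for name in ("area_km2", "disturbance_duration_years"):
        v = getattr(r, name)
        if v is not None and (not math.isfinite(v) or v < 0):
            out.append(f"{name}: must be >= 0, got {v!r}")
    return out


def record_fields() -> list[str]:
    """Column order used when records are written to or read from tables."""
    return [f.name for f in fields(OutcomeMeasure) if f.name not in ("extras",)]
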