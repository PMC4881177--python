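"""Domain types for zones, supply sites and hospitals.

All coordinates are planar meters in a single projected frame; the package
never performs geodesic math. A *zone* is the smallest census unit (a basic
statistical area in the motivating setting, ~300 residents); a *supply
site* is either a fixed public AED reached on foot or an EMS station whose
ambulance carries an AED to the scene; both are modelled as points with a
service (catchment) radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

# Default catchment radii by supply type, meters. Derived from a 4-minute
# response budget: a bystander walks ~100 m/min round trip to a fixed AED
# (200 m), an ambulance drives one way at ~900 m/min (3600 m).
DEFAULT_CATCHMENT_M = {"onsite_aed": 200.0, "ems_station": 3600.0}

SITE_TYPES = frozenset(DEFAULT_CATCHMENT_M)

COVARIATE_FIELDS = (
    "pop_density",
    "pct_elderly",
    "pct_housing",
    "pct_transport",
    "pct_public",
)

PERCENT_FIELDS = ("pct_elderly", "pct_housing", "pct_transport", "pct_public")


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


class SchemaError(ValueError):
    """Raised when a required field/column is absent."""


@dataclass
class Zone:
    """One census zone: geometry or centroid plus demand covariates.

    ``observed_count`` is the number of adverse events (OHCA incidents)
    recorded in the zone over the study window.
    """

    zone_id: str
    centroid: tuple[float, float]
    population: float
    pop_density: float
    pct_elderly: float
    pct_housing: float
    pct_transport: float
    pct_public: float
    observed_count: int
    geometry: Optional[BaseGeometry] = None

    def __post_init__(self) -> None:
        if self.geometry is not None and self.centroid is None:
            c = self.geometry.centroid
            self.centroid = (c.x, c.y)
        if self.centroid is None:
            raise ValidationError(f"zone {self.zone_id}: no centroid and no geometry")
        x, y = self.centroid
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"zone {self.zone_id}: non-finite centroid")
        # Range violations (negative population, percentages outside
        # [0, 100]) are surfaced by io.validate_region, report-style, so a
        # suspect record can still be loaded and inspected.
        if self.observed_count != int(self.observed_count) or self.observed_count < 0:
            raise ValidationError(
                f"zone {self.zone_id}: observed_count must be a non-negative integer"
            )
        self.observed_count = int(self.observed_count)

    @classmethod
    def from_geometry(cls, zone_id: str, geometry, **attrs) -> "Zone":
        geom = geometry if isinstance(geometry, BaseGeometry) else _shapely_shape(geometry)
        c = geom.centroid
        return cls(zone_id=zone_id, centroid=(c.x, c.y), geometry=geom, **attrs)

    @property
    def covariates(self) -> tuple[float, ...]:
        return tuple(getattr(self, f) for f in COVARIATE_FIELDS)


@dataclass
class SupplySite:
    """A point supply of defibrillation: fixed AED or EMS (ambulance) station."""

    site_id: str
    site_type: str
    location: tuple[float, float]
    capacity: float = 1.0
    catchment_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValidationError(
                f"site {self.site_id}: unknown site_type {self.site_type!r} "
                f"(expected one of {sorted(SITE_TYPES)})"
            )
        if self.catchment_radius is None:
            self.catchment_radius = DEFAULT_CATCHMENT_M[self.site_type]
        if self.catchment_radius <= 0:
            raise ValidationError(f"site {self.site_id}: catchment_radius must be > 0")
        if self.capacity <= 0:
            raise ValidationError(f"site {self.site_id}: capacity must be > 0")
        x, y = self.location
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"site {self.site_id}: non-finite location")


@dataclass
class Hospital:
    """A hospital destination used only by the priority-ranking stage."""

    hospital_id: str
    location: tuple[float, float]

    def __post_init__(self) -> None:
        x, y = self.location
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValidationError(f"hospital {self.hospital_id}: non-finite location")


@dataclass
class StudyRegion:
    """A complete study area: zones, supply sites, hospitals."""

    zones: list[Zone] = field(default_factory=list)
    supply_sites: list[SupplySite] = field(default_factory=list)
    hospitals: list[Hospital] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def zone_ids(self) -> list[str]:
        return [z.zone_id for z in self.zones]


def _unique_ids(ids: Sequence[str]) -> list[str]:
    """Return the ids that occur more than once, in first-seen order."""
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups
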