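"""Priority ranking of underserved zones for AED deployment.

Zones whose accessibility score is zero (no supply reachable) are ordered
for deployment: zones more than 4 minutes from the nearest hospital (at
ambulance speed, 900 m/min) come first, and within each stratum larger
populations rank higher. The rationale: where a patient can be rushed to
a hospital quickly the marginal value of a community AED is lower, and
among remote zones an AED protects more people where more people live.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .accessibility import AccessibilityResult
from .datamodel import Hospital, ValidationError, Zone

logger = logging.getLogger(__name__)

AMBULANCE_SPEED_M_PER_MIN = 900.0
HOSPITAL_TIME_THRESHOLD_MIN = 4.0

FAR = "far_from_hospital"
NEAR = "near_hospital"


@dataclass
class RankedZone:
    zone_id: str
    accessibility: float
    travel_time_min: float
    stratum: str  # far_from_hospital | near_hospital
    population: float
    rank: int


def travel_time_to_nearest_hospital(
    zone: Zone,
    hospitals: Sequence[Hospital],
    speed: float = AMBULANCE_SPEED_M_PER_MIN,
) -> float:
    """Minutes from the zone centroid to the closest hospital, straight line."""
    if not hospitals:
        raise ValidationError("no hospitals given")
    if speed <= 0:
        raise ValidationError("speed must be > 0")
    return min(math.dist(zone.centroid, h.location) for h in hospitals) / speed


def rank_priority(
    result: AccessibilityResult,
    zones: Sequence[Zone],
    hospitals: Sequence[Hospital],
    *,
    access_threshold: float = 0.0,
    time_threshold_min: float = HOSPITAL_TIME_THRESHOLD_MIN,
    speed: float = AMBULANCE_SPEED_M_PER_MIN,
) -> list[RankedZone]:
    """Rank zones with accessibility <= ``access_threshold`` for deployment.

    Ordering: (1) far-from-hospital stratum (travel time > 4 min) before
    near-hospital; (2) descending population within stratum; (3) ascending
    zone_id as a deterministic tie-break. Ranks are contiguous from 1.
    Near-hospital zones are kept at the bottom of the list rather than
    dropped. Returns an empty list (with a log message) when no zone
    qualifies.
    """
    amap = result.as_dict()
    missing = [z.zone_id for z in zones if z.zone_id not in amap]
    if missing:
        raise ValidationError(f"accessibility missing for zone(s): {missing[:5]}")
    eligible = [z for z in zones if amap[z.zone_id] <= access_threshold]
    if not eligible:
        logger.warning("no zones at or below accessibility threshold %g",
                       access_threshold)
        return []
    entries = []
    for z in eligible:
        t = travel_time_to_nearest_hospital(z, hospitals, speed)
        stratum = FAR if t > time_threshold_min else NEAR
        entries.append((z, t, stratum))
    entries.sort(key=lambda e: (e[2] != FAR, -e[0].population, e[0].zone_id))
    return [
        RankedZone(
            zone_id=z.zone_id,
            accessibility=amap[z.zone_id],
            travel_time_min=t,
            stratum=stratum,
            population=z.population,
            rank=r,
        )
        for r, (z, t, stratum) in enumerate(entries, start=1)
    ]
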