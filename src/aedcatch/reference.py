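"""Published summary counts from the motivating Kaohsiung OHCA cohort.

The 2011-2013 Kaohsiung cohort (6135 usable out-of-hospital cardiac
arrests) is IRB-restricted, but its published marginal tables — the age
distribution of patients and the land-use classification of event
locations — are public summary statistics. They document the demand
profile the synthetic generator emulates (a majority of events among the
elderly, and a large majority in residential land use), and the derived
percentages are recomputed from these counts rather than hard-coded.
"""

from __future__ import annotations

OHCA_TOTAL = 6135

# Age distribution of OHCA patients (years -> patient count).
OHCA_AGE_COUNTS = {
    "0-14": 65,
    "15-64": 2494,
    "65+": 3488,
    "unknown": 88,
}

# OHCA incidents by first-level land-use classification of the event
# location; "housing" is the residential subcategory of built-up land.
OHCA_LANDUSE_COUNTS = {
    "agriculture": 34,
    "forest": 8,
    "transportation": 559,
    "water_conservation": 14,
    "built_up": 5240,
    "housing": 4849,          # subcategory of built_up
    "public": 167,
    "amusement_rest": 75,
    "rock_salt": 0,
    "other": 38,
}


def percentage_table(counts: dict[str, int], total: int) -> dict[str, float]:
    """Percentages (0-100) of ``total`` for each category, rounded to the
    two decimals conventionally printed in cohort tables."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def cohort_percentages() -> dict[str, float]:
    """All published cohort shares as percentages of the usable total."""
    out = {f"age_{k}": v for k, v in
           percentage_table(OHCA_AGE_COUNTS, OHCA_TOTAL).items()}
    out.update({f"landuse_{k}": v for k, v in
                percentage_table(OHCA_LANDUSE_COUNTS, OHCA_TOTAL).items()})
    return out
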