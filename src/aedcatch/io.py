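"""Readers, writers, validation and the density-outlier zone filter.

Formats: GeoJSON (RFC 7946 structure; coordinates are planar meters by
contract, not lon/lat) and CSV (comma-separated, header row, UTF-8, "."
decimal). Every tabular output carries a ``zone_id`` column so results can
be joined back onto zone geometries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from shapely.geometry import mapping as _shapely_mapping, shape as _shapely_shape

from .datamodel import (
    COVARIATE_FIELDS,
    PERCENT_FIELDS,
    Hospital,
    SchemaError,
    StudyRegion,
    SupplySite,
    ValidationError,
    Zone,
    _unique_ids,
)

logger = logging.getLogger(__name__)

_ZONE_ATTRS = (
    "population",
    "pop_density",
    "pct_elderly",
    "pct_housing",
    "pct_transport",
    "pct_public",
    "observed_count",
)


def _detect_format(path, format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix in (".geojson", ".json"):
        return "geojson"
    return "csv"


def _get_attr(props: dict, key: str, context: str) -> float:
    if key not in props or props[key] is None or props[key] == "":
        raise SchemaError(f"{context}: missing required field {key!r}")
    try:
        return float(props[key])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{context}: non-numeric value {props[key]!r} for {key!r}") from exc


def read_zones(path, format: Optional[str] = None) -> list[Zone]:
    """Read zones from a GeoJSON FeatureCollection or a CSV table.

    GeoJSON features need the attribute fields in ``properties`` plus a
    polygon (or point) geometry; centroids are computed from polygons.
    CSV rows need ``centroid_x``/``centroid_y`` columns instead.
    """
    fmt = _detect_format(path, format)
    zones: list[Zone] = []
    if fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        features = gj.get("features")
        if features is None:
            raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
        for idx, feat in enumerate(features):
            props = feat.get("properties") or {}
            ctx = f"{path} feature {idx}"
            if "zone_id" not in props:
                raise SchemaError(f"{ctx}: missing required field 'zone_id'")
            attrs = {k: _get_attr(props, k, ctx) for k in _ZONE_ATTRS}
            attrs["observed_count"] = int(attrs["observed_count"])
            geom = _shapely_shape(feat["geometry"])
            zones.append(Zone.from_geometry(str(props["zone_id"]), geom, **attrs))
    elif fmt == "csv":
        df = pd.read_csv(path, comment="#")
        required = ("zone_id", "centroid_x", "centroid_y") + _ZONE_ATTRS
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        for idx, row in df.iterrows():
            ctx = f"{path} row {idx}"
            attrs = {k: _get_attr(row, k, ctx) for k in _ZONE_ATTRS}
            attrs["observed_count"] = int(attrs["observed_count"])
            cx = _get_attr(row, "centroid_x", ctx)
            cy = _get_attr(row, "centroid_y", ctx)
            zones.append(Zone(zone_id=str(row["zone_id"]), centroid=(cx, cy), **attrs))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return zones


def read_supply_sites(path, format: Optional[str] = None) -> list[SupplySite]:
    """Read AED/EMS supply points from CSV or GeoJSON.

    Missing ``catchment_radius`` is filled by the type default (200 m for
    onsite AEDs, 3600 m for EMS stations); missing ``capacity`` defaults
    to 1.
    """
    fmt = _detect_format(path, format)
    rows: list[dict] = []
    if fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        for feat in gj.get("features", []):
            props = dict(feat.get("properties") or {})
            geom = _shapely_shape(feat["geometry"])
            props["x"], props["y"] = geom.centroid.x, geom.centroid.y
            rows.append(props)
    else:
        df = pd.read_csv(path, comment="#")
        for col in ("site_id", "site_type", "x", "y"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r}")
        rows = df.to_dict("records")

    sites: list[SupplySite] = []
    for idx, row in enumerate(rows):
        radius = row.get("catchment_radius")
        if radius is None or (isinstance(radius, float) and pd.isna(radius)) or radius == "":
            radius = None
        else:
            radius = float(radius)
        capacity = row.get("capacity")
        if capacity is None or (isinstance(capacity, float) and pd.isna(capacity)) or capacity == "":
            capacity = 1.0
        else:
            capacity = float(capacity)
        sites.append(
            SupplySite(
                site_id=str(row["site_id"]),
                site_type=str(row["site_type"]),
                location=(float(row["x"]), float(row["y"])),
                capacity=capacity,
                catchment_radius=radius,
            )
        )
    return sites


def read_hospitals(path, format: Optional[str] = None) -> list[Hospital]:
    fmt = _detect_format(path, format)
    if fmt == "geojson":
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        out = []
        for feat in gj.get("features", []):
            props = feat.get("properties") or {}
            geom = _shapely_shape(feat["geometry"])
            out.append(Hospital(str(props["hospital_id"]), (geom.centroid.x, geom.centroid.y)))
        return out
    df = pd.read_csv(path, comment="#")
    for col in ("hospital_id", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return [
        Hospital(str(r["hospital_id"]), (float(r["x"]), float(r["y"])))
        for r in df.to_dict("records")
    ]


def filter_density_outliers(
    zones: list[Zone], multiplier: float
) -> tuple[list[Zone], list[Zone]]:
    """Drop zones whose population density exceeds ``multiplier`` times the
    mean density of the *input* zones.

    The threshold is computed once from the original mean and is not
    iterated: re-applying the filter to its own output can remove further
    zones only because the survivor mean differs. This mirrors excluding a
    single extreme census tract before model fitting.
    """
    if not zones:
        raise ValidationError("filter_density_outliers: empty zone list")
    if multiplier <= 1:
        raise ValidationError("filter_density_outliers: multiplier must be > 1")
    mean_density = sum(z.pop_density for z in zones) / len(zones)
    threshold = multiplier * mean_density
    kept, removed = [], []
    for z in zones:
        (removed if z.pop_density > threshold else kept).append(z)
    for z in removed:
        logger.info(
            "removed density outlier zone %s (density %.6g > %.6g = %g x mean)",
            z.zone_id, z.pop_density, threshold, multiplier,
        )
    return kept, removed


def write_results(
    records: pd.DataFrame,
    path,
    format: Optional[str] = None,
    zones: Optional[Iterable[Zone]] = None,
) -> None:
    """Write a zone-keyed results table as CSV, or as GeoJSON joined onto
    zone geometries.

    Round-trip stable: values read back equal the written ones to 1e-9.
    """
    if "zone_id" not in records.columns:
        raise SchemaError("write_results: records must carry a zone_id column")
    fmt = _detect_format(path, format)
    if fmt == "csv":
        records.to_csv(path, index=False)
        return
    if fmt != "geojson":
        raise ValueError(f"unknown format {fmt!r}")
    if zones is None:
        raise ValueError("GeoJSON export needs the zones to join onto")
    by_id = {z.zone_id: z for z in zones}
    unknown = [zid for zid in records["zone_id"].astype(str) if zid not in by_id]
    if unknown:
        raise ValidationError(f"write_results: unknown zone_id(s) {unknown[:5]}")
    features = []
    for rec in records.to_dict("records"):
        z = by_id[str(rec["zone_id"])]
        if z.geometry is not None:
            geom = _shapely_mapping(z.geometry)
        else:
            geom = {"type": "Point", "coordinates": list(z.centroid)}
        features.append({"type": "Feature", "geometry": geom, "properties": rec})
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_zones(zones: list[Zone], path, format: Optional[str] = None) -> None:
    """Write zones in the same dialect :func:`read_zones` accepts."""
    fmt = _detect_format(path, format)
    if fmt == "geojson":
        features = []
        for z in zones:
            props = {"zone_id": z.zone_id}
            props.update({k: getattr(z, k) for k in _ZONE_ATTRS})
            if z.geometry is not None:
                geom = _shapely_mapping(z.geometry)
            else:
                geom = {"type": "Point", "coordinates": list(z.centroid)}
            features.append({"type": "Feature", "geometry": geom, "properties": props})
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
        return
    rows = []
    for z in zones:
        row = {"zone_id": z.zone_id, "centroid_x": z.centroid[0], "centroid_y": z.centroid[1]}
        row.update({k: getattr(z, k) for k in _ZONE_ATTRS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_supply_sites(sites: list[SupplySite], path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "site_type": s.site_type,
            "x": s.location[0],
            "y": s.location[1],
            "capacity": s.capacity,
            "catchment_radius": s.catchment_radius,
        }
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_hospitals(hospitals: list[Hospital], path) -> None:
    rows = [
        {"hospital_id": h.hospital_id, "x": h.location[0], "y": h.location[1]}
        for h in hospitals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_region(region: StudyRegion) -> list[str]:
    """Report-only validation: returns a list of violation messages,
    empty iff the region is internally consistent."""
    report: list[str] = []
    for dup in _unique_ids([z.zone_id for z in region.zones]):
        report.append(f"duplicate zone_id: {dup}")
    for dup in _unique_ids([s.site_id for s in region.supply_sites]):
        report.append(f"duplicate site_id: {dup}")
    for z in region.zones:
        if z.population < 0:
            report.append(f"zone {z.zone_id}: negative population")
        if z.pop_density < 0:
            report.append(f"zone {z.zone_id}: negative pop_density")
        for name in PERCENT_FIELDS:
            v = getattr(z, name)
            if not (0.0 <= v <= 100.0):
                report.append(f"zone {z.zone_id}: {name}={v} outside [0, 100]")
        x, y = z.centroid
        if not (pd.notna(x) and pd.notna(y)):
            report.append(f"zone {z.zone_id}: non-finite centroid")
    return report
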