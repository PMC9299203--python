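"""File formats: occurrence CSV/GeoJSON, regime CSV, scenario/config JSON,
assessment reports and the matrix grid.

Occurrence CSV columns: ``species_id, site_id, site_name, lat, lon,
management_area_id`` (one row per species × site, WGS84 decimal degrees,
point coordinates at site centroids). The optional GeoJSON reader accepts a
FeatureCollection of Point features carrying the same keys as properties,
with coordinates in [lon, lat] order per the GeoJSON standard.

Regime CSV columns: ``management_area_id, regime, jurisdiction, notes``
where ``regime`` is one of the four enum tokens.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .engine import Assessment, ThresholdTable
from .errors import ValidationError
from .geo import GeoConfig, VentField
from .scenarios import MatrixCell, Scenario
from .threats import RegulatoryRegime

__all__ = [
    "read_occurrences",
    "read_occurrences_csv",
    "read_occurrences_geojson",
    "write_occurrences_csv",
    "write_occurrences_geojson",
    "read_regimes",
    "write_regimes_csv",
    "read_scenario",
    "read_config",
    "write_assessment_json",
    "write_matrix",
]

_OCC_COLUMNS = ["species_id", "site_id", "site_name", "lat", "lon", "management_area_id"]


def _field_from_record(rec: Mapping[str, Any], row: int) -> tuple[str, VentField]:
    for col in _OCC_COLUMNS:
        if col not in rec or rec[col] is None or (
            isinstance(rec[col], float) and math.isnan(rec[col])
        ):
            raise ValidationError(f"missing value for '{col}'", row=row, field=col)
    for col in ("lat", "lon"):
        try:
            float(rec[col])
        except (TypeError, ValueError):
            raise ValidationError(
                f"non-numeric coordinate {rec[col]!r}", row=row, field=col
            ) from None
    fp = rec.get("footprint_km2")
    if fp is not None and isinstance(fp, float) and math.isnan(fp):
        fp = None
    try:
        vf = VentField(
            site_id=str(rec["site_id"]),
            name=str(rec["site_name"]),
            lat=float(rec["lat"]),
            lon=float(rec["lon"]),
            management_area_id=str(rec["management_area_id"]),
            footprint_km2=float(fp) if fp is not None else None,
        )
    except ValidationError as exc:
        raise ValidationError(str(exc), row=row) from None
    return str(rec["species_id"]), vf


def _group(records: list[tuple[str, VentField, int]]) -> dict[str, list[VentField]]:
    seen: set[tuple[str, str]] = set()
    grouped: dict[str, list[VentField]] = {}
    for species_id, vf, row in records:
        key = (species_id, vf.site_id)
        if key in seen:
            raise ValidationError(
                f"duplicate (species_id, site_id) = {key}", row=row, field="site_id"
            )
        seen.add(key)
        grouped.setdefault(species_id, []).append(vf)
    return grouped


def read_occurrences_csv(path: str | Path) -> dict[str, list[VentField]]:
    """Read an occurrence CSV, grouped by species, with row-level validation."""
    df = pd.read_csv(path, dtype={"species_id": str, "site_id": str,
                                  "site_name": str, "management_area_id": str})
    missing = [c for c in _OCC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    records = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        # data row numbers are 1-based (header excluded)
        records.append((*_field_from_record(rec, row=i + 1), i + 1))
    if not records:
        raise ValidationError("occurrence file contains no data rows")
    return _group(records)


def read_occurrences_geojson(path: str | Path) -> dict[str, list[VentField]]:
    """Read a GeoJSON FeatureCollection of site points, grouped by species."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("expected a GeoJSON FeatureCollection")
    records = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError("expected Point geometry", row=i + 1)
        lon, lat = geom["coordinates"][:2]
        rec = dict(feat.get("properties") or {})
        rec["lat"], rec["lon"] = lat, lon
        records.append((*_field_from_record(rec, row=i + 1), i + 1))
    if not records:
        raise ValidationError("GeoJSON file contains no features")
    return _group(records)


def read_occurrences(path: str | Path, format: str | None = None) -> dict[str, list[VentField]]:
    """Read occurrences from CSV or GeoJSON (inferred from the extension)."""
    path = Path(path)
    fmt = (format or ("geojson" if path.suffix.lower() in (".geojson", ".json") else "csv")).lower()
    if fmt == "csv":
        return read_occurrences_csv(path)
    if fmt == "geojson":
        return read_occurrences_geojson(path)
    raise ValidationError(f"unknown occurrence format {format!r}")


def write_occurrences_csv(
    grouped: Mapping[str, Sequence[VentField]], path: str | Path
) -> None:
    rows = []
    for species_id, fields in grouped.items():
        for f in fields:
            rows.append(
                {
                    "species_id": species_id,
                    "site_id": f.site_id,
                    "site_name": f.name,
                    "lat": f.lat,
                    "lon": f.lon,
                    "management_area_id": f.management_area_id,
                    "footprint_km2": f.footprint_km2,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_occurrences_geojson(
    grouped: Mapping[str, Sequence[VentField]], path: str | Path
) -> None:
    features = []
    for species_id, fields in grouped.items():
        for f in fields:
            props = {
                "species_id": species_id,
                "site_id": f.site_id,
                "site_name": f.name,
                "management_area_id": f.management_area_id,
            }
            if f.footprint_km2 is not None:
                props["footprint_km2"] = f.footprint_km2
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [f.lon, f.lat]},
                    "properties": props,
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def read_regimes(path: str | Path) -> dict[str, RegulatoryRegime]:
    """Read the management-area → regime table from CSV."""
    df = pd.read_csv(path, dtype=str)
    for col in ("management_area_id", "regime"):
        if col not in df.columns:
            raise ValidationError(f"missing column(s): {col}")
    regimes: dict[str, RegulatoryRegime] = {}
    for i, rec in enumerate(df.to_dict(orient="records")):
        area = rec["management_area_id"]
        if area in regimes:
            raise ValidationError(f"duplicate management_area_id {area!r}", row=i + 1)
        regimes[area] = RegulatoryRegime.from_token(rec["regime"])
    if not regimes:
        raise ValidationError("regime file contains no data rows")
    return regimes


def write_regimes_csv(
    regimes: Mapping[str, RegulatoryRegime],
    path: str | Path,
    jurisdictions: Mapping[str, str] | None = None,
) -> None:
    rows = [
        {
            "management_area_id": area,
            "regime": regime.name,
            "jurisdiction": (jurisdictions or {}).get(area, ""),
            "notes": "",
        }
        for area, regime in regimes.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenario(path: str | Path) -> Scenario:
    """Read a scenario JSON: {name, description, overrides: {area: regime}}."""
    with open(path) as fh:
        doc = json.load(fh)
    if "overrides" not in doc or not isinstance(doc["overrides"], dict):
        raise ValidationError("scenario JSON requires an 'overrides' object")
    overrides = {
        area: RegulatoryRegime.from_token(token)
        for area, token in doc["overrides"].items()
    }
    return Scenario(
        name=str(doc.get("name", Path(path).stem)),
        regime_overrides=overrides,
        description=str(doc.get("description", "")),
    )


def read_config(path: str | Path) -> tuple[GeoConfig, ThresholdTable]:
    """Read a config JSON with optional 'geo' and 'thresholds' sections."""
    with open(path) as fh:
        doc = json.load(fh)
    geo = GeoConfig(**doc.get("geo", {}))
    thresholds = ThresholdTable(**doc.get("thresholds", {}))
    return geo, thresholds


def write_assessment_json(assessment: Assessment, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(assessment.to_dict(), fh, indent=1)


def write_matrix(cells: Sequence[MatrixCell], csv_path: str | Path,
                 json_path: str | Path | None = None) -> None:
    """Write the location-threat matrix as a band × regime CSV grid (and
    optionally as JSON with provenance tags)."""
    bands = list(dict.fromkeys(c.n_locations_band for c in cells))
    rows = list(dict.fromkeys(c.regime_row for c in cells))
    by_key = {(c.n_locations_band, c.regime_row): c for c in cells}
    grid = pd.DataFrame(
        {band: [by_key[(band, row)].label for row in rows] for band in bands},
        index=pd.Index(rows, name="regime"),
    )
    grid.columns.name = "n_locations"
    grid.to_csv(csv_path)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(
                [
                    {
                        "n_locations_band": c.n_locations_band,
                        "regime_row": c.regime_row,
                        "category": c.category.name,
                        "possibly_extinct": c.possibly_extinct,
                        "provenance": c.provenance,
                    }
                    for c in cells
                ],
                fh,
                indent=1,
            )
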