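"""Serialization of regions and surfaces to GeoJSON, CSV and YAML.

Coordinates are planar metres; cell ids are row-major from the
southwest corner.  All JSON is written with sorted keys so that equal
regions serialize to byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .access import DemandCell, Facility
from .network import RoadSegment
from .synthetic import RegionConfig, StudyRegion

NETWORK_FILE = "network.geojson"
CELLS_GEOJSON = "cells.geojson"
CELLS_CSV = "cells.csv"
FACILITIES_GEOJSON = "facilities.geojson"
FACILITIES_CSV = "facilities.csv"
REGION_META = "region.json"
CONFIG_FILE = "config.yaml"


def _feature(geom_type: str, coords, props: dict) -> dict:
    return {"type": "Feature",
            "geometry": {"type": geom_type, "coordinates": coords},
            "properties": props}


def _dump_geojson(features: list[dict], path: Path) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def network_to_geojson(segments: list[RoadSegment], path) -> None:
    feats = [
        _feature(
            "LineString",
            [list(c) for c in s.coords],
            {"road_class": s.road_class, "speed_kmh": s.speed_kmh, "is_rail": s.is_rail},
        )
        for s in segments
    ]
    _dump_geojson(feats, Path(path))


def network_from_geojson(path) -> list[RoadSegment]:
    doc = json.loads(Path(path).read_text())
    return [
        RoadSegment(
            tuple(tuple(c) for c in f["geometry"]["coordinates"]),
            f["properties"]["road_class"],
            f["properties"]["speed_kmh"],
        )
        for f in doc["features"]
    ]


def cells_to_frame(cells: list[DemandCell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x": [c.x for c in cells],
            "y": [c.y for c in cells],
            "population": [c.population for c in cells],
            "aging_count": [c.aging_count for c in cells],
            "agricultural_count": [c.agricultural_count for c in cells],
            "county_id": [c.county_id for c in cells],
            "city_id": [c.city_id for c in cells],
            "subdivision": [c.subdivision for c in cells],
        }
    )


def cells_from_frame(df: pd.DataFrame) -> list[DemandCell]:
    return [
        DemandCell(
            id=int(r.id), x=float(r.x), y=float(r.y), population=float(r.population),
            aging_count=float(r.aging_count), agricultural_count=float(r.agricultural_count),
            county_id=str(r.county_id), city_id=int(r.city_id), subdivision=str(r.subdivision),
        )
        for r in df.itertuples()
    ]


def facilities_to_frame(facilities: list[Facility]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f.id for f in facilities],
            "x": [f.x for f in facilities],
            "y": [f.y for f in facilities],
            "level": [f.level for f in facilities],
            "staff": [f.staff for f in facilities],
            "capacity_weight": [f.capacity_weight for f in facilities],
            "city_id": [f.city_id for f in facilities],
        }
    )


def facilities_from_frame(df: pd.DataFrame) -> list[Facility]:
    return [
        Facility(
            id=int(r.id), x=float(r.x), y=float(r.y), level=str(r.level),
            staff=float(r.staff), capacity_weight=float(r.capacity_weight),
            city_id=int(r.city_id),
        )
        for r in df.itertuples()
    ]


def _points_geojson(df: pd.DataFrame, path: Path) -> None:
    feats = []
    for r in df.to_dict("records"):
        props = {k: v for k, v in r.items() if k not in ("x", "y")}
        feats.append(_feature("Point", [r["x"], r["y"]], props))
    _dump_geojson(feats, path)


def save_region(region: StudyRegion, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    network_to_geojson(region.segments, d / NETWORK_FILE)
    cdf = cells_to_frame(region.cells)
    cdf.to_csv(d / CELLS_CSV, index=False)
    _points_geojson(cdf, d / CELLS_GEOJSON)
    fdf = facilities_to_frame(region.facilities)
    fdf.to_csv(d / FACILITIES_CSV, index=False)
    _points_geojson(fdf, d / FACILITIES_GEOJSON)
    meta = {
        "capital_city_id": region.capital_city_id,
        "subdivisions": {str(k): v for k, v in region.subdivisions.items()},
    }
    (d / REGION_META).write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    if region.config is not None:
        (d / CONFIG_FILE).write_text(yaml.safe_dump(region.config.to_dict(), sort_keys=True))


def load_region(directory) -> StudyRegion:
    d = Path(directory)
    segments = network_from_geojson(d / NETWORK_FILE)
    cells = cells_from_frame(pd.read_csv(d / CELLS_CSV))
    facilities = facilities_from_frame(pd.read_csv(d / FACILITIES_CSV))
    meta = json.loads((d / REGION_META).read_text())
    config = None
    cfg_path = d / CONFIG_FILE
    if cfg_path.exists():
        config = RegionConfig.from_dict(yaml.safe_load(cfg_path.read_text()))
    return StudyRegion(
        segments=segments,
        cells=cells,
        facilities=facilities,
        subdivisions={int(k): v for k, v in meta["subdivisions"].items()},
        capital_city_id=meta["capital_city_id"],
        config=config,
    )


def surface_to_geojson(surface, cells, path) -> None:
    feats = [
        _feature("Point", [c.x, c.y], {"cell_id": c.id, surface.label: float(v)})
        for c, v in zip(cells, surface.values)
    ]
    _dump_geojson(feats, Path(path))
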