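"""Readers and writers for the fix/metadata/territory file dialects.

All coordinates are planar metres in a projected CRS. Tables that look
like geographic lon/lat degrees are refused outright — reprojection is a
pre-processing concern and silently treating degrees as metres would
corrupt every distance in the analysis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .geometry import TerritoryMap, TerritoryPolygon

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["animal_id", "group_id", "timestamp", "x", "y"]
ANIMAL_COLUMNS = ["animal_id", "group_id", "sex", "birth_year"]
EXCLUSION_COLUMNS = ["animal_id", "start_date", "end_date"]


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_fixes(path) -> pd.DataFrame:
    """Read a GPS fix table (CSV): typed, sorted, de-duplicated, units-checked."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, FIX_COLUMNS, path)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:20]  # 1-based incl. header
        raise SchemaError(f"{path}: unparseable timestamps at rows {rows}")
    if df["timestamp"].isna().any() or df[["x", "y"]].isna().any().any():
        raise SchemaError(f"{path}: missing timestamp or coordinate values")
    df = df.assign(timestamp=ts)
    df[["x", "y"]] = df[["x", "y"]].astype(float)

    if len(df) and df["x"].abs().le(180).all() and df["y"].abs().le(90).all():
        raise SchemaError(
            f"{path}: coordinates all lie within lon/lat degree ranges; "
            "this reader requires planar metres — reproject to a metric CRS first"
        )
    n_before = len(df)
    df = df.drop_duplicates(subset=["animal_id", "timestamp"], keep="first")
    if len(df) < n_before:
        logger.warning("%s: collapsed %d duplicate (animal, timestamp) rows",
                       path, n_before - len(df))
    return df.sort_values(["animal_id", "timestamp"], kind="stable").reset_index(drop=True)


def read_animals(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ANIMAL_COLUMNS, path)
    if df["animal_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate animal_id rows")
    if "breeding_status" not in df.columns:
        df["breeding_status"] = "unknown"
    df["birth_year"] = df["birth_year"].astype(int)
    return df


def read_exclusions(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, EXCLUSION_COLUMNS, path)
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    if (df["end_date"] < df["start_date"]).any():
        raise SchemaError(f"{path}: exclusion period ends before it starts")
    return df


def write_territories(maps: dict[int, TerritoryMap] | TerritoryMap, path) -> None:
    """Territory polygons as a GeoJSON FeatureCollection (planar metres)."""
    if isinstance(maps, TerritoryMap):
        maps = {maps.year: maps}
    features = []
    for year in sorted(maps):
        tmap = maps[year]
        for gid in tmap.groups():
            tp = tmap[gid]
            features.append({
                "type": "Feature",
                "properties": {"group_id": str(tp.group_id), "year": int(tp.year),
                               "source": tp.source},
                "geometry": mapping(tp.polygon),
            })
    doc = {
        "type": "FeatureCollection",
        "properties": {"crs_note": "planar projected coordinates in metres, not WGS84"},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_territories(path) -> dict[int, TerritoryMap]:
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    by_year: dict[int, dict[str, TerritoryPolygon]] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        try:
            gid, year = str(props["group_id"]), int(props["year"])
        except KeyError as exc:
            raise SchemaError(f"{path}: feature missing property {exc}") from exc
        tp = TerritoryPolygon(
            group_id=gid, year=year, polygon=shape(feat["geometry"]),
            source=props.get("source", "provided"),
        )
        if gid in by_year.setdefault(year, {}):
            raise SchemaError(f"{path}: duplicate polygon for group {gid} in {year}")
        by_year[year][gid] = tp
    return {year: TerritoryMap(year=year, polygons=polys)
            for year, polys in sorted(by_year.items())}


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
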