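"""Geospatial and tabular IO: GeoJSON geometries joined to CSV attributes.

The unit of analysis is an areal table: one polygon per administrative unit
plus numeric percentage attributes keyed by a shared unit ID.  Geometry
input/output is GeoJSON (FeatureCollection); attributes travel as plain CSV.
Invalid polygons are repaired by zero-width buffering with a warning rather
than rejected, since administrative boundary files routinely contain
slivers.  Missing or non-numeric attribute values are an error, never
imputed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)


@dataclass
class AreaTable:
    """Areal units: aligned ids, shapely geometries, and a numeric
    attribute frame indexed by unit id."""

    ids: list[str]
    geometries: list
    attributes: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.geometries):
            raise ValueError("ids and geometries length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("unit ids are not unique")
        if len(self.attributes) != len(self.ids):
            raise ValueError("attribute rows do not match units")

    @property
    def n(self) -> int:
        return len(self.ids)


def _read_geojson(path, id_field: str):
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    ids, geoms = [], []
    for k, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise ValueError(f"{path}: feature {k} lacks id field {id_field!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            logger.warning(
                "%s: repairing invalid geometry for unit %s", path, props[id_field]
            )
            geom = geom.buffer(0)
        ids.append(str(props[id_field]))
        geoms.append(geom)
    return ids, geoms


def read_areas(geometry_path, attribute_path, id_field: str) -> AreaTable:
    """Inner-join GeoJSON geometries with a CSV attribute table on
    ``id_field``; unmatched IDs on either side are logged.

    Raises on duplicate IDs, zero matched IDs, or any non-numeric attribute
    cell (identified by row and column).
    """
    ids, geoms = _read_geojson(geometry_path, id_field)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{geometry_path}: duplicate unit ids")
    attrs = pd.read_csv(attribute_path, dtype={id_field: str})
    if id_field not in attrs.columns:
        raise ValueError(f"{attribute_path}: missing id column {id_field!r}")
    if attrs[id_field].duplicated().any():
        dupes = attrs[id_field][attrs[id_field].duplicated()].tolist()
        raise ValueError(f"{attribute_path}: duplicate ids {dupes}")
    attrs = attrs.set_index(id_field)
    for col in attrs.columns:
        coerced = pd.to_numeric(attrs[col], errors="coerce")
        bad = attrs.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{attribute_path}: non-numeric value in column {col!r} "
                f"at unit(s) {list(bad[:5])}"
            )
        attrs[col] = coerced.astype(float)

    geo_ids = set(ids)
    csv_ids = set(attrs.index)
    matched = [u for u in ids if u in csv_ids]
    if not matched:
        raise ValueError("no unit ids matched between geometry and attributes")
    orphans_geo = sorted(geo_ids - csv_ids)
    orphans_csv = sorted(csv_ids - geo_ids)
    if orphans_geo:
        logger.warning("%d geometry id(s) without attributes: %s", len(orphans_geo), orphans_geo[:10])
    if orphans_csv:
        logger.warning("%d attribute id(s) without geometry: %s", len(orphans_csv), orphans_csv[:10])
    keep = {u: g for u, g in zip(ids, geoms) if u in csv_ids}
    out_ids = list(keep)
    return AreaTable(
        ids=out_ids,
        geometries=[keep[u] for u in out_ids],
        attributes=attrs.loc[out_ids],
    )


def write_geojson(area: AreaTable, path, properties: pd.DataFrame | None = None, id_field: str = "unit_id") -> None:
    """Write the units as a GeoJSON FeatureCollection; ``properties`` (a
    frame indexed like the units) adds per-feature fields."""
    feats = []
    for i, (uid, geom) in enumerate(zip(area.ids, area.geometries)):
        props = {id_field: uid}
        if properties is not None:
            row = properties.iloc[i]
            for key, val in row.items():
                props[str(key)] = _jsonable(val)
        feats.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _jsonable(val):
    if isinstance(val, (np.floating, float)):
        return float(f"{float(val):.12g}")
    if isinstance(val, (np.integer, int)):
        return int(val)
    return str(val)


CLUSTER_LABELS = ("HH", "LL", "HL", "LH", "NS")


def write_cluster_geojson(
    area: AreaTable,
    labels,
    stats,
    p_values,
    path,
    id_field: str = "unit_id",
) -> None:
    """Significant-cluster map: each feature carries the unit id, the local
    statistic, its pseudo p-value, and a label in {HH, LL, HL, LH, NS}."""
    labels = list(labels)
    stats = np.asarray(stats, dtype=float)
    p_values = np.asarray(p_values, dtype=float)
    if not (len(labels) == len(stats) == len(p_values) == area.n):
        raise ValueError("labels/stats/p_values must align with units")
    bad = sorted({l for l in labels} - set(CLUSTER_LABELS))
    if bad:
        raise ValueError(f"unknown cluster labels: {bad}")
    props = pd.DataFrame(
        {"local_i": stats, "p_sim": p_values, "label": labels},
        index=area.ids,
    )
    write_geojson(area, path, properties=props, id_field=id_field)


def read_cluster_geojson(path, id_field: str = "unit_id") -> pd.DataFrame:
    """Read back a cluster GeoJSON into a frame of (label, local_i, p_sim)
    indexed by unit id."""
    with open(path) as fh:
        gj = json.load(fh)
    rows = {}
    for feat in gj["features"]:
        p = feat["properties"]
        rows[str(p[id_field])] = {
            "local_i": float(p["local_i"]),
            "p_sim": float(p["p_sim"]),
            "label": str(p["label"]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
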