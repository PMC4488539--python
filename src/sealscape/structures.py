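"""Anthropogenic sea-floor structure geometries.

Four structure classes are modelled: pipelines and cable routes (polylines)
and wells and shipwrecks (points). Pipelines and cables are kept as separate
collections but are merged into a single "pipes/cables" layer for distance
rasters and habitat models, matching how they are treated as one explanatory
variable in the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from shapely.geometry import LineString, Point, mapping, shape
from shapely.ops import unary_union

STRUCTURE_TYPES = ("pipeline", "cable", "well", "shipwreck")

#: structure types grouped as they enter the analysis
LAYER_GROUPS = {
    "pipes_cables": ("pipeline", "cable"),
    "wells": ("well",),
    "shipwrecks": ("shipwreck",),
}


@dataclass
class StructureSet:
    """Collections of structure geometries in planar metre coordinates."""

    pipelines: list = field(default_factory=list)
    cables: list = field(default_factory=list)
    wells: list = field(default_factory=list)
    shipwrecks: list = field(default_factory=list)

    def geometries(self, types=STRUCTURE_TYPES) -> list:
        """All geometries whose structure type is in ``types``."""
        out = []
        for stype in types:
            out.extend(self._collection(stype))
        return out

    def _collection(self, stype: str) -> list:
        try:
            return {
                "pipeline": self.pipelines,
                "cable": self.cables,
                "well": self.wells,
                "shipwreck": self.shipwrecks,
            }[stype]
        except KeyError:
            raise ValueError(f"unknown structure type {stype!r}") from None

    def union(self, types=STRUCTURE_TYPES):
        geoms = self.geometries(types)
        if not geoms:
            return None
        return unary_union(geoms)

    def is_empty(self) -> bool:
        return not any(
            (self.pipelines, self.cables, self.wells, self.shipwrecks)
        )

    def counts(self) -> dict:
        return {
            "pipeline": len(self.pipelines),
            "cable": len(self.cables),
            "well": len(self.wells),
            "shipwreck": len(self.shipwrecks),
        }

    # -- GeoJSON round trip ------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for stype in STRUCTURE_TYPES:
            for geom in self._collection(stype):
                features.append(
                    {
                        "type": "Feature",
                        "geometry": mapping(geom),
                        "properties": {"stype": stype},
                    }
                )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "StructureSet":
        ss = cls()
        for feat in obj.get("features", []):
            stype = feat.get("properties", {}).get("stype")
            if stype not in STRUCTURE_TYPES:
                raise ValueError(f"feature missing valid 'stype': {stype!r}")
            ss._collection(stype).append(shape(feat["geometry"]))
        return ss

    @classmethod
    def read_geojson(cls, path) -> "StructureSet":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def make_point(x: float, y: float) -> Point:
    return Point(float(x), float(y))


def make_polyline(coords) -> LineString:
    return LineString([(float(x), float(y)) for x, y in coords])
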