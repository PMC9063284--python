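"""Minimal vector-layer plumbing: typed feature lists and GeoJSON I/O.

Vector layers are plain lists of ``(shapely geometry, properties dict)``
pairs in the same planar metric frame as the rasters.  GeoJSON is used as
the on-disk format (coordinates are metres, not lon/lat; the files are
self-contained within a synthetic scenario).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

Feature = tuple[BaseGeometry, dict[str, Any]]


def write_geojson(features: Iterable[Feature], path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": props}
            for geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(fc, sort_keys=True))


def read_geojson(path: str | Path) -> list[Feature]:
    fc = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties") or {})
            for f in fc["features"]]
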