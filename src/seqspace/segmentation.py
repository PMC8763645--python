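"""Cell segmentation polygons with embryo / z-slice / FOV provenance.

Coordinates are continuous pixel units with the origin at the FOV top-left
and y increasing downward, matching image-derived segmentations.  Polygons
are ordered vertex lists, implicitly closed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = ["SegmentedCell", "SegmentationSet"]


@dataclass(frozen=True)
class SegmentedCell:
    cell_id: int
    embryo: str
    z_slice: int
    fov: int
    vertices: np.ndarray  # (n, 2) pixels

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon.centroid.coords[0])


@dataclass
class SegmentationSet:
    """Collection of per-cell polygons keyed by unique ``cell_id``."""

    cells: list[SegmentedCell] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def subset(self, cell_ids) -> "SegmentationSet":
        keep = set(cell_ids)
        return SegmentationSet([c for c in self.cells if c.cell_id in keep])

    def strata(self):
        """Iterate (embryo, z_slice) -> list of cells."""
        groups: dict[tuple, list[SegmentedCell]] = {}
        for c in self.cells:
            groups.setdefault((c.embryo, c.z_slice), []).append(c)
        return sorted(groups.items())

    def fovs(self):
        """Iterate (embryo, z_slice, fov) -> list of cells."""
        groups: dict[tuple, list[SegmentedCell]] = {}
        for c in self.cells:
            groups.setdefault((c.embryo, c.z_slice, c.fov), []).append(c)
        return sorted(groups.items())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            cx, cy = c.centroid
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "embryo": c.embryo,
                    "z_slice": c.z_slice,
                    "fov": c.fov,
                    "area": c.area,
                    "x": cx,
                    "y": cy,
                }
            )
        return pd.DataFrame(rows).set_index("cell_id")

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self) -> dict:
        features = []
        for c in self.cells:
            ring = [[float(x), float(y)] for x, y in c.vertices]
            if ring and ring[0] != ring[-1]:
                ring = ring + [ring[0]]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "cell_id": c.cell_id,
                        "embryo": c.embryo,
                        "z_slice": c.z_slice,
                        "fov": c.fov,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, obj: dict) -> "SegmentationSet":
        cells = []
        for feat in obj["features"]:
            props = feat["properties"]
            ring = feat["geometry"]["coordinates"][0]
            verts = np.asarray(ring[:-1] if ring[0] == ring[-1] else ring, dtype=float)
            cells.append(
                SegmentedCell(
                    cell_id=int(props["cell_id"]),
                    embryo=str(props["embryo"]),
                    z_slice=int(props["z_slice"]),
                    fov=int(props["fov"]),
                    vertices=verts,
                )
            )
        return cls(cells)

    @classmethod
    def read_geojson(cls, path) -> "SegmentationSet":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))
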