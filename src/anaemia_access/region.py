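"""Domain containers for the study region.

The analysis world is planar (coordinates in metres): a stack of aligned
rasters describing the landscape, a hospital location, and a tiling of the
region into enumeration areas (EAs) — census micro-units of roughly 100
households that act as the "village" spatial unit to which admissions are
geolocated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .raster import RasterGrid

__all__ = [
    "ROAD_CLASSES",
    "LAND_COVER_CLASSES",
    "LandscapeLayers",
    "EnumerationArea",
    "eas_to_geojson",
    "eas_from_geojson",
    "eas_to_frame",
]

# Integer codes used in the categorical rasters.
ROAD_CLASSES: dict[int, str] = {0: "none", 1: "tarmac", 2: "gravel", 3: "earth"}
LAND_COVER_CLASSES: dict[int, str] = {
    1: "builtup",
    2: "cultivated",
    3: "grassland",
    4: "bushland",
    5: "forest",
}


@dataclass
class LandscapeLayers:
    """Aligned raster stack describing the physical region.

    ``road_class`` and ``land_cover`` are categorical (integer codes per
    :data:`ROAD_CLASSES` / :data:`LAND_COVER_CLASSES`), ``barrier_mask`` marks
    impassable cells (water bodies, protected areas), ``altitude`` is metres
    above sea level.  ``hospital_xy`` is the planar location of the referral
    hospital offering emergency care.
    """

    road_class: RasterGrid
    land_cover: RasterGrid
    barrier_mask: RasterGrid
    altitude: RasterGrid
    hospital_xy: tuple[float, float]

    def __post_init__(self) -> None:
        ref = self.road_class
        for name in ("land_cover", "barrier_mask", "altitude"):
            layer: RasterGrid = getattr(self, name)
            if not ref.same_grid(layer):
                raise ValueError(f"layer {name!r} is not aligned with road_class")
        r, c = self.hospital_rowcol
        if bool(self.barrier_mask.data[r, c]):
            raise ValueError("hospital pixel falls on a barrier cell")

    @property
    def pixel_size(self) -> float:
        return self.road_class.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.road_class.shape

    @property
    def hospital_rowcol(self) -> tuple[int, int]:
        return self.road_class.xy_to_rowcol(*self.hospital_xy)

    def write_dir(self, outdir: str | Path) -> None:
        """Write every layer as an ASCII grid plus a small JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.road_class.write_ascii(outdir / "road_class.asc")
        self.land_cover.write_ascii(outdir / "land_cover.asc")
        RasterGrid(
            self.barrier_mask.data.astype(int),
            self.barrier_mask.pixel_size,
            self.barrier_mask.origin,
        ).write_ascii(outdir / "barrier_mask.asc")
        self.altitude.write_ascii(outdir / "altitude.asc")
        meta = {"hospital_xy": list(self.hospital_xy)}
        (outdir / "landscape.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read_dir(cls, indir: str | Path) -> "LandscapeLayers":
        indir = Path(indir)
        meta = json.loads((indir / "landscape.json").read_text())
        barrier = RasterGrid.read_ascii(indir / "barrier_mask.asc")
        barrier.data = barrier.data.astype(bool)
        return cls(
            road_class=RasterGrid.read_ascii(indir / "road_class.asc"),
            land_cover=RasterGrid.read_ascii(indir / "land_cover.asc"),
            barrier_mask=barrier,
            altitude=RasterGrid.read_ascii(indir / "altitude.asc"),
            hospital_xy=tuple(meta["hospital_xy"]),
        )


@dataclass
class EnumerationArea:
    """One census enumeration area.

    pop_u5 is the resident under-five population, ntl the mean night-time
    light value (NTL > 0 classifies the EA as urban), pfpr the community
    *P. falciparum* parasite rate in 2-10 year olds (fraction in [0, 1]),
    mean_altitude_m the EA-mean altitude used for haemoglobin adjustment.
    mean_travel_min is filled in by the accessibility stage.
    """

    ea_id: str
    polygon: BaseGeometry
    centroid: tuple[float, float]
    pop_u5: int
    ntl: float
    pfpr: float
    mean_altitude_m: float = 1200.0
    mean_travel_min: float | None = None

    def __post_init__(self) -> None:
        if self.pop_u5 < 0:
            raise ValueError("pop_u5 must be non-negative")
        if not 0.0 <= self.pfpr <= 1.0:
            raise ValueError("pfpr must lie in [0, 1]")
        if self.ntl < 0:
            raise ValueError("ntl must be non-negative")

    @property
    def urban(self) -> bool:
        return self.ntl > 0


def eas_to_geojson(eas: list[EnumerationArea], path: str | Path) -> None:
    """Write EAs as a GeoJSON FeatureCollection (planar metre coordinates)."""
    features = []
    for ea in eas:
        props = {
            "ea_id": ea.ea_id,
            "pop_u5": int(ea.pop_u5),
            "ntl": float(ea.ntl),
            "pfpr": float(ea.pfpr),
            "mean_altitude_m": float(ea.mean_altitude_m),
            "centroid_x": float(ea.centroid[0]),
            "centroid_y": float(ea.centroid[1]),
        }
        if ea.mean_travel_min is not None:
            props["mean_travel_min"] = float(ea.mean_travel_min)
        features.append(
            {"type": "Feature", "geometry": mapping(ea.polygon), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def eas_from_geojson(path: str | Path) -> list[EnumerationArea]:
    doc = json.loads(Path(path).read_text())
    eas = []
    for feat in doc["features"]:
        p = feat["properties"]
        eas.append(
            EnumerationArea(
                ea_id=str(p["ea_id"]),
                polygon=shape(feat["geometry"]),
                centroid=(p["centroid_x"], p["centroid_y"]),
                pop_u5=int(p["pop_u5"]),
                ntl=float(p["ntl"]),
                pfpr=float(p["pfpr"]),
                mean_altitude_m=float(p.get("mean_altitude_m", 1200.0)),
                mean_travel_min=p.get("mean_travel_min"),
            )
        )
    return eas


def eas_to_frame(eas: list[EnumerationArea]) -> pd.DataFrame:
    """Tabular view of EA attributes (no geometry)."""
    return pd.DataFrame(
        {
            "ea_id": [ea.ea_id for ea in eas],
            "centroid_x": [ea.centroid[0] for ea in eas],
            "centroid_y": [ea.centroid[1] for ea in eas],
            "pop_u5": [ea.pop_u5 for ea in eas],
            "ntl": [ea.ntl for ea in eas],
            "urban": [ea.urban for ea in eas],
            "pfpr": [ea.pfpr for ea in eas],
            "mean_altitude_m": [ea.mean_altitude_m for ea in eas],
            "mean_travel_min": [ea.mean_travel_min for ea in eas],
        }
    )
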