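#!/usr/bin/env python
"""Travel-time modelling: friction surface, least-cost paths, EA means.

Reads the landscape from results/region/, computes the travel-time raster
to the hospital and the per-EA mean travel times with 30-min classes and
15-min bands, and writes them under results/traveltime/.
"""

import argparse
from pathlib import Path

import pandas as pd

from anaemia_access.accessibility import (
    SpeedTable,
    build_friction_surface,
    least_cost_travel_time,
    zonal_mean_travel_time,
)
from anaemia_access.region import LandscapeLayers, eas_from_geojson, eas_to_geojson


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    region_dir = args.results / "region"
    layers = LandscapeLayers.read_dir(region_dir)
    eas = eas_from_geojson(region_dir / "eas.geojson")

    friction = build_friction_surface(layers, SpeedTable.default())
    tt = least_cost_travel_time(friction, layers.hospital_rowcol)
    zonal = zonal_mean_travel_time(tt, eas)

    outdir = args.results / "traveltime"
    outdir.mkdir(parents=True, exist_ok=True)
    tt.grid.write_ascii(outdir / "travel_time_min.asc")
    zonal.to_csv(outdir / "ea_travel_time.csv", index=False)
    eas_to_geojson(eas, outdir / "eas_with_travel.geojson")

    ok = zonal["mean_travel_min"].notna()
    print(
        f"Travel time computed for {ok.sum()}/{len(zonal)} EAs "
        f"(median {zonal.loc[ok, 'mean_travel_min'].median():.1f} min, "
        f"max {zonal.loc[ok, 'mean_travel_min'].max():.1f} min)."
    )
    print("EA counts per 30-min class:")
    print(zonal.loc[ok, "class30"].value_counts().to_string())
    print(f"Outputs in {outdir}/")


if __name__ == "__main__":
    main()
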