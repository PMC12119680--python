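#!/usr/bin/env python
"""Generate the synthetic study region: landscape raster stack + EA tiling.

Writes ASCII-grid layers (road class, land cover, barrier mask, altitude),
the EA label grid and the EA GeoJSON under results/region/.
"""

import argparse
from pathlib import Path

from anaemia_access.region import eas_to_frame
from anaemia_access.synthetic import RegionConfig, generate_landscape


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    region = generate_landscape(RegionConfig(), seed=args.seed)
    outdir = args.results / "region"
    region.write_dir(outdir)

    frame = eas_to_frame(region.eas)
    frame.to_csv(outdir / "ea_attributes.csv", index=False)
    n_urban = int(frame["urban"].sum())
    print(
        f"Simulated a {region.layers.shape[0]}x{region.layers.shape[1]} region "
        f"({region.layers.pixel_size:.0f} m pixels) with {len(region.eas)} EAs; "
        f"{n_urban} EAs are urban (NTL > 0), total under-5 population "
        f"{frame['pop_u5'].sum():,}."
    )
    print(f"Outputs in {outdir}/")


if __name__ == "__main__":
    main()
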