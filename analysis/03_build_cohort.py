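#!/usr/bin/env python
"""Simulate the admissions register and build the analysis cohort.

Admissions are simulated from the generative severity model (travel-time
effects + covariates + Matern spatial field) over the EAs produced by the
travel-time stage; haemoglobin is altitude-adjusted, severity classified
and the exclusion cascade applied.  Writes the admissions register, the
analysed cohort and the flow ledger under results/cohort/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from anaemia_access.accessibility import bin_travel_time
from anaemia_access.cohort import adjust_hb_for_altitude, apply_exclusions
from anaemia_access.region import eas_from_geojson
from anaemia_access.synthetic import default_truth, simulate_admissions


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-admissions", type=int, default=4361)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    eas = eas_from_geojson(args.results / "traveltime" / "eas_with_travel.geojson")
    usable = [ea for ea in eas if ea.mean_travel_min is not None]
    tt_class = {ea.ea_id: str(bin_travel_time(ea.mean_travel_min)) for ea in usable}

    truth = default_truth(args.seed)
    admissions, truth = simulate_admissions(
        usable, tt_class, truth, args.n_admissions, seed=args.seed
    )
    measured = admissions["hb_raw"].notna()
    admissions["hb_adj"] = np.nan
    admissions.loc[measured, "hb_adj"] = adjust_hb_for_altitude(
        admissions.loc[measured, "hb_raw"].to_numpy(),
        admissions.loc[measured, "altitude_m"].to_numpy(),
    )
    cohort, ledger = apply_exclusions(admissions)

    outdir = args.results / "cohort"
    outdir.mkdir(parents=True, exist_ok=True)
    admissions.to_csv(outdir / "admissions.csv", index=False)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    truth.to_json(outdir / "truth.json")
    (outdir / "flow_ledger.json").write_text(json.dumps(ledger.as_dict(), indent=2))

    d = ledger.as_dict()
    print(
        f"Extracted {d['extracted']:,} admissions; excluded {d['excluded_cause']} "
        f"for cause, {d['excluded_no_hb']} without Hb, "
        f"{d['excluded_not_anaemic']} not anaemic; analysed {d['analysed']:,}."
    )
    print(
        "Severity mix: "
        + ", ".join(
            f"{k} {v}" for k, v in cohort["severity"].value_counts().items()
        )
    )
    print(f"Outputs in {outdir}/")


if __name__ == "__main__":
    main()
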