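"""End-to-end pipeline: simulate -> traveltime -> cohort -> describe -> fit.

Each stage persists its outputs so it can be re-run in isolation; a run
manifest records seeds, package version and a checksum for every file.
Failures abort with the stage name; partial outputs are moved under a
``failed/`` prefix.  Record counts are logged at every stage boundary,
mirroring the cohort flow ledger.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .accessibility import (
    SpeedTable,
    bin_travel_time,
    build_friction_surface,
    least_cost_travel_time,
    zonal_mean_travel_time,
)
from .cohort import adjust_hb_for_altitude, apply_exclusions
from .descriptive import band_admission_rates, crude_or, ea_admission_rates, summarize_table1
from .geostat import ModelSpec, adjusted_or_table, ea_mean_residuals, empirical_variogram, fit_spatial_logit, univariate_screen
from .region import eas_from_geojson, eas_to_frame, eas_to_geojson
from .synthetic import (
    CohortMarginals,
    RegionConfig,
    SyntheticTruth,
    default_truth,
    generate_landscape,
    simulate_admissions,
)

log = logging.getLogger("anaemia_access")

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

CANDIDATE_COVARIATES = [
    "age_cat", "sex", "nutrition", "vaccinated", "malaria_dx", "scd",
    "weekday", "wet_season", "pfpr", "urban",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study run."""

    outdir: Path
    seed: int = 0
    region: RegionConfig = field(default_factory=RegionConfig)
    marginals: CohortMarginals = field(default_factory=CohortMarginals)
    truth: SyntheticTruth | None = None
    n_admissions: int = 4361
    speeds: SpeedTable = field(default_factory=SpeedTable.default)
    model: ModelSpec | None = None
    make_figures: bool = True

    def validate(self) -> None:
        self.outdir = Path(self.outdir)
        if self.n_admissions < 1:
            raise ValueError("n_admissions must be positive")
        if self.region.n_eas < 2:
            raise ValueError("need at least two EAs")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the report directory.

    Deterministic stages are bit-identical across reruns with the same
    config and seed.
    """
    config.validate()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        # ---- simulate ---------------------------------------------------
        stage = "simulate"
        region = generate_landscape(config.region, seed=config.seed)
        region.write_dir(outdir)
        log.info("simulate: %d EAs, %s pixels", len(region.eas), region.layers.shape)

        # ---- traveltime -------------------------------------------------
        stage = "traveltime"
        friction = build_friction_surface(region.layers, config.speeds)
        tt = least_cost_travel_time(friction, region.layers.hospital_rowcol)
        tt.grid.write_ascii(outdir / "travel_time_min.asc")
        zonal = zonal_mean_travel_time(tt, region.eas)
        zonal.to_csv(outdir / "ea_travel_time.csv", index=False)
        eas_to_geojson(region.eas, outdir / "eas.geojson")
        log.info("traveltime: %d/%d EAs reachable", zonal["mean_travel_min"].notna().sum(), len(zonal))

        # ---- cohort -----------------------------------------------------
        stage = "cohort"
        usable = [ea for ea in region.eas if ea.mean_travel_min is not None]
        tt_class = {
            ea.ea_id: str(bin_travel_time(ea.mean_travel_min)) for ea in usable
        }
        truth = config.truth or default_truth(config.seed)
        admissions, truth = simulate_admissions(
            usable, tt_class, truth, config.n_admissions, seed=config.seed,
            marginals=config.marginals,
        )
        admissions.to_csv(outdir / "admissions.csv", index=False)
        truth.to_json(outdir / "truth.json")
        measured = admissions["hb_raw"].notna()
        admissions["hb_adj"] = np.nan
        admissions.loc[measured, "hb_adj"] = adjust_hb_for_altitude(
            admissions.loc[measured, "hb_raw"].to_numpy(),
            admissions.loc[measured, "altitude_m"].to_numpy(),
        )
        cohort, ledger = apply_exclusions(admissions)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        (outdir / "flow_ledger.json").write_text(json.dumps(ledger.as_dict(), indent=2))
        log.info("cohort: %s", ledger.as_dict())

        # ---- describe ---------------------------------------------------
        stage = "describe"
        ea_frame = eas_to_frame(usable)
        ea_frame["band15"] = bin_travel_time(
            ea_frame["mean_travel_min"].to_numpy(dtype=float), scheme="15min"
        )
        cohort = cohort.merge(
            ea_frame[["ea_id", "band15"]], on="ea_id", how="left"
        )
        table1 = summarize_table1(cohort, fisher_seed=config.seed)
        table1.to_csv(outdir / "table1.csv", index=False)
        ea_rates = ea_admission_rates(cohort, ea_frame)
        ea_rates.to_csv(outdir / "ea_admission_rates.csv", index=False)
        band_rates = band_admission_rates(cohort, ea_frame)
        band_rates.to_csv(outdir / "band_admission_rates.csv", index=False)
        crude = {}
        ref = cohort[cohort["tt_class"] == "<30"]
        for cls in ["30-59", "60-89", ">=90"]:
            sub = cohort[cohort["tt_class"] == cls]
            if len(sub) and sub["severe"].sum() and ref["severe"].sum():
                crude[cls] = crude_or(
                    [
                        [int(sub["severe"].sum()), int((1 - sub["severe"]).sum())],
                        [int(ref["severe"].sum()), int((1 - ref["severe"]).sum())],
                    ]
                )
        if config.make_figures:
            _band_rate_figure(band_rates, outdir / "band_rates.png")

        # ---- fit --------------------------------------------------------
        stage = "fit"
        screen = univariate_screen(cohort, ["tt_class"] + CANDIDATE_COVARIATES)
        centroids = pd.DataFrame(
            {
                "ea_id": [ea.ea_id for ea in usable],
                "x": [ea.centroid[0] for ea in usable],
                "y": [ea.centroid[1] for ea in usable],
            }
        )
        centroids = centroids[centroids["ea_id"].isin(cohort["ea_id"])]
        resid = ea_mean_residuals(cohort, screen.selected)
        coords = centroids.set_index("ea_id").loc[resid.index, ["x", "y"]].to_numpy()
        variogram = empirical_variogram(resid.to_numpy(), coords)
        variogram.to_csv(outdir / "variogram.csv", index=False)
        spec = config.model or ModelSpec(covariates=screen.selected)
        fit = fit_spatial_logit(cohort, spec, centroids)
        fit.coef_table().to_csv(outdir / "fit_coefficients.csv")
        fit_meta = {
            "selected_covariates": screen.selected,
            "screen_p_values": screen.p_values,
            "sigma2": fit.sigma2,
            "kappa": fit.kappa,
            "nu": fit.nu,
            "log_marginal": fit.log_marginal,
            "n_newton": fit.n_newton,
            "separation_flag": fit.separation_flag,
        }
        (outdir / "fit.json").write_text(json.dumps(fit_meta, indent=2, default=float))
        table2 = adjusted_or_table(fit, cohort, crude)
        table2.to_csv(outdir / "table2.csv", index=False)
        log.info("fit: sigma2=%.3g kappa=%.3g", fit.sigma2, fit.kappa)

        # ---- report -----------------------------------------------------
        stage = "report"
        files = sorted(
            p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_admissions": config.n_admissions,
            "files": {
                str(p.relative_to(outdir)): _checksum(p) for p in files
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return outdir
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for p in outdir.iterdir():
            if p.is_file():
                shutil.move(str(p), failed / p.name)
        raise PipelineError(stage, exc) from exc


def _band_rate_figure(band_rates: pd.DataFrame, path: Path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    order = ["<15", "15-29", "30-44", "45-59", "60-74", "75-89", ">=90"]
    br = band_rates.set_index("band15").reindex(order)
    for ax, sev in zip(axes, ["mild", "moderate", "severe"]):
        ax.bar(range(len(br)), br[f"rate_{sev}"].to_numpy())
        ax.set_xticks(range(len(br)), order, rotation=45)
        ax.set_title(f"{sev} anaemia")
        ax.set_xlabel("travel time band (min)")
    axes[0].set_ylabel("admissions / 1,000 under-5 / window")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
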