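"""Shared fixtures: small landscapes and a study-scale synthetic cohort.

Everything is generated programmatically at fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from anaemia_access.accessibility import bin_travel_time
from anaemia_access.cohort import adjust_hb_for_altitude, classify_anaemia
from anaemia_access.raster import RasterGrid
from anaemia_access.region import LandscapeLayers
from anaemia_access.synthetic import (
    CohortMarginals,
    RegionConfig,
    default_truth,
    generate_landscape,
    make_random_eas,
    simulate_admissions,
)

# the set of covariates the severity truth acts on (the "significant eight")
TRUE_COVARIATES = [
    "age_cat", "nutrition", "vaccinated", "malaria_dx", "scd",
    "weekday", "pfpr", "urban",
]


def make_uniform_friction_layers(
    n: int = 5, pixel_size: float = 12.5, cover_code: int = 3
) -> LandscapeLayers:
    """An n x n all-grassland landscape with the hospital at the centre."""
    z = np.zeros((n, n), dtype=int)
    cover = np.full((n, n), cover_code, dtype=int)
    alt = np.full((n, n), 1200.0)
    mk = lambda d: RasterGrid(d, pixel_size)
    layers = LandscapeLayers(
        road_class=mk(z),
        land_cover=mk(cover),
        barrier_mask=mk(np.zeros((n, n), dtype=bool)),
        altitude=mk(alt),
        hospital_xy=mk(z).rowcol_to_xy(np.array(n // 2), np.array(n // 2)),
    )
    return layers


def attach_severity(adm: pd.DataFrame) -> pd.DataFrame:
    """Adjusted Hb -> severity columns, without the exclusion cascade."""
    adm = adm.copy()
    hb_adj = adjust_hb_for_altitude(
        adm["hb_raw"].to_numpy(), adm["altitude_m"].to_numpy()
    )
    adm["hb_adj"] = hb_adj
    adm["severity"] = classify_anaemia(hb_adj)
    adm["severe"] = (adm["severity"] == "severe").astype(int)
    return adm


def simulate_clean_cohort(
    n: int,
    n_ea: int,
    seed: int,
    truth=None,
    marginals: CohortMarginals | None = None,
    geometry: str = "correlated",
):
    """Admissions with no exclusion pathway, severity attached; returns
    (cohort, centroids, truth)."""
    truth = truth or default_truth(seed)
    m = marginals or CohortMarginals(
        p_exclusion_cause=0.0, p_missing_hb=0.0, p_not_anaemic=0.0, decay_per_min=0.0
    )
    eas = make_random_eas(n_ea, seed=seed + 10_000, geometry=geometry)
    cls = {ea.ea_id: str(bin_travel_time(ea.mean_travel_min)) for ea in eas}
    adm, truth = simulate_admissions(eas, cls, truth, n, seed=seed, marginals=m)
    cohort = attach_severity(adm)
    centroids = pd.DataFrame(
        {
            "ea_id": [ea.ea_id for ea in eas],
            "x": [ea.centroid[0] for ea in eas],
            "y": [ea.centroid[1] for ea in eas],
        }
    )
    return cohort, centroids, truth


@pytest.fixture(scope="session")
def small_region():
    """A 60x60 region with 12 EAs — fast but fully featured."""
    cfg = RegionConfig(
        nrow=60, ncol=60, pixel_size=250.0, n_eas=12, n_tarmac=2, n_secondary=4
    )
    return generate_landscape(cfg, seed=3)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale clean cohort (n=2187, 300 EAs) under the default truth."""
    return simulate_clean_cohort(2187, 300, seed=7)
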