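"""Synthetic study region and admission cohort with known ground truth.

The generator emulates the three inputs the analysis consumes — a landscape
raster stack, enumeration areas (EAs) with population/NTL/PfPR attributes,
and an admissions table — with the statistical structure the downstream
model assumes.  Severity is generated from the analysis's own logit model
(travel-time class effects + covariate effects + a Matern Gaussian field
over EA centroids), so every stage of the pipeline can be exercised against
a known truth.

Scales follow the study setting: a rural county with a single referral
hospital, EA under-five populations of order 10^2, community PfPR around
0.33, ~29% of analysed anaemia admissions severe, and an extraction window
of 42 surveillance months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.linalg import cholesky
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import expit

from .cohort import WHO_ALTITUDE_STEPS
from .geostat import MaternParams, matern_covariance_matrix
from .raster import RasterGrid
from .region import EnumerationArea, LandscapeLayers

__all__ = [
    "RegionConfig",
    "SyntheticRegion",
    "CohortMarginals",
    "SyntheticTruth",
    "default_truth",
    "generate_landscape",
    "simulate_matern_field",
    "simulate_admissions",
    "make_random_eas",
]

SURVEY_START, SURVEY_END = "2020-01-01", "2023-07-31"  # 42 surveillance months


# --------------------------------------------------------------------------
# landscape
# --------------------------------------------------------------------------


@dataclass
class RegionConfig:
    """Synthetic-region parameters.

    The default is a 30 x 30 km region at 100 m pixels with a sparse road
    network (two trunk roads, eight secondary): large enough, and slow
    enough off-road, for travel times to span all four 30-min classes with
    roughly the admission shares seen in rural referral settings, while
    keeping the pixel graph small.  (The accessibility module itself is
    resolution-agnostic; the 12.5 m convention of real road/land-cover data
    remains available through ``pixel_size``.)
    """

    nrow: int = 300
    ncol: int = 300
    pixel_size: float = 100.0
    n_eas: int = 60
    n_tarmac: int = 2
    n_secondary: int = 8
    barrier_frac: float = 0.04
    altitude_range: tuple[float, float] = (1130.0, 1350.0)
    pop_u5_log_mean: float = np.log(150.0)
    pop_u5_log_sd: float = 0.8
    urban_radius_m: float = 2500.0
    pfpr_range: tuple[float, float] = (0.20, 0.55)


@dataclass
class SyntheticRegion:
    layers: LandscapeLayers
    eas: list[EnumerationArea]
    ea_label: RasterGrid  # integer EA index per pixel

    def write_dir(self, outdir: str | Path) -> None:
        from .region import eas_to_geojson

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.layers.write_dir(outdir)
        self.ea_label.write_ascii(outdir / "ea_label.asc")
        eas_to_geojson(self.eas, outdir / "eas.geojson")


def _bresenham(r0: int, c0: int, r1: int, c1: int):
    """Integer pixels on the line segment (r0,c0)-(r1,c1), inclusive."""
    dr, dc = abs(r1 - r0), -abs(c1 - c0)
    sr, sc = (1 if r1 >= r0 else -1), (1 if c1 >= c0 else -1)
    err = dr + dc
    r, c = r0, c0
    while True:
        yield r, c
        if (r, c) == (r1, c1):
            return
        e2 = 2 * err
        if e2 >= dc:
            err += dc
            r += sr
        if e2 <= dr:
            err += dr
            c += sc


def generate_landscape(config: RegionConfig, seed: int) -> SyntheticRegion:
    """Generate aligned landscape layers and a Voronoi EA tiling.

    Roads form a connected network anchored at the hospital: trunk (tarmac)
    roads run from the hospital to the region edge, secondary gravel/earth
    roads branch off the existing network.  Land cover and altitude are
    thresholded/scaled smoothed noise; water barriers avoid road pixels and
    the hospital.  Every pixel belongs to exactly one EA (nearest seed
    point).  Deterministic for a fixed (config, seed).
    """
    if config.nrow < 50 or config.ncol < 50:
        raise ValueError("region must be at least 50 x 50 pixels")
    if config.n_eas < 2:
        raise ValueError("need at least 2 enumeration areas")
    if config.barrier_frac >= 1.0:
        raise ValueError("an all-barrier region is degenerate")
    rng = np.random.default_rng(seed)
    nrow, ncol, px = config.nrow, config.ncol, config.pixel_size

    hosp_rc = (nrow // 2, ncol // 2)

    # --- road network ----------------------------------------------------
    road = np.zeros((nrow, ncol), dtype=int)
    angles = rng.uniform(0, 2 * np.pi) + np.arange(config.n_tarmac) * (
        2 * np.pi / max(config.n_tarmac, 1)
    )
    for ang in angles:
        rr = hosp_rc[0] + int(np.round(np.sin(ang) * 2 * nrow))
        cc = hosp_rc[1] + int(np.round(np.cos(ang) * 2 * ncol))
        rr, cc = np.clip(rr, 0, nrow - 1), np.clip(cc, 0, ncol - 1)
        for r, c in _bresenham(hosp_rc[0], hosp_rc[1], rr, cc):
            road[r, c] = 1
    for _ in range(config.n_secondary):
        r1, c1 = rng.integers(0, nrow), rng.integers(0, ncol)
        on_road = np.argwhere(road > 0)
        tree = cKDTree(on_road)
        _, i = tree.query([r1, c1])
        r0, c0 = on_road[i]
        cls = int(rng.choice([2, 3]))  # gravel or earth
        for r, c in _bresenham(r0, c0, r1, c1):
            if road[r, c] == 0:
                road[r, c] = cls

    # --- land cover ------------------------------------------------------
    noise = gaussian_filter(rng.standard_normal((nrow, ncol)), sigma=6)
    q = np.quantile(noise, [0.45, 0.70, 0.91])
    cover = np.select(
        [noise < q[0], noise < q[1], noise < q[2]], [2, 3, 4], 5
    )  # cultivated / grassland / bushland / forest
    rr, cc = np.ogrid[:nrow, :ncol]
    near_hosp = (rr - hosp_rc[0]) ** 2 + (cc - hosp_rc[1]) ** 2 <= (
        config.urban_radius_m / (2 * px)
    ) ** 2
    cover[near_hosp] = 1  # builtup core around the hospital

    # --- barriers (water) ------------------------------------------------
    if config.barrier_frac > 0:
        wnoise = gaussian_filter(rng.standard_normal((nrow, ncol)), sigma=8)
        barrier = wnoise > np.quantile(wnoise, 1 - config.barrier_frac)
    else:
        barrier = np.zeros((nrow, ncol), dtype=bool)
    barrier[road > 0] = False  # bridges
    barrier[hosp_rc] = False
    if barrier.all():
        raise ValueError("degenerate config: all pixels are barriers")

    # --- altitude --------------------------------------------------------
    anoise = gaussian_filter(rng.standard_normal((nrow, ncol)), sigma=15)
    lo, hi = config.altitude_range
    altitude = lo + (hi - lo) * (anoise - anoise.min()) / np.ptp(anoise)

    origin = (0.0, 0.0)
    grids = {
        "road": RasterGrid(road, px, origin),
        "cover": RasterGrid(cover, px, origin),
        "barrier": RasterGrid(barrier, px, origin),
        "alt": RasterGrid(altitude, px, origin),
    }
    hx, hy = grids["road"].rowcol_to_xy(np.array(hosp_rc[0]), np.array(hosp_rc[1]))
    layers = LandscapeLayers(
        road_class=grids["road"],
        land_cover=grids["cover"],
        barrier_mask=grids["barrier"],
        altitude=grids["alt"],
        hospital_xy=(float(hx), float(hy)),
    )

    # --- EA tiling: every pixel to its nearest seed ----------------------
    seeds_rc = rng.choice(nrow * ncol, size=config.n_eas, replace=False)
    seeds = np.column_stack(np.unravel_index(seeds_rc, (nrow, ncol)))
    tree = cKDTree(seeds)
    allpix = np.column_stack(
        [np.repeat(np.arange(nrow), ncol), np.tile(np.arange(ncol), nrow)]
    )
    _, label_flat = tree.query(allpix)
    label = label_flat.reshape(nrow, ncol)
    label_grid = RasterGrid(label, px, origin)

    # pfpr varies smoothly in space
    pnoise = gaussian_filter(rng.standard_normal((nrow, ncol)), sigma=20)
    plo, phi = config.pfpr_range
    pfpr_surface = plo + (phi - plo) * (pnoise - pnoise.min()) / np.ptp(pnoise)

    xs, ys = grids["road"].cell_centers()
    eas: list[EnumerationArea] = []
    for k in range(config.n_eas):
        mask = label == k
        boxes = shapely.box(
            xs[mask] - px / 2, ys[mask] - px / 2, xs[mask] + px / 2, ys[mask] + px / 2
        )
        poly = shapely.union_all(boxes)
        cx, cy = float(xs[mask].mean()), float(ys[mask].mean())
        if not poly.contains(shapely.Point(cx, cy)):
            rp = poly.representative_point()
            cx, cy = float(rp.x), float(rp.y)
        dist_h = float(np.hypot(cx - hx, cy - hy))
        pop = int(np.round(rng.lognormal(config.pop_u5_log_mean, config.pop_u5_log_sd)))
        ntl = float(rng.gamma(2.0, 3.0)) if dist_h <= config.urban_radius_m else 0.0
        eas.append(
            EnumerationArea(
                ea_id=f"EA{k:04d}",
                polygon=poly,
                centroid=(cx, cy),
                pop_u5=max(pop, 1),
                ntl=ntl,
                pfpr=float(pfpr_surface[mask].mean()),
                mean_altitude_m=float(altitude[mask].mean()),
            )
        )
    return SyntheticRegion(layers=layers, eas=eas, ea_label=label_grid)


# --------------------------------------------------------------------------
# Matern field
# --------------------------------------------------------------------------


def simulate_matern_field(
    centroids: np.ndarray, matern: MaternParams, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one zero-mean Gaussian field value per EA centroid.

    Exact multivariate-normal draw via Cholesky of the Matern covariance
    (diagonal jitter at most 1e-8 * sigma2); sigma2 = 0 returns exact zeros.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = len(centroids)
    if n < 1:
        raise ValueError("need at least one centroid")
    if matern.sigma2 == 0:
        return np.zeros(n)
    cov = matern_covariance_matrix(centroids, matern, jitter_frac=1e-8)
    L = cholesky(cov, lower=True)
    return L @ rng.standard_normal(n)


# --------------------------------------------------------------------------
# admissions
# --------------------------------------------------------------------------


@dataclass
class CohortMarginals:
    """Marginal distributions for simulated admission covariates.

    Defaults match the severity-stratified characteristics of the published
    cohort (overall column): age-category shares, 41.2% female, nutrition
    mix with 8.4% missing MUAC, 94% vaccinated, 40% malaria at discharge,
    16% SCD, 78.5% weekday, 51.6% wet season.  Exclusion-path fractions
    reproduce the published cascade proportions (665/4361 cause, 264/3696
    missing Hb, 1245/3432 not anaemic).  Covariates are drawn independently
    of one another by default.
    """

    p_age: dict[str, float] = field(
        default_factory=lambda: {
            "<1": 0.285, "1": 0.299, "2": 0.166, "3": 0.128, "4": 0.122,
        }
    )
    p_female: float = 0.412
    p_nutrition: dict[str, float] = field(
        default_factory=lambda: {
            "well": 0.381,
            "mild_malnutrition": 0.321,
            "moderate_malnutrition": 0.131,
            "severe_malnutrition": 0.082,
            "missing": 0.085,
        }
    )
    p_vaccinated: float = 0.94
    p_malaria: float = 0.40
    p_scd: float = 0.16
    p_weekday: float = 0.785
    p_wet: float = 0.516
    p_mild_given_not_severe: float = 1151.0 / 1553.0
    p_exclusion_cause: float = 665.0 / 4361.0
    p_missing_hb: float = 264.0 / 3696.0
    p_not_anaemic: float = 1245.0 / 3432.0
    p_nonresident: float = 0.0
    # admission propensity per EA: pop_u5 * exp(-decay_per_min * travel time);
    # 0.04/min makes band rates fall ~5-6x between the 15- and 60-min bands.
    decay_per_min: float = 0.04


@dataclass
class SyntheticTruth:
    """Generative parameters of the severity model (the recovery target)."""

    beta0: float
    beta_tt: dict[str, float]
    beta_cov: dict[str, object]  # name -> log-OR, or name -> {level: log-OR}
    matern: MaternParams
    iid_sd: float = 0.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["matern"] = {
            "sigma2": self.matern.sigma2,
            "kappa": self.matern.kappa,
            "nu": self.matern.nu,
        }
        Path(path).write_text(json.dumps(d, indent=2))


def default_truth(seed: int = 0) -> SyntheticTruth:
    """Study-condition truth: travel-class log-ORs mirroring the published
    adjusted estimates, moderate covariate effects, a Matern field with
    sigma2 = 0.5 and practical range ~2.8 km, no admission-level noise."""
    return SyntheticTruth(
        beta0=-4.8,
        beta_tt={
            "30-59": float(np.log(2.44)),
            "60-89": float(np.log(3.55)),
            ">=90": float(np.log(3.41)),
        },
        beta_cov={
            "malaria_dx": float(np.log(2.0)),
            "scd": float(np.log(1.8)),
            "vaccinated": float(np.log(2.0)),
            "weekday": float(np.log(1.6)),
            "rural": float(np.log(2.0)),
            "pfpr": 2.5,
            "age_cat": {"1": 0.0, "2": 0.5, "3": 0.6, "4": 0.7},
            "nutrition": {
                "mild_malnutrition": 0.3,
                "moderate_malnutrition": 0.5,
                "severe_malnutrition": 0.5,
                "missing": 0.0,
            },
        },
        matern=MaternParams(sigma2=0.5, kappa=1.0 / 1000.0, nu=1.0),
        iid_sd=0.0,
        seed=seed,
    )


_AGE_MONTH_RANGES = {
    "<1": (1, 11), "1": (12, 23), "2": (24, 35), "3": (36, 47), "4": (48, 59),
}
_MUAC_BANDS = {
    "well": (-1.0, 1.5),
    "mild_malnutrition": (-2.0, -1.0),
    "moderate_malnutrition": (-3.0, -2.0),
    "severe_malnutrition": (-3.8, -3.0),
}
_CLASS_MIDPOINT_MIN = {"<30": 15.0, "30-59": 45.0, "60-89": 75.0, ">=90": 105.0}


def _altitude_increment(alt_m: float) -> float:
    bounds = np.array([b for b, _ in WHO_ALTITUDE_STEPS])
    decs = np.array([d for _, d in WHO_ALTITUDE_STEPS])
    return float(decs[np.searchsorted(bounds, alt_m, side="right")])


def _date_pools() -> dict[tuple[bool, bool], np.ndarray]:
    days = pd.date_range(SURVEY_START, SURVEY_END, freq="D")
    wet = days.month.isin([4, 5, 6, 10, 11, 12])
    wd = days.weekday < 5
    return {
        (bool(a), bool(b)): days[(wd == a) & (wet == b)].to_numpy()
        for a in (True, False)
        for b in (True, False)
    }


def simulate_admissions(
    eas: list[EnumerationArea],
    tt_class: dict[str, str],
    truth: SyntheticTruth,
    n_admissions: int,
    seed: int,
    marginals: CohortMarginals | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the pre-exclusion admissions table.

    Every admission's EA must have a travel-time class.  Severity among
    anaemic admissions follows Bernoulli(logit^-1(beta0 + beta_tt[class] +
    sum_j beta_j x_j + omega_k + eps_i)) with omega a Matern field over EA
    centroids; mild vs moderate among the non-severe is a single Bernoulli
    split.  Raw Hb is back-derived from the adjusted value and the EA
    altitude so the cohort stage recovers the generated class exactly.
    Returns (admissions table, truth) — truth carries the seed used.
    """
    if n_admissions < 1:
        raise ValueError("n_admissions must be at least 1")
    m = marginals or CohortMarginals()
    for ea in eas:
        if ea.ea_id not in tt_class:
            raise ValueError(f"EA {ea.ea_id} has no travel-time class")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        beta0=truth.beta0,
        beta_tt=dict(truth.beta_tt),
        beta_cov=dict(truth.beta_cov),
        matern=truth.matern,
        iid_sd=truth.iid_sd,
        seed=seed,
    )

    ea_ids = np.array([ea.ea_id for ea in eas])
    pop = np.array([ea.pop_u5 for ea in eas], dtype=float)
    tmin = np.array(
        [
            ea.mean_travel_min
            if ea.mean_travel_min is not None
            else _CLASS_MIDPOINT_MIN[tt_class[ea.ea_id]]
            for ea in eas
        ]
    )
    weight = pop * np.exp(-m.decay_per_min * tmin)
    weight /= weight.sum()
    k_of = rng.choice(len(eas), size=n_admissions, p=weight)

    centroids = np.array([ea.centroid for ea in eas])
    omega = simulate_matern_field(centroids, truth.matern, rng)

    # covariates from configured marginals
    age_cats = np.array(list(m.p_age))
    age_cat = rng.choice(age_cats, size=n_admissions, p=list(m.p_age.values()))
    age_months = np.array(
        [rng.integers(*_AGE_MONTH_RANGES[a]) + rng.integers(0, 2) for a in age_cat]
    )
    age_months = np.clip(age_months, 1, 59)
    sex = np.where(rng.random(n_admissions) < m.p_female, "female", "male")
    nut_cats = np.array(list(m.p_nutrition))
    nutrition = rng.choice(nut_cats, size=n_admissions, p=list(m.p_nutrition.values()))
    muac_z = np.array(
        [
            np.nan if n == "missing" else rng.uniform(*_MUAC_BANDS[n])
            for n in nutrition
        ]
    )
    vaccinated = rng.random(n_admissions) < m.p_vaccinated
    malaria = rng.random(n_admissions) < m.p_malaria
    scd = rng.random(n_admissions) < m.p_scd
    weekday = rng.random(n_admissions) < m.p_weekday
    wet = rng.random(n_admissions) < m.p_wet
    pools = _date_pools()
    dates = np.array(
        [rng.choice(pools[(bool(w), bool(s))]) for w, s in zip(weekday, wet)]
    )
    urban = np.array([eas[k].urban for k in k_of])
    pfpr = np.array([eas[k].pfpr for k in k_of])
    alt = np.array([eas[k].mean_altitude_m for k in k_of])
    cls = np.array([tt_class[ea_ids[k]] for k in k_of])

    # linear predictor of the severity model
    eta = np.full(n_admissions, truth.beta0)
    for c, b in truth.beta_tt.items():
        eta += b * (cls == c)
    covs: dict[str, np.ndarray] = {
        "malaria_dx": malaria,
        "scd": scd,
        "vaccinated": vaccinated,
        "weekday": weekday,
        "wet_season": wet,
        "rural": ~urban,
        "urban": urban,
        "pfpr": pfpr,
        "sex_female": sex == "female",
        "age_cat": age_cat,
        "nutrition": nutrition,
    }
    for name, b in truth.beta_cov.items():
        x = covs[name]
        if isinstance(b, dict):
            for level, bl in b.items():
                eta += bl * (x == level)
        else:
            eta += b * np.asarray(x, dtype=float)
    eta += omega[k_of]
    if truth.iid_sd > 0:
        eta += rng.normal(0, truth.iid_sd, n_admissions)
    severe = rng.random(n_admissions) < expit(eta)

    # exclusion-path outcomes
    cause = np.full(n_admissions, "none", dtype=object)
    is_cause = rng.random(n_admissions) < m.p_exclusion_cause
    cause[is_cause] = rng.choice(
        ["bite", "burn", "malignancy", "poisoning", "surgery", "trauma"],
        size=int(is_cause.sum()),
    )
    missing_hb = (~is_cause) & (rng.random(n_admissions) < m.p_missing_hb)
    not_anaemic = (
        (~is_cause) & (~missing_hb) & (rng.random(n_admissions) < m.p_not_anaemic)
    )

    # adjusted Hb consistent with the generated class; raw Hb adds back the
    # altitude increment so the cohort stage recovers the class exactly
    hb_adj = np.where(
        not_anaemic,
        rng.uniform(10.0, 13.0, n_admissions),
        np.where(
            severe,
            rng.uniform(2.5, 5.0, n_admissions),
            np.where(
                rng.random(n_admissions) < m.p_mild_given_not_severe,
                rng.uniform(7.0, 10.0, n_admissions),
                rng.uniform(5.0, 7.0, n_admissions),
            ),
        ),
    )
    hb_adj = np.minimum(hb_adj, np.nextafter(np.where(not_anaemic, 13.0, 10.0), 0))
    inc = np.array([_altitude_increment(a) for a in alt])
    hb_raw = np.where(missing_hb, np.nan, hb_adj + inc)

    resident = rng.random(n_admissions) >= m.p_nonresident

    df = pd.DataFrame(
        {
            "admission_id": [f"A{i:06d}" for i in range(n_admissions)],
            "ea_id": ea_ids[k_of],
            "date": pd.to_datetime(dates),
            "age_months": age_months,
            "age_cat": age_cat,
            "sex": sex,
            "hb_raw": hb_raw,
            "muac_z": muac_z,
            "nutrition": nutrition,
            "vaccinated": vaccinated,
            "malaria_dx": malaria,
            "scd": scd,
            "weekday": weekday,
            "wet_season": wet,
            "exclusion_cause": cause,
            "resident": resident,
            "urban": urban,
            "rural": ~urban,
            "pfpr": pfpr,
            "altitude_m": alt,
            "tt_class": cls,
            "mean_travel_min": tmin[k_of],
        }
    )
    return df, truth


def make_random_eas(
    n_ea: int,
    seed: int,
    domain_km: float = 30.0,
    class_probs: dict[str, float] | None = None,
    geometry: str = "correlated",
) -> list[EnumerationArea]:
    """EAs with random centroids and travel times drawn by class, without a
    landscape — the light-weight path for model-recovery experiments.

    class_probs gives the EA-level travel-class distribution (default
    mirrors the analysed cohort's N-column shares 58/32/7/2%); minutes are
    drawn uniformly within the class interval.  geometry="correlated"
    places distal-class EAs farther from the domain centre (distance-decay
    realism, which partially confounds travel time with the spatial field);
    "uniform" places centroids independently of travel time, the clean
    condition for parameter-recovery experiments.
    """
    if geometry not in {"correlated", "uniform"}:
        raise ValueError("geometry must be 'correlated' or 'uniform'")
    probs = class_probs or {"<30": 0.581, "30-59": 0.322, "60-89": 0.073, ">=90": 0.023}
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    rng = np.random.default_rng(seed)
    side = domain_km * 1000.0
    spans = {"<30": (2.0, 30.0), "30-59": (30.0, 60.0), "60-89": (60.0, 90.0), ">=90": (90.0, 120.0)}
    # proportional class allocation (largest remainder, >= 1 EA per class
    # when feasible) so every exposure class is represented, then shuffled
    keys = list(probs)
    raw = np.array([probs[k] * n_ea for k in keys])
    counts = np.floor(raw).astype(int)
    if n_ea >= len(keys):
        counts = np.maximum(counts, 1)
    short = n_ea - counts.sum()
    order = np.argsort(raw - np.floor(raw))[::-1]
    i = 0
    while short != 0:
        j = order[i % len(keys)]
        step = 1 if short > 0 else -1
        if counts[j] + step >= (1 if n_ea >= len(keys) else 0):
            counts[j] += step
            short -= step
        i += 1
    class_list = rng.permutation(np.repeat(keys, counts))
    eas = []
    for k in range(n_ea):
        cls = str(class_list[k])
        minutes = float(rng.uniform(*spans[cls]))
        if geometry == "correlated":
            # proximal EAs tend to sit nearer the domain centre, but only
            # loosely: with road-based access, EAs at one radius span classes
            ang = rng.uniform(0, 2 * np.pi)
            rad = side / 2 * float(
                np.clip((minutes / 120.0) * rng.lognormal(0.0, 0.45), 0.03, 1.0)
            )
            cx = side / 2 + rad * np.cos(ang)
            cy = side / 2 + rad * np.sin(ang)
        else:
            cx, cy = rng.uniform(0, side), rng.uniform(0, side)
        poly = shapely.Point(cx, cy).buffer(300.0, quad_segs=4)
        eas.append(
            EnumerationArea(
                ea_id=f"EA{k:04d}",
                polygon=poly,
                centroid=(cx, cy),
                pop_u5=int(rng.lognormal(np.log(150.0), 0.8)) + 1,
                ntl=float(rng.gamma(2.0, 3.0)) if minutes < 20 else 0.0,
                pfpr=float(np.clip(rng.normal(0.33 + 0.001 * minutes, 0.08), 0.05, 0.65)),
                mean_altitude_m=float(rng.uniform(1150, 1300)),
                mean_travel_min=minutes,
            )
        )
    return eas
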