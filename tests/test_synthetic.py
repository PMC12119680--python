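"""Generator contracts: determinism, tiling, marginal calibration and the
statistical structure of the simulated fields and cohorts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import shapely

from anaemia_access.accessibility import bin_travel_time
from anaemia_access.geostat import MaternParams
from anaemia_access.synthetic import (
    CohortMarginals,
    RegionConfig,
    default_truth,
    generate_landscape,
    make_random_eas,
    simulate_admissions,
    simulate_matern_field,
)
from scipy.special import expit, logit

from conftest import attach_severity


SMALL = RegionConfig(nrow=60, ncol=60, pixel_size=250.0, n_eas=10, n_tarmac=2, n_secondary=3)


class TestLandscape:
    def test_seed_determinism(self):
        a = generate_landscape(SMALL, seed=1)
        b = generate_landscape(SMALL, seed=1)
        for name in ["road_class", "land_cover", "barrier_mask", "altitude"]:
            np.testing.assert_array_equal(
                getattr(a.layers, name).data, getattr(b.layers, name).data
            )
        np.testing.assert_array_equal(a.ea_label.data, b.ea_label.data)
        assert [ea.pop_u5 for ea in a.eas] == [ea.pop_u5 for ea in b.eas]

    def test_zero_barrier_fraction(self):
        cfg = dataclasses.replace(SMALL, barrier_frac=0.0)
        region = generate_landscape(cfg, seed=2)
        assert not region.layers.barrier_mask.data.any()

    def test_every_pixel_in_exactly_one_ea(self):
        cfg = RegionConfig(
            nrow=100, ncol=100, pixel_size=100.0, n_eas=25, n_tarmac=2, n_secondary=3
        )
        region = generate_landscape(cfg, seed=4)
        label = region.ea_label.data
        assert label.shape == (100, 100)
        assert label.min() >= 0 and label.max() < 25
        assert len(np.unique(label)) == 25
        # polygons tile the region: areas sum to the region area and pixel
        # centres fall in the polygon of their own label
        total = sum(ea.polygon.area for ea in region.eas)
        assert total == pytest.approx(100 * 100 * 100.0**2, rel=1e-9)
        xs, ys = region.ea_label.cell_centers()
        rng = np.random.default_rng(0)
        for idx in rng.integers(0, 100 * 100, size=60):
            r, c = divmod(int(idx), 100)
            k = int(label[r, c])
            assert region.eas[k].polygon.contains(shapely.Point(xs[r, c], ys[r, c]))

    def test_roads_touch_hospital_and_connect(self):
        region = generate_landscape(SMALL, seed=5)
        road = region.layers.road_class.data
        r0, c0 = region.layers.hospital_rowcol
        assert road[r0, c0] > 0
        # flood fill from hospital over road pixels reaches every road pixel
        from scipy.ndimage import label as cc_label

        lab, n = cc_label(road > 0, structure=np.ones((3, 3)))
        assert n == 1

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(dataclasses.replace(SMALL, n_eas=1), seed=0)
        with pytest.raises(ValueError):
            generate_landscape(dataclasses.replace(SMALL, nrow=20), seed=0)
        with pytest.raises(ValueError):
            generate_landscape(dataclasses.replace(SMALL, barrier_frac=1.0), seed=0)

    def test_hospital_pixel_never_barrier(self):
        region = generate_landscape(dataclasses.replace(SMALL, barrier_frac=0.3), seed=6)
        r0, c0 = region.layers.hospital_rowcol
        assert not region.layers.barrier_mask.data[r0, c0]


class TestMaternField:
    def test_single_ea_standard_normal(self):
        p = MaternParams(1.0, 1e-3, 1.0)
        rng = np.random.default_rng(0)
        vals = np.array(
            [simulate_matern_field([[0.0, 0.0]], p, rng)[0] for _ in range(10_000)]
        )
        assert vals.mean() == pytest.approx(0.0, abs=0.05)
        assert vals.var() == pytest.approx(1.0, abs=0.05)

    def test_zero_variance_gives_exact_zeros(self):
        p = MaternParams(0.0, 1e-3, 1.0)
        out = simulate_matern_field(np.random.default_rng(1).uniform(0, 1e4, (20, 2)), p, 3)
        assert np.all(out == 0.0)

    def test_pairwise_correlation_matches_exponential_limit(self):
        # nu = 1/2: corr(h) = exp(-kappa h)
        kappa, h = 1.0 / 2000.0, 1500.0
        p = MaternParams(1.0, kappa, 0.5)
        coords = np.array([[0.0, 0.0], [h, 0.0]])
        rng = np.random.default_rng(2)
        draws = np.array([simulate_matern_field(coords, p, rng) for _ in range(20_000)])
        corr = np.corrcoef(draws.T)[0, 1]
        assert corr == pytest.approx(np.exp(-kappa * h), abs=0.02)

    def test_variogram_of_field_rises_to_sill(self):
        """Averaged empirical variogram approaches the marginal variance at
        lags beyond the practical range."""
        from anaemia_access.geostat import empirical_variogram

        sigma2 = 0.8
        p = MaternParams(sigma2, 1.0 / 800.0, 1.0)
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 20_000, size=(150, 2))
        acc = None
        for _ in range(60):
            f = simulate_matern_field(coords, p, rng)
            vg = empirical_variogram(f, coords, n_bins=10)
            acc = vg["semivariance"] if acc is None else acc + vg["semivariance"]
        gamma = (acc / 60).to_numpy()
        # top three lag bins are far beyond the ~2.3 km practical range
        assert np.nanmean(gamma[-3:]) == pytest.approx(sigma2, rel=0.15)


class TestAdmissions:
    def _eas(self, seed=0, n=50):
        eas = make_random_eas(n, seed=seed)
        cls = {ea.ea_id: str(bin_travel_time(ea.mean_travel_min)) for ea in eas}
        return eas, cls

    def test_seed_determinism(self):
        eas, cls = self._eas()
        t = default_truth(0)
        a, _ = simulate_admissions(eas, cls, t, 500, seed=9)
        b, _ = simulate_admissions(eas, cls, t, 500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_ea_rejected(self):
        eas, cls = self._eas()
        cls.pop(eas[0].ea_id)
        with pytest.raises(ValueError, match="travel-time class"):
            simulate_admissions(eas, cls, default_truth(0), 10, seed=0)

    def test_null_model_severe_fraction(self):
        """With no effects and no spatial field the severe fraction is
        binomial around logit^-1(beta0)."""
        eas, cls = self._eas(seed=3)
        beta0 = -1.0
        t = dataclasses.replace(
            default_truth(0),
            beta0=beta0,
            beta_tt={"30-59": 0.0, "60-89": 0.0, ">=90": 0.0},
            beta_cov={},
            matern=MaternParams(0.0, 1e-3, 1.0),
        )
        m = CohortMarginals(p_exclusion_cause=0, p_missing_hb=0, p_not_anaemic=0)
        n = 10_000
        adm, _ = simulate_admissions(eas, cls, t, n, seed=1, marginals=m)
        cohort = attach_severity(adm)
        p = expit(beta0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(cohort["severe"].mean() - p) < 3 * se

    def test_large_n_odds_ratio_consistency(self):
        """A single travel-class effect of log(2.44) reappears as the
        empirical odds ratio at large n without a spatial field."""
        eas, cls = self._eas(seed=4, n=80)
        t = dataclasses.replace(
            default_truth(0),
            beta0=logit(0.2),
            beta_tt={"30-59": float(np.log(2.44)), "60-89": 0.0, ">=90": 0.0},
            beta_cov={},
            matern=MaternParams(0.0, 1e-3, 1.0),
        )
        m = CohortMarginals(
            p_exclusion_cause=0, p_missing_hb=0, p_not_anaemic=0, decay_per_min=0.0
        )
        adm, _ = simulate_admissions(eas, cls, t, 100_000, seed=2, marginals=m)
        cohort = attach_severity(adm)
        tab = pd.crosstab(cohort["tt_class"] == "30-59", cohort["severe"])
        a, b = tab.loc[True, 1], tab.loc[True, 0]
        c, d = tab.loc[False, 1], tab.loc[False, 0]
        # exclude the other exposed classes from the reference
        ref = cohort[cohort["tt_class"] == "<30"]
        c, d = ref["severe"].sum(), (1 - ref["severe"]).sum()
        or_hat = (a / b) / (c / d)
        se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert abs(np.log(or_hat) - np.log(2.44)) < 3 * se_log

    def test_marginal_calibration(self):
        """Simulated covariate prevalences match the configured targets
        within Monte-Carlo error at n=10,000."""
        eas, cls = self._eas(seed=5)
        m = CohortMarginals()
        n = 10_000
        adm, _ = simulate_admissions(eas, cls, default_truth(0), n, seed=3, marginals=m)
        checks = {
            "malaria_dx": m.p_malaria,
            "scd": m.p_scd,
            "vaccinated": m.p_vaccinated,
            "weekday": m.p_weekday,
            "wet_season": m.p_wet,
        }
        for col, target in checks.items():
            se = np.sqrt(target * (1 - target) / n)
            assert abs(adm[col].mean() - target) < 4 * se, col
        assert abs((adm["sex"] == "female").mean() - m.p_female) < 4 * 0.005
        for cat, target in m.p_age.items():
            se = np.sqrt(target * (1 - target) / n)
            assert abs((adm["age_cat"] == cat).mean() - target) < 4 * se
        # cascade fractions
        assert abs(
            (adm["exclusion_cause"] != "none").mean() - m.p_exclusion_cause
        ) < 4 * 0.005

    def test_weekday_and_season_consistent_with_dates(self):
        eas, cls = self._eas(seed=6)
        adm, _ = simulate_admissions(eas, cls, default_truth(0), 300, seed=4)
        dates = pd.to_datetime(adm["date"])
        assert ((dates.dt.weekday < 5) == adm["weekday"]).all()
        assert (dates.dt.month.isin([4, 5, 6, 10, 11, 12]) == adm["wet_season"]).all()
        assert dates.between("2020-01-01", "2023-07-31").all()

    def test_truth_round_trip_json(self, tmp_path):
        import json

        t = default_truth(11)
        t.to_json(tmp_path / "truth.json")
        d = json.loads((tmp_path / "truth.json").read_text())
        assert d["beta0"] == t.beta0
        assert d["matern"]["sigma2"] == t.matern.sigma2
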