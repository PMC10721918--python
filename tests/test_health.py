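"""Buffer-ring assignment, balance t-tests and the firm FE regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollugrid.config import SyntheticConfig
from pollugrid.geo import haversine_km
from pollugrid.health import (assign_buffers, covariate_balance_test,
                              fit_firm_regression)
from pollugrid.synthetic import generate_cancer_villages, generate_firm_panel


def firms_at(dist_km):
    """Firms due east of a single village at (100, 30), at given great-circle
    distances."""
    rows = []
    for i, d in enumerate(dist_km):
        dlon = d / (111.19492664455873 * np.cos(np.radians(30.0)))
        rows.append({"firm_id": i, "lon": 100.0 + dlon, "lat": 30.0})
    return pd.DataFrame(rows)


VILLAGE = pd.DataFrame({"village_id": [0], "lon": [100.0], "lat": [30.0]})


class TestAssignBuffers:
    def test_ring_thresholds(self):
        out = assign_buffers(firms_at([30.0, 60.0, 100.0]), VILLAGE)
        assert out["buffer"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(out["buffer"].iloc[2])

    def test_empty_villages_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_buffers(firms_at([10.0]), VILLAGE.iloc[:0])

    def test_matches_all_pairs_brute_force(self, rng):
        firms = pd.DataFrame({"firm_id": np.arange(500),
                              "lon": rng.uniform(98, 112, 500),
                              "lat": rng.uniform(24, 36, 500)})
        villages = pd.DataFrame({"village_id": np.arange(20),
                                 "lon": rng.uniform(98, 112, 20),
                                 "lat": rng.uniform(24, 36, 20)})
        out = assign_buffers(firms, villages).set_index("firm_id")
        for f in firms.itertuples():
            d = [haversine_km(f.lon, f.lat, v.lon, v.lat)
                 for v in villages.itertuples()]
            dmin = min(d)
            expect = 1.0 if dmin <= 40 else (0.0 if dmin <= 80 else np.nan)
            got = out.loc[f.firm_id]
            assert got["distance_km"] == pytest.approx(dmin, abs=1e-9)
            if np.isnan(expect):
                assert np.isnan(got["buffer"])
            else:
                assert got["buffer"] == expect

    def test_nearest_tie_broken_by_smallest_village_id(self):
        villages = pd.DataFrame({"village_id": [5, 2],
                                 "lon": [99.0, 101.0], "lat": [30.0, 30.0]})
        out = assign_buffers(firms_at([0.0]), villages)
        assert out["village_id"].iloc[0] == 2   # equidistant, smaller id


class TestBalance:
    def test_identical_samples_t_zero_p_one(self):
        units = pd.DataFrame({"g": [1, 1, 1, 0, 0, 0],
                              "v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = covariate_balance_test(units, "g", ["v"])
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_closed_form_welch(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 2, 45)
        units = pd.DataFrame({"g": [1] * 30 + [0] * 45,
                              "v": np.concatenate([a, b])})
        out = covariate_balance_test(units, "g", ["v"])
        t_cf = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 30
                                               + b.var(ddof=1) / 45)
        assert out["t"].iloc[0] == pytest.approx(t_cf, abs=1e-12)

    def test_shifted_group_detected(self, rng):
        base = rng.normal(0, 1, 50)
        units = pd.DataFrame({
            "g": [1] * 50 + [0] * 50,
            "v": np.concatenate([base, base + 5 * base.std()])})
        out = covariate_balance_test(units, "g", ["v"])
        assert out["p"].iloc[0] < 0.01

    def test_tiny_group_rejected(self):
        units = pd.DataFrame({"g": [1, 0, 0], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="< 2"):
            covariate_balance_test(units, "g", ["v"])


@pytest.fixture(scope="module")
def noise_free():
    cfg = SyntheticConfig(seed=31, noise_sd=0.0, beta_buffer=0.25,
                          beta_east_x_year_pre=0.0,
                          beta_east_x_year_post=0.0,
                          firms_per_cluster_mean=60, n_villages=2)
    panel, truth = generate_firm_panel(cfg)
    villages = generate_cancer_villages(panel, cfg, ground_truth=truth)
    return cfg, panel, villages


class TestFirmRegression:

    def test_noise_free_panel_recovers_alphas_exactly(self, noise_free):
        cfg, panel, villages = noise_free
        assign = assign_buffers(panel, villages)
        fit = fit_firm_regression(
            panel, assign, pollutant="wastewater", zero_rule="strict",
            covariates=["lnsize", "lnage", "roa", "leverage",
                        "state_owned", "foreign_owned"])
        res = fit.result
        assert abs(res.params["buffer"] - cfg.beta_buffer) < 1e-8
        assert abs(res.params["lnsize"] - cfg.beta_size) < 1e-8
        assert abs(res.params["roa"]) < 1e-8        # true coefficient is 0
        assert res.r2 == pytest.approx(1.0)

    def test_duplicate_covariate_dropped_fit_unchanged(self, noise_free):
        cfg, panel, villages = noise_free
        assign = assign_buffers(panel, villages)
        dup = panel.assign(lnsize_dup=panel["lnsize"])
        covs = ["lnsize", "lnsize_dup", "lnage", "roa"]
        fit = fit_firm_regression(dup, assign, pollutant="cod",
                                  covariates=covs, zero_rule="strict")
        base = fit_firm_regression(panel, assign, pollutant="cod",
                                   covariates=["lnsize", "lnage", "roa"],
                                   zero_rule="strict")
        assert fit.duplicate_dropped == ["lnsize_dup"]
        assert fit.result.params["lnsize"] == pytest.approx(
            base.result.params["lnsize"], abs=1e-12)

    def test_buffer_coefficient_ci_covers_truth_single_replicate(self):
        cfg = SyntheticConfig(seed=77, beta_buffer=0.2, noise_sd=0.5,
                              beta_east_x_year_pre=0.0,
                              beta_east_x_year_post=0.0,
                              n_clusters=8, firms_per_cluster_mean=80,
                              n_villages=4)
        panel, truth = generate_firm_panel(cfg)
        villages = generate_cancer_villages(panel, cfg, ground_truth=truth)
        assign = assign_buffers(panel, villages)
        fit = fit_firm_regression(
            panel, assign, pollutant="cod", zero_rule="strict",
            covariates=["lnsize", "lnage", "roa", "leverage"])
        ci = fit.result.conf_int().loc["buffer"]
        assert ci["low"] < 0.2 < ci["high"]

    def test_far_firms_counted_as_excluded(self, noise_free):
        cfg, panel, villages = noise_free
        assign = assign_buffers(panel, villages)
        fit = fit_firm_regression(panel, assign, pollutant="so2",
                                  covariates=["lnsize", "lnage"])
        n_firms = panel["firm_id"].nunique()
        assert fit.n_excluded_far == int(assign["buffer"].isna().sum()) \
            * len(cfg.years)
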