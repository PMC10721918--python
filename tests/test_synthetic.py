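"""Generator contracts: determinism, known-parameter recovery, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from pollugrid.config import SyntheticConfig
from pollugrid.synthetic import (generate_cancer_villages,
                                 generate_city_covariates,
                                 generate_firm_panel, generate_grid_panel)


def test_record_count_matches_cluster_process_expectation():
    """5 clusters x Poisson(40) firms x 15 years gives ~3,000 records,
    within generous Poisson bounds (200 +- 4*sqrt(200) firms)."""
    cfg = SyntheticConfig(n_clusters=5, firms_per_cluster_mean=40, seed=3)
    panel, _ = generate_firm_panel(cfg)
    n_firms = panel["firm_id"].nunique()
    assert 200 - 4 * np.sqrt(200) < n_firms < 200 + 4 * np.sqrt(200)
    assert len(panel) == n_firms * 15
    assert not panel.duplicated(["firm_id", "year"]).any()


def test_same_seed_byte_identical_different_seed_differs():
    a1, _ = generate_firm_panel(SyntheticConfig(seed=42))
    a2, _ = generate_firm_panel(SyntheticConfig(seed=42))
    b, _ = generate_firm_panel(SyntheticConfig(seed=43))
    pd.testing.assert_frame_equal(a1, a2)
    assert not np.array_equal(a1["x"].to_numpy()[: len(b)],
                              b["x"].to_numpy()[: len(a1)])


def test_noise_free_size_elasticity_one_gives_constant_ratio():
    """With noise 0, beta_size 1 and every other effect off, ln(P) - ln(size)
    is the pollutant's intercept at every record."""
    cfg = SyntheticConfig(seed=5, noise_sd=0.0, beta_size=1.0,
                          beta_buffer=0.0, beta_year_pre=0.0,
                          beta_year_post=0.0, beta_east_x_year_pre=0.0,
                          beta_east_x_year_post=0.0)
    panel, _ = generate_firm_panel(cfg)
    diff = np.log(panel["cod"]) - panel["lnsize"]
    assert np.ptp(diff.to_numpy()) < 1e-10
    assert diff.iloc[0] == pytest.approx(cfg.intercepts["cod"], abs=1e-10)


def test_noise_free_regression_recovers_beta_size_exactly():
    cfg = SyntheticConfig(seed=11, noise_sd=0.0, beta_buffer=0.0,
                          beta_year_pre=0.0, beta_year_post=0.0,
                          beta_east_x_year_pre=0.0, beta_east_x_year_post=0.0,
                          firms_per_cluster_mean=100)
    panel, _ = generate_firm_panel(cfg)
    slope = np.polyfit(panel["lnsize"], np.log(panel["wastewater"]), 1)[0]
    assert abs(slope - cfg.beta_size) < 1e-10


def test_cluster_process_is_more_clustered_than_uniform():
    """Mean nearest-neighbour distance under the cluster process is smaller
    than under a uniform process of the same intensity."""
    cfg = SyntheticConfig(seed=9, n_clusters=12, firms_per_cluster_mean=100)
    panel, _ = generate_firm_panel(cfg)
    pts = panel.drop_duplicates("firm_id")[["x", "y"]].to_numpy()
    assert len(pts) >= 1000
    rng = np.random.default_rng(99)
    x0, y0, x1, y1 = cfg.extent
    unif = np.column_stack([rng.uniform(x0, x1, len(pts)),
                            rng.uniform(y0, y1, len(pts))])

    def mean_nn(p):
        d, _ = cKDTree(p).query(p, k=2)
        return d[:, 1].mean()

    assert mean_nn(pts) < mean_nn(unif)


def test_invalid_extent_rejected():
    with pytest.raises(ValueError, match="extent"):
        SyntheticConfig(extent=(0.0, 0.0, -10.0, 5.0))


def test_break_year_outside_range_rejected():
    with pytest.raises(ValueError, match="break_year"):
        SyntheticConfig(year_start=1998, year_end=2012, break_year=1995)


class TestVillages:
    def test_single_village_near_top_emitting_cluster(self):
        cfg = SyntheticConfig(seed=21, n_villages=1)
        panel, truth = generate_firm_panel(cfg)
        villages = generate_cancer_villages(panel, cfg, ground_truth=truth)
        top = np.asarray(truth.cluster_centers)[truth.cluster_emission_rank[0]]
        d = np.hypot(villages["x"].iloc[0] - top[0],
                     villages["y"].iloc[0] - top[1])
        assert d < 2 * cfg.cluster_sd_km

    def test_zero_villages_empty_collection(self):
        cfg = SyntheticConfig(seed=21, n_villages=0)
        panel, truth = generate_firm_panel(cfg)
        assert generate_cancer_villages(panel, cfg, ground_truth=truth).empty

    def test_fixed_seed_identical_coordinates(self):
        cfg = SyntheticConfig(seed=8)
        p1, t1 = generate_firm_panel(cfg)
        p2, t2 = generate_firm_panel(cfg)
        v1 = generate_cancer_villages(p1, cfg, ground_truth=t1)
        v2 = generate_cancer_villages(p2, cfg, ground_truth=t2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_more_villages_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="n_villages"):
            SyntheticConfig(n_clusters=2, n_villages=5)

    def test_estimated_centers_path_without_ground_truth(self):
        cfg = SyntheticConfig(seed=21, n_villages=2)
        panel, _ = generate_firm_panel(cfg)
        v = generate_cancer_villages(panel, cfg)
        assert len(v) == 2 and v[["lon", "lat"]].notna().all().all()

    def test_empty_firms_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_cancer_villages(pd.DataFrame(), SyntheticConfig())


class TestCityCovariates:
    def test_shares_within_bounds_any_seed(self):
        for seed in (1, 2, 3):
            tab = generate_city_covariates(SyntheticConfig(seed=seed))
            assert ((tab["secondary"] + tab["tertiary"]) <= 100).all()
            assert tab["urbanrate"].between(0, 100).all()

    def test_fixed_seed_reproducible(self):
        t1 = generate_city_covariates(SyntheticConfig(seed=4))
        t2 = generate_city_covariates(SyntheticConfig(seed=4))
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_noise_gives_exactly_linear_trends(self):
        tab = generate_city_covariates(
            SyntheticConfig(seed=4, covariate_noise_sd=0.0))
        for _, g in tab.groupby("province"):
            second_diff = np.diff(g.sort_values("year")["gdppc"], n=2)
            assert np.abs(second_diff).max() < 1e-10


def test_grid_panel_truth_round_trip():
    panel, truth = generate_grid_panel(n_cells_x=4, n_cells_y=4,
                                       years=range(2001, 2011), seed=2)
    assert truth["beta_year_pre"] == 0.02
    assert set(panel["year"]) == set(range(2001, 2011))
    assert panel.groupby("cell_id")["east"].nunique().max() == 1
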