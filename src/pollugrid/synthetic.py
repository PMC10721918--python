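"""Synthetic firm-year pollution panels with known ground truth.

The real national firm-pollution database behind this kind of study is
confidential, so every downstream stage (gridding, interpolation, Moran
statistics, buffer and regime regressions) is exercised on panels generated
here, with the generating parameters returned alongside the data.

Generating model
----------------
Firm locations follow a Matern-style cluster process: parent centers uniform
in the planar extent, offspring Gaussian with sd ``cluster_sd_km``.  Each firm
keeps its location, industry and province for the whole 1998-2012 window.  Log
emissions of pollutant j by firm i in year t are

    ln P_jit = b0_j + beta_size * lnsize_it + beta_buffer * near_village_i
               + s_j * trend(t, east_i) + eps_jit,   eps ~ N(0, noise_sd)

where ``trend`` is piecewise linear, rising before the break year and falling
after it, with an additional East-region slope differential, and ``s_j`` is a
per-pollutant scale.  ``near_village_i`` indicates a firm within the inner
buffer ring (default 40 km, great-circle) of a cancer village; villages are
sited at jittered centers of the highest-emitting clusters, so proximity and
emissions correlate positively by construction.

Cluster-level heterogeneity enters emissions only through the observed
covariate ``lnsize`` (cluster-specific mean shifts), never through an
unobserved intercept, so the buffer coefficient stays identified in the
downstream regression.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .config import POLLUTANTS, GroundTruth, SyntheticConfig
from .geo import SyntheticPlane, haversine_km

__all__ = [
    "generate_firm_panel",
    "generate_city_covariates",
    "generate_cancer_villages",
    "generate_grid_panel",
    "write_firm_panel",
    "write_covariates",
    "write_villages_geojson",
    "read_villages_geojson",
]


def _province_of(x, y, cfg: SyntheticConfig):
    """Map planar points to rectangular province blocks P00..Pnm."""
    x0, y0, x1, y1 = cfg.extent
    ix = np.clip(((np.asarray(x) - x0) / (x1 - x0) * cfg.n_prov_x).astype(int),
                 0, cfg.n_prov_x - 1)
    iy = np.clip(((np.asarray(y) - y0) / (y1 - y0) * cfg.n_prov_y).astype(int),
                 0, cfg.n_prov_y - 1)
    return np.array([f"P{a:d}{b:d}" for a, b in zip(ix, iy)])


def province_region_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Province -> region lookup (East / Central / West) from block centers."""
    x0, y0, x1, y1 = cfg.extent
    rows = []
    for ix in range(cfg.n_prov_x):
        cx = x0 + (ix + 0.5) * (x1 - x0) / cfg.n_prov_x
        if cx >= cfg.east_boundary_x:
            region = "East"
        elif cx < cfg.west_boundary_x:
            region = "West"
        else:
            region = "Central"
        for iy in range(cfg.n_prov_y):
            rows.append({"province": f"P{ix:d}{iy:d}", "region": region})
    return pd.DataFrame(rows)


def _trend(year, east, cfg: SyntheticConfig):
    """Piecewise-linear log-emission trend, peaking at the break year."""
    year = np.asarray(year, dtype=float)
    east = np.asarray(east, dtype=float)
    tau = year - cfg.break_year
    pre = tau <= 0
    slope = np.where(pre,
                     cfg.beta_year_pre + east * cfg.beta_east_x_year_pre,
                     cfg.beta_year_post + east * cfg.beta_east_x_year_post)
    return slope * tau


def generate_firm_panel(config: SyntheticConfig):
    """Generate a firm-year panel and its :class:`GroundTruth`.

    Returns ``(panel, truth)`` where ``panel`` is a DataFrame with one row per
    firm-year and ``truth`` records cluster centers, village sites and every
    coefficient used.  The same config (including seed) yields byte-identical
    output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    x0, y0, x1, y1 = cfg.extent
    plane = SyntheticPlane()

    centers = np.column_stack([
        rng.uniform(x0, x1, cfg.n_clusters),
        rng.uniform(y0, y1, cfg.n_clusters),
    ])
    lnsize_shift = rng.normal(0.0, cfg.cluster_size_sd, cfg.n_clusters)
    n_per = rng.poisson(cfg.firms_per_cluster_mean, cfg.n_clusters)
    n_per = np.maximum(n_per, 1)

    cluster_id = np.repeat(np.arange(cfg.n_clusters), n_per)
    n_firms = int(n_per.sum())
    xy = centers[cluster_id] + rng.normal(0.0, cfg.cluster_sd_km, (n_firms, 2))
    lon, lat = plane.inverse(xy[:, 0], xy[:, 1])

    lnsize_base = rng.normal(4.0, 1.0, n_firms) + lnsize_shift[cluster_id]
    lnage = np.log(rng.integers(1, 41, n_firms).astype(float))
    export = np.where(rng.random(n_firms) < 0.3, rng.uniform(0, 1, n_firms), 0.0)
    roa = rng.normal(0.05, 0.05, n_firms)
    leverage = rng.normal(1.0, 0.3, n_firms)
    state_owned = (rng.random(n_firms) < 0.2).astype(int)
    foreign_owned = (rng.random(n_firms) < 0.15).astype(int)
    industry = rng.integers(13, 43, n_firms)
    province = _province_of(xy[:, 0], xy[:, 1], cfg)
    region_map = province_region_table(cfg).set_index("province")["region"]
    region = region_map.loc[province].to_numpy()
    east = (region == "East").astype(int)

    # Rank clusters by expected wastewater output (before any village effect)
    # and site villages at jittered centers of the top emitters.
    potential = np.exp(cfg.intercepts["wastewater"] + cfg.beta_size * lnsize_base)
    cluster_pot = np.bincount(cluster_id, weights=potential,
                              minlength=cfg.n_clusters)
    rank = np.argsort(-cluster_pot)
    village_xy = (centers[rank[: cfg.n_villages]]
                  + rng.normal(0.0, cfg.village_jitter_km,
                               (cfg.n_villages, 2)))
    if cfg.n_villages:
        vlon, vlat = plane.inverse(village_xy[:, 0], village_xy[:, 1])
        village_lonlat = np.column_stack([vlon, vlat])
        dist = haversine_km(lon[:, None], lat[:, None],
                            vlon[None, :], vlat[None, :])
        near_village = (dist.min(axis=1) <= cfg.buffer_inner_km).astype(int)
    else:
        village_lonlat = np.empty((0, 2))
        near_village = np.zeros(n_firms, dtype=int)

    years = np.array(cfg.years)
    n_years = len(years)
    rep = lambda a: np.repeat(a, n_years)  # noqa: E731 firm-level -> panel
    panel = pd.DataFrame({
        "firm_id": rep(np.arange(n_firms)),
        "year": np.tile(years, n_firms),
        "lon": rep(lon), "lat": rep(lat),
        "x": rep(xy[:, 0]), "y": rep(xy[:, 1]),
        "industry": rep(industry),
        "province": rep(province),
        "region": rep(region),
        "lnage": rep(lnage), "export": rep(export), "roa": rep(roa),
        "leverage": rep(leverage),
        "state_owned": rep(state_owned), "foreign_owned": rep(foreign_owned),
    })
    lnsize = rep(lnsize_base) + rng.uniform(-0.1, 0.1, len(panel))
    panel["lnsize"] = lnsize

    trend = _trend(panel["year"].to_numpy(), rep(east), cfg)
    base = cfg.beta_size * lnsize + cfg.beta_buffer * rep(near_village)
    for pol in POLLUTANTS:
        eps = rng.normal(0.0, cfg.noise_sd, len(panel)) if cfg.noise_sd > 0 else 0.0
        lnp = cfg.intercepts[pol] + base + cfg.trend_scale[pol] * trend + eps
        panel[pol] = np.exp(lnp)

    cols = ["firm_id", "year", "lon", "lat", "x", "y", "industry", "province",
            "region", "wastewater", "cod", "so2", "lnsize", "lnage", "export",
            "roa", "leverage", "state_owned", "foreign_owned"]
    panel = panel[cols]

    truth = GroundTruth(
        config=cfg,
        cluster_centers=centers.tolist(),
        cluster_lnsize_shift=lnsize_shift.tolist(),
        village_xy=village_xy.tolist(),
        village_lonlat=village_lonlat.tolist(),
        cluster_emission_rank=rank.tolist(),
    )
    return panel, truth


def generate_city_covariates(config: SyntheticConfig) -> pd.DataFrame:
    """Province-year covariate table with smooth trends plus small noise.

    Columns: province, year, gdppc (10k RMB), secondary and tertiary (shares
    of GDP, percent, summing to <= 100), urbanrate (percent, in [0, 100]),
    pop_intensity (persons per km2 proxy), unemployment (percent).  With
    ``covariate_noise_sd = 0`` every series is exactly linear in the year.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 10_000)
    provinces = province_region_table(cfg)["province"].tolist()
    years = np.array(cfg.years, dtype=float)
    t = years - years[0]
    rows = []
    for prov in provinces:
        base = {
            "gdppc": rng.uniform(1.0, 5.0), "gdppc_slope": rng.uniform(0.1, 0.3),
            "secondary": rng.uniform(35.0, 48.0),
            "secondary_slope": rng.uniform(-0.4, 0.0),
            "tertiary": rng.uniform(28.0, 38.0),
            "tertiary_slope": rng.uniform(0.0, 0.4),
            "urbanrate": rng.uniform(30.0, 55.0),
            "urbanrate_slope": rng.uniform(0.4, 1.0),
            "pop_intensity": rng.uniform(200.0, 2000.0),
            "pop_slope": rng.uniform(0.0, 20.0),
            "unemployment": rng.uniform(3.0, 5.0),
            "unemp_slope": rng.uniform(-0.05, 0.05),
        }
        # per-variable noise scales (units of each series) times the config
        # multiplier; year-to-year variation keeps the covariates from being
        # collinear with a within-province linear trend
        scales = np.array([0.2, 1.0, 1.0, 1.0, 5.0, 0.2])
        noise = (rng.normal(0.0, 1.0, (6, len(years)))
                 * (cfg.covariate_noise_sd * scales)[:, None]
                 if cfg.covariate_noise_sd > 0 else np.zeros((6, len(years))))
        rows.append(pd.DataFrame({
            "province": prov, "year": years.astype(int),
            "gdppc": base["gdppc"] + base["gdppc_slope"] * t + noise[0],
            "secondary": base["secondary"] + base["secondary_slope"] * t + noise[1],
            "tertiary": base["tertiary"] + base["tertiary_slope"] * t + noise[2],
            "urbanrate": np.clip(
                base["urbanrate"] + base["urbanrate_slope"] * t + noise[3],
                0.0, 100.0),
            "pop_intensity": base["pop_intensity"] + base["pop_slope"] * t
                             + noise[4],
            "unemployment": np.clip(
                base["unemployment"] + base["unemp_slope"] * t + noise[5],
                0.0, None),
        }))
    return pd.concat(rows, ignore_index=True)


def generate_cancer_villages(firms: pd.DataFrame, config: SyntheticConfig,
                             ground_truth: GroundTruth | None = None) -> pd.DataFrame:
    """Cancer-village sites near the highest-emission firm clusters.

    With ``ground_truth`` given, returns the exact villages used during panel
    generation.  Otherwise cluster centers are re-estimated from the firm
    locations (k-means, seeded) and ranked by total recorded wastewater.
    Returns a DataFrame (village_id, lon, lat, x, y).
    """
    cfg = config
    if firms.empty:
        raise ValueError("firm collection is empty")
    if cfg.n_villages == 0:
        return pd.DataFrame(columns=["village_id", "lon", "lat", "x", "y"])

    if ground_truth is not None:
        xy = np.asarray(ground_truth.village_xy, dtype=float)
        ll = np.asarray(ground_truth.village_lonlat, dtype=float)
        return pd.DataFrame({
            "village_id": np.arange(len(xy)),
            "lon": ll[:, 0], "lat": ll[:, 1],
            "x": xy[:, 0], "y": xy[:, 1],
        })

    from sklearn.cluster import KMeans
    locs = firms.drop_duplicates("firm_id")[["firm_id", "x", "y"]]
    km = KMeans(n_clusters=cfg.n_clusters, n_init=10,
                random_state=cfg.seed % (2**31)).fit(locs[["x", "y"]])
    lab = pd.Series(km.labels_, index=locs["firm_id"].to_numpy())
    totals = (firms.assign(_c=lab.reindex(firms["firm_id"]).to_numpy())
              .groupby("_c")["wastewater"].sum())
    top = totals.sort_values(ascending=False).index[: cfg.n_villages]
    rng = np.random.default_rng(cfg.seed + 20_000)
    xy = km.cluster_centers_[np.asarray(top, dtype=int)] + rng.normal(
        0.0, cfg.village_jitter_km, (cfg.n_villages, 2))
    lon, lat = SyntheticPlane().inverse(xy[:, 0], xy[:, 1])
    return pd.DataFrame({"village_id": np.arange(cfg.n_villages),
                         "lon": lon, "lat": lat, "x": xy[:, 0], "y": xy[:, 1]})


def generate_grid_panel(n_cells_x=20, n_cells_y=20, years=range(2001, 2011),
                        break_year=2006, beta_year_pre=0.02,
                        beta_year_post=-0.03, beta_east_pre=0.01,
                        beta_east_post=0.01, gamma=None, noise_sd=0.02,
                        ar_rho=0.0, east_frac=0.4, seed=0,
                        value_col="index") -> tuple[pd.DataFrame, dict]:
    """Cell-year index panel with a built-in trend regime shift.

    Direct data-generating process for the grid-panel regression: cell fixed
    effects drawn U(0.35, 0.6), piecewise-linear year trend with slope
    ``beta_year_pre`` strictly before ``break_year`` and ``beta_year_post``
    from the break on (each plus the East differential for eastern cells),
    optional province-covariate effects ``gamma`` and optionally AR(1) errors
    within a cell (``ar_rho``) to induce cluster correlation.

    Slopes apply to year centered at each regime window's start, so the
    regression's centered-year coefficient equals the generating slope.
    Returns ``(panel, truth)``.
    """
    years = np.array(sorted(years))
    rng = np.random.default_rng(seed)
    n_cells = n_cells_x * n_cells_y
    gamma = dict(gamma or {})
    cols = np.arange(n_cells) % n_cells_x
    east = (cols >= (1.0 - east_frac) * n_cells_x).astype(int)
    cell_fe = rng.uniform(0.35, 0.6, n_cells)
    provinces = cols // max(1, n_cells_x // 4)

    n_prov = int(provinces.max()) + 1
    cov_base = {name: rng.uniform(1.0, 5.0, n_prov)
                for name in ("gdppc", "secondary", "tertiary", "urbanrate")}
    cov_slope = {name: rng.uniform(-0.1, 0.1, n_prov)
                 for name in cov_base}

    recs = []
    pre_start, post_start = years[years < break_year], years[years >= break_year]
    for i in range(n_cells):
        e = np.zeros(len(years))
        white = rng.normal(0.0, noise_sd, len(years))
        for t in range(len(years)):
            e[t] = (ar_rho * e[t - 1] if t else 0.0) + white[t]
        for t, yr in enumerate(years):
            if yr < break_year:
                yc = yr - (pre_start[0] if len(pre_start) else yr)
                tr = (beta_year_pre + east[i] * beta_east_pre) * yc
            else:
                yc = yr - (post_start[0] if len(post_start) else yr)
                tr = (beta_year_post + east[i] * beta_east_post) * yc
            xk = {name: cov_base[name][provinces[i]]
                  + cov_slope[name][provinces[i]] * (yr - years[0])
                  for name in cov_base}
            val = cell_fe[i] + tr + sum(gamma.get(k, 0.0) * v
                                        for k, v in xk.items()) + e[t]
            recs.append({"cell_id": i, "year": int(yr), value_col: val,
                         "east": int(east[i]), "province": int(provinces[i]),
                         **xk})
    panel = pd.DataFrame(recs)
    truth = {"beta_year_pre": beta_year_pre, "beta_year_post": beta_year_post,
             "beta_east_pre": beta_east_pre, "beta_east_post": beta_east_post,
             "gamma": gamma, "noise_sd": noise_sd, "ar_rho": ar_rho,
             "break_year": break_year, "cell_fe": cell_fe.tolist()}
    return panel, truth


# ---------------------------------------------------------------------------
# Writers for the ingestion schema


def write_firm_panel(panel: pd.DataFrame, path):
    panel.to_csv(path, index=False, float_format="%.10g")


def write_covariates(table: pd.DataFrame, path):
    table.to_csv(path, index=False, float_format="%.10g")


def write_villages_geojson(villages: pd.DataFrame, path):
    """Write village points as a WGS84 GeoJSON FeatureCollection."""
    features = [{
        "type": "Feature",
        "geometry": {"type": "Point",
                     "coordinates": [round(float(r.lon), 10),
                                     round(float(r.lat), 10)]},
        "properties": {"village_id": int(r.village_id)},
    } for r in villages.itertuples()]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features},
                  fh, indent=1, sort_keys=True)


def read_villages_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    rows = [{"village_id": f["properties"].get("village_id", i),
             "lon": f["geometry"]["coordinates"][0],
             "lat": f["geometry"]["coordinates"][1]}
            for i, f in enumerate(gj["features"])]
    return pd.DataFrame(rows)
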