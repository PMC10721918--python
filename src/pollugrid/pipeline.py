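"""One-command pipeline: synthetic panel -> grid -> surfaces -> indices ->
Moran/LISA -> buffer regression -> regime regressions, with a hashed
artifact manifest.

Every stage writes plain CSV (fixed float formatting, so reruns with the
same seed are byte-identical) into the output directory and re-reads its
inputs from there, which makes the pipeline re-entrant: any stage can be
re-run from an existing directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grid as gridmod
from . import health, moran, raster, regime, surfaces, synthetic
from .config import POLLUTANTS, SyntheticConfig
from .regression import format_table

log = logging.getLogger("pollugrid")

FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Pipeline settings; either synthetic generation or input paths."""

    outdir: str = "run"
    seed: int = 0
    synthetic: bool = True
    synthetic_params: dict = field(default_factory=dict)
    firm_csv: str | None = None
    covariates_csv: str | None = None
    villages_geojson: str | None = None
    region_csv: str | None = None
    cell_size: float = 100.0
    empty_cells: str = "missing"        # or "zero"
    nq: int = 13
    nw: int = 19
    pooling: str = "pooled"
    weights_scheme: str = "queen"
    weights_standardization: str = "row"
    n_permutations: int = 999
    lisa_alpha: float = 0.05
    lisa_years: list | None = None      # default: first, break, last
    covariate_preset: str = "table1"
    zero_rule: str = "log1p"

    def __post_init__(self):
        if not self.synthetic:
            missing = [p for p in (self.firm_csv, self.covariates_csv,
                                   self.villages_geojson) if p is None]
            if missing:
                raise ValueError("non-synthetic runs need firm_csv, "
                                 "covariates_csv and villages_geojson")
            for p in (self.firm_csv, self.covariates_csv,
                      self.villages_geojson):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.seed, **self.synthetic_params)


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out: Path):
    scfg = cfg.synthetic_config()
    panel, truth = synthetic.generate_firm_panel(scfg)
    cov = synthetic.generate_city_covariates(scfg)
    villages = synthetic.generate_cancer_villages(panel, scfg,
                                                  ground_truth=truth)
    synthetic.write_firm_panel(panel, out / "firms.csv")
    synthetic.write_covariates(cov, out / "covariates.csv")
    synthetic.write_villages_geojson(villages, out / "villages.geojson")
    _write(synthetic.province_region_table(scfg), out / "province_regions.csv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({**truth.__dict__, "config": scfg.to_dict()}, fh, indent=1,
                  sort_keys=True, default=float)
    log.info("simulate: %d firm-years, %d villages", len(panel),
             len(villages))


def _load_inputs(cfg: RunConfig, out: Path):
    if cfg.synthetic:
        firms = pd.read_csv(out / "firms.csv")
        cov = pd.read_csv(out / "covariates.csv")
        villages = synthetic.read_villages_geojson(out / "villages.geojson")
        regions = pd.read_csv(out / "province_regions.csv")
    else:
        firms = pd.read_csv(cfg.firm_csv)
        cov = pd.read_csv(cfg.covariates_csv)
        villages = synthetic.read_villages_geojson(cfg.villages_geojson)
        regions = gridmod.load_province_regions(cfg.region_csv)
        if "x" not in firms.columns:
            from .geo import AlbersEqualArea
            proj = AlbersEqualArea()
            firms["x"], firms["y"] = proj.forward(
                firms["lon"], firms["lat"], ids=firms["firm_id"])
    return firms, cov, villages, regions


def _grid_spec(cfg: RunConfig, firms: pd.DataFrame) -> gridmod.GridSpec:
    if cfg.synthetic:
        extent = cfg.synthetic_config().extent
    else:
        pad = cfg.cell_size / 2
        extent = (firms["x"].min() - pad, firms["y"].min() - pad,
                  firms["x"].max() + pad, firms["y"].max() + pad)
    return gridmod.build_grid(extent, cfg.cell_size)


def stage_grid(cfg: RunConfig, out: Path):
    firms, _, _, regions = _load_inputs(cfg, out)
    spec = _grid_spec(cfg, firms)
    cells, excluded = gridmod.assign_cells(firms, spec)
    agg = gridmod.aggregate_panel(firms, cells, spec, empty=cfg.empty_cells)

    # cell metadata: province = modal province of firms in the cell, filled
    # from the nearest occupied cell; region from the province lookup.
    frame = spec.frame()
    firms2 = firms.assign(cell=cells)
    modal = (firms2[firms2["cell"] >= 0].groupby("cell")["province"]
             .agg(lambda s: s.mode().iloc[0]))
    frame["province"] = frame["cell"].map(modal)
    occ = frame.dropna(subset=["province"])
    if frame["province"].isna().any():
        from scipy.spatial import cKDTree
        tree = cKDTree(occ[["x", "y"]])
        miss = frame["province"].isna()
        _, j = tree.query(frame.loc[miss, ["x", "y"]])
        frame.loc[miss, "province"] = occ["province"].to_numpy()[j]
    rmap = regions.set_index("province")["region"]
    frame["region"] = frame["province"].map(rmap)
    frame["region2"] = np.where(frame["region"] == "East", "East",
                                "Central & West")
    _write(frame, out / "cells.csv")
    _write(excluded, out / "exclusions.csv")
    _write(agg, out / "aggregates.csv")
    log.info("grid: %dx%d cells, %d excluded firm-years",
             spec.n_rows, spec.n_cols, len(excluded))
    return spec


def stage_interpolate(cfg: RunConfig, out: Path):
    firms, *_ = _load_inputs(cfg, out)
    spec = _grid_spec(cfg, firms)
    agg = pd.read_csv(out / "aggregates.csv")
    surf = surfaces.build_surfaces(agg, spec, nq=cfg.nq, nw=cfg.nw)
    _write(surf, out / "surfaces.csv")
    log.info("interpolate: %d surfaces",
             surf.groupby(["pollutant", "year"]).ngroups)


def stage_index(cfg: RunConfig, out: Path):
    surf = pd.read_csv(out / "surfaces.csv")
    cells = pd.read_csv(out / "cells.csv")
    idx = surfaces.normalize_indices(surf, pooling=cfg.pooling)
    _write(idx, out / "indices.csv")
    series = surfaces.regional_series(
        idx, cells.set_index("cell")["region2"])
    _write(series, out / "regional_series.csv")
    y0, y1 = int(idx["year"].min()), int(idx["year"].max())
    _write(surfaces.index_change(series, y0, y1), out / "index_changes.csv")
    log.info("index: pooled min/max per pollutant, changes %d->%d", y0, y1)


def stage_moran(cfg: RunConfig, out: Path):
    firms, *_ = _load_inputs(cfg, out)
    spec = _grid_spec(cfg, firms)
    idx = pd.read_csv(out / "indices.csv")
    W = moran.build_contiguity_weights(
        spec, scheme=cfg.weights_scheme,
        standardization=cfg.weights_standardization)
    rows = []
    for (pol, year), sub in idx.groupby(["pollutant", "year"]):
        vals = sub.sort_values("cell")["index"].to_numpy()
        res = moran.global_morans_i(vals, W, cfg.n_permutations,
                                    seed=cfg.seed)
        rows.append({"pollutant": pol, "year": year, "I": res.I,
                     "expected_I": res.expected_I, "p_value": res.p_value})
    _write(pd.DataFrame(rows), out / "moran_global.csv")
    log.info("moran: %d pollutant-years", len(rows))


def stage_lisa(cfg: RunConfig, out: Path):
    firms, *_ = _load_inputs(cfg, out)
    spec = _grid_spec(cfg, firms)
    idx = pd.read_csv(out / "indices.csv")
    years = sorted(idx["year"].unique())
    use_years = cfg.lisa_years or sorted(
        {years[0], years[len(years) // 2], years[-1]})
    W = moran.build_contiguity_weights(
        spec, scheme=cfg.weights_scheme,
        standardization=cfg.weights_standardization)
    for pol in idx["pollutant"].unique():
        for year in use_years:
            sub = idx[(idx["pollutant"] == pol) & (idx["year"] == year)]
            vals = sub.sort_values("cell")["index"].to_numpy()
            res = moran.local_morans_i(vals, W, cfg.n_permutations,
                                       seed=cfg.seed)
            labels = moran.classify_clusters(res, alpha=cfg.lisa_alpha)
            tab = pd.DataFrame({"cell": res.ids, "I_i": res.I,
                                "quadrant": res.quadrant,
                                "pseudo_p": res.p_value, "label": labels})
            stem = f"lisa_{pol}_{year}"
            _write(tab, out / f"{stem}.csv")
            raster.export_lisa_png(labels, spec, out / f"{stem}.png")
            raster.export_heatmap(vals, spec, out / f"index_{pol}_{year}.tif",
                                  png_path=out / f"index_{pol}_{year}.png")
    log.info("lisa: years %s", use_years)


def stage_health(cfg: RunConfig, out: Path):
    firms, cov, villages, _ = _load_inputs(cfg, out)
    panel = firms.merge(
        cov[["province", "year", "gdppc", "pop_intensity", "unemployment"]],
        on=["province", "year"], how="left")
    assign = health.assign_buffers(firms, villages)
    _write(assign, out / "buffer_assignments.csv")
    mid_year = int(np.median(firms["year"].unique()))
    units = firms[firms["year"] == mid_year].merge(
        assign[["firm_id", "buffer"]], on="firm_id").dropna(subset=["buffer"])
    balance = health.covariate_balance_test(
        units, "buffer", ["lnsize", "lnage", "roa", "leverage"])
    _write(balance, out / "health_balance.csv")
    results = {}
    for pol in POLLUTANTS:
        fit = health.fit_firm_regression(
            panel, assign, pollutant=pol, covariates=cfg.covariate_preset,
            zero_rule=cfg.zero_rule)
        results[f"ln_{pol}"] = fit.result
        _write(fit.result.tidy(), out / f"health_regression_{pol}.csv")
    (out / "health_regression.txt").write_text(
        format_table(results, title="Firm emissions vs cancer-village "
                     "buffer rings") + "\n")
    log.info("health: %d firms in rings, balance year %d",
             int(assign["buffer"].notna().sum()), mid_year)


def stage_regime(cfg: RunConfig, out: Path):
    idx = pd.read_csv(out / "indices.csv")
    cells = pd.read_csv(out / "cells.csv")
    cov = _load_inputs(cfg, out)[1]
    meta = cells.set_index("cell")
    panel = idx.rename(columns={"cell": "cell_id"})
    panel["east"] = (meta["region2"].reindex(panel["cell_id"])
                     .eq("East").to_numpy().astype(int))
    panel["province"] = meta["province"].reindex(panel["cell_id"]).to_numpy()
    panel = panel.merge(
        cov[["province", "year", "gdppc", "secondary", "tertiary",
             "urbanrate"]], on=["province", "year"], how="left")
    contrasts = []
    results = {}
    for pol in panel["pollutant"].unique():
        sub = panel[panel["pollutant"] == pol].rename(
            columns={"index": "index_val"})
        fits = {}
        for window in (regime.FYP10, regime.FYP11):
            fit = regime.fit_grid_panel_regression(sub, "index_val", window)
            fits[window.label] = fit
            results[f"{pol} {window.label}"] = fit.result
            _write(fit.result.tidy(),
                   out / f"regime_{pol}_{window.label}.csv")
        con = regime.regime_contrast(fits["FYP10"], fits["FYP11"])
        contrasts.append({
            "pollutant": pol,
            "year_pre": con["year"]["pre"]["coef"],
            "year_post": con["year"]["post"]["coef"],
            "year_sign_flip": con["year"]["sign_flip"],
            "regime_shift": con["regime_shift"],
        })
    _write(pd.DataFrame(contrasts), out / "regime_contrast.csv")
    (out / "regime_regression.txt").write_text(
        format_table(results, title="Grid-panel index trends by FYP window")
        + "\n")
    log.info("regime: %d pollutants contrasted", len(contrasts))


STAGES = {
    "simulate": stage_simulate,
    "grid": stage_grid,
    "interpolate": stage_interpolate,
    "index": stage_index,
    "moran": stage_moran,
    "lisa": stage_lisa,
    "health": stage_health,
    "regime": stage_regime,
}


def write_manifest(out: Path) -> dict:
    """Hash every artifact in the run directory (sha256 of file bytes)."""
    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(cfg: RunConfig, stages=None) -> dict:
    """Execute the requested stages (default: all) and write the manifest.

    Any stage failure aborts with the stage name attached.  Returns the
    manifest mapping artifact names to content hashes.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else list(stages)
    if not cfg.synthetic and "simulate" in todo:
        todo.remove("simulate")
    for name in todo:
        t0 = time.perf_counter()
        try:
            STAGES[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
    return write_manifest(out)
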