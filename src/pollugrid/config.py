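"""Configuration dataclasses for the synthetic generator and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

POLLUTANTS = ("wastewater", "cod", "so2")


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the synthetic firm-year panel.

    The generator emulates a national firm-level pollution panel: spatially
    clustered firm locations (Matern-style cluster process), three pollutant
    series log-linear in firm size and covariates, an upward emission trend
    before ``break_year`` and a downward trend after it with an East-vs-rest
    differential, and cancer villages sited near the highest-emission
    clusters.

    Trend coefficients are per-year changes of log emissions; ``trend_scale``
    differentiates the three pollutants (COD steeper than wastewater and SO2,
    mirroring the ordering of observed declines after pollutant-specific
    control targets).
    """

    n_clusters: int = 5
    cluster_sd_km: float = 30.0
    firms_per_cluster_mean: float = 40.0
    year_start: int = 1998
    year_end: int = 2012
    break_year: int = 2006
    beta_size: float = 0.9
    beta_buffer: float = 0.2
    beta_year_pre: float = 0.04
    beta_year_post: float = -0.07
    beta_east_x_year_pre: float = -0.005
    beta_east_x_year_post: float = -0.005
    noise_sd: float = 0.5
    n_villages: int = 3
    extent: tuple = (0.0, 0.0, 2000.0, 1500.0)  # (x0, y0, x1, y1) km
    east_boundary_x: float = 1200.0
    west_boundary_x: float = 600.0
    seed: int = 0
    # per-pollutant log-level intercepts and trend multipliers
    intercepts: dict = field(default_factory=lambda: {
        "wastewater": 8.0, "cod": 4.0, "so2": 5.0})
    trend_scale: dict = field(default_factory=lambda: {
        "wastewater": 0.6, "cod": 2.0, "so2": 0.7})
    cluster_size_sd: float = 0.5      # sd of cluster-level mean-lnsize shifts
    village_jitter_km: float = 5.0    # jitter of village sites about centers
    buffer_inner_km: float = 40.0     # radius of the treated inner ring
    n_prov_x: int = 4                 # province blocks along x
    n_prov_y: int = 3                 # province blocks along y
    covariate_noise_sd: float = 0.5   # province covariate noise multiplier

    def __post_init__(self):
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"extent must have positive area, got {self.extent}")
        if self.year_end < self.year_start:
            raise ValueError("years range is empty")
        if not (self.year_start <= self.break_year <= self.year_end):
            raise ValueError("break_year must lie inside the year range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("n_clusters", "n_prov_x", "n_prov_y"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.firms_per_cluster_mean < 1:
            raise ValueError("firms_per_cluster_mean must be >= 1")
        if self.n_villages < 0:
            raise ValueError("n_villages must be >= 0")
        if self.n_villages > self.n_clusters:
            raise ValueError(
                f"n_villages ({self.n_villages}) cannot exceed "
                f"n_clusters ({self.n_clusters})")

    @property
    def years(self):
        return list(range(self.year_start, self.year_end + 1))

    def to_dict(self):
        return asdict(self)


@dataclass
class GroundTruth:
    """Record of the parameters actually used for generation.

    Returned alongside every synthetic panel so recovery tests never have to
    re-derive the truth from the data.
    """

    config: SyntheticConfig
    cluster_centers: "list"           # (n_clusters, 2) planar km
    cluster_lnsize_shift: "list"      # per-cluster mean-lnsize shift
    village_xy: "list"                # (n_villages, 2) planar km
    village_lonlat: "list"            # (n_villages, 2) WGS84
    cluster_emission_rank: "list"     # cluster indices, highest emitters first
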