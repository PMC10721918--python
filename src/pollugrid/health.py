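"""Cancer-village buffer rings and the firm-level pollutant regression.

Firms are assigned to buffer rings by great-circle distance to the nearest
cancer village: the inner disk (<= 40 km, ``buffer = 1``, treated), the
annulus (40-80 km, ``buffer = 0``, control), and beyond 80 km (excluded from
the regression sample).  The regression is OLS of log pollutant emissions on
the buffer dummy, its interactions with the 10th/11th Five-Year-Plan period
dummies, firm and city covariates, and industry + year fixed effects:

    ln P_it = a0 + a1 buffer + a2 buffer x k10 + a3 buffer x k11
              + covariates + industry FE + year FE + e_it

Zero pollutant values are handled by ln(1 + P) by default; a strict-log mode
drops them instead (both choices are surfaced in the result).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import haversine_km
from .regression import RegressionResult, fit_ols_fe

__all__ = ["assign_buffers", "covariate_balance_test", "fit_firm_regression",
           "COVARIATE_PRESETS"]

#: Covariate presets: "table1" matches the published regression table's
#: column list (includes export, omits unemployment); "equation" follows the
#: model equation's narrative list (includes unemployment).
COVARIATE_PRESETS = {
    "table1": ["lnsize", "lnage", "export", "roa", "leverage", "state_owned",
               "foreign_owned", "pop_intensity", "gdppc"],
    "equation": ["lnsize", "lnage", "roa", "leverage", "state_owned",
                 "foreign_owned", "pop_intensity", "unemployment", "gdppc"],
}


def assign_buffers(firms: pd.DataFrame, villages: pd.DataFrame,
                   inner_km=40.0, outer_km=80.0) -> pd.DataFrame:
    """Distance to the nearest village and the resulting ring assignment.

    One row per unique firm: ``distance_km``, ``village_id`` (nearest, ties
    broken by smallest id), and ``buffer`` (1 inner, 0 annulus, NaN beyond
    ``outer_km`` — excluded).  A firm within ``inner_km`` of ANY village is
    treated, regardless of other villages' rings (nearest-village rule).
    """
    if villages.empty:
        raise ValueError("village list is empty")
    if not inner_km < outer_km:
        raise ValueError("inner_km must be smaller than outer_km")
    locs = firms.drop_duplicates("firm_id")[["firm_id", "lon", "lat"]]
    v = villages.sort_values("village_id")
    d = haversine_km(locs["lon"].to_numpy()[:, None],
                     locs["lat"].to_numpy()[:, None],
                     v["lon"].to_numpy()[None, :],
                     v["lat"].to_numpy()[None, :])
    nearest = d.argmin(axis=1)          # argmin takes the first (smallest id)
    dist = d[np.arange(len(locs)), nearest]
    buf = np.where(dist <= inner_km, 1.0,
                   np.where(dist <= outer_km, 0.0, np.nan))
    return pd.DataFrame({
        "firm_id": locs["firm_id"].to_numpy(),
        "distance_km": dist,
        "village_id": v["village_id"].to_numpy()[nearest],
        "buffer": buf,
    })


def covariate_balance_test(units: pd.DataFrame, group_col: str,
                           covariates) -> pd.DataFrame:
    """Welch two-sample t-test of each covariate between the two buffer
    groups; reports group means, t and p."""
    groups = sorted(units[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, found {groups}")
    g1 = units[units[group_col] == groups[1]]
    g0 = units[units[group_col] == groups[0]]
    rows = []
    for cov in covariates:
        a, b = g1[cov].dropna(), g0[cov].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group with < 2 units for covariate {cov!r}")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"covariate": cov, "mean_treated": a.mean(),
                     "mean_control": b.mean(), "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class FirmRegressionOutput:
    result: RegressionResult
    outcome: str
    zero_rule: str
    n_excluded_far: int
    duplicate_dropped: list


def fit_firm_regression(panel: pd.DataFrame, assignments: pd.DataFrame,
                        pollutant="wastewater", covariates="table1",
                        zero_rule="log1p", se_type="plain", cluster=None,
                        fyp10_years=range(2001, 2006),
                        fyp11_start=2006) -> FirmRegressionOutput:
    """Firm-level FE regression of log emissions on the buffer dummy.

    ``covariates`` is a preset name or an explicit list; exact-duplicate
    covariate columns are dropped with a report (other perfect collinearity
    raises).  ``zero_rule='log1p'`` uses ln(1+P); ``'strict'`` drops zero
    emissions before taking logs.
    """
    if isinstance(covariates, str):
        covariates = COVARIATE_PRESETS[covariates]
    covariates = list(covariates)
    df = panel.merge(assignments[["firm_id", "buffer"]], on="firm_id")
    n_far = int(df["buffer"].isna().sum())
    df = df.dropna(subset=["buffer"]).copy()
    if df.empty:
        raise ValueError("empty sample: every firm is beyond the outer ring")

    p = df[pollutant].to_numpy(dtype=float)
    if zero_rule == "log1p":
        df["_lnp"] = np.log1p(p)
    elif zero_rule == "strict":
        df = df[p > 0].copy()
        df["_lnp"] = np.log(df[pollutant].to_numpy(dtype=float))
    else:
        raise ValueError("zero_rule must be 'log1p' or 'strict'")

    fyp10 = set(fyp10_years)
    df["buffer_x_k10"] = df["buffer"] * df["year"].isin(fyp10)
    df["buffer_x_k11"] = df["buffer"] * (df["year"] >= fyp11_start)

    # exact-duplicate covariates: drop with a report, keep the first
    dup_dropped = []
    kept = []
    for c in covariates:
        if any(np.array_equal(df[c].to_numpy(), df[k].to_numpy())
               for k in kept):
            dup_dropped.append(c)
        else:
            kept.append(c)
    xcols = ["buffer", "buffer_x_k10", "buffer_x_k11"] + kept
    res = fit_ols_fe(df, "_lnp", xcols, fe_factors=["industry", "year"],
                     se_type=se_type, cluster=cluster)
    return FirmRegressionOutput(result=res, outcome=f"ln_{pollutant}",
                                zero_rule=zero_rule, n_excluded_far=n_far,
                                duplicate_dropped=dup_dropped)
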