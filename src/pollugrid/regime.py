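"""Grid-panel trend regressions across Five-Year-Plan regimes.

For each pollutant index and plan window (10th FYP 2001-2005, 11th FYP
2006-2010) the model is

    Index_it = a + b1 year_t x east_i + b2 year_t + X_kt G + cell FE + e_it

estimated by OLS with cell fixed effects and CR1 standard errors clustered
at the cell level.  ``year`` enters centered at the window start (changes
only the intercept).  ``regime_contrast`` compares the two windows' trend
and interaction terms and flags a regime shift when the trend changes sign
significantly between the plans.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .regression import RegressionResult, fit_ols_fe

__all__ = ["RegimeWindow", "FYP10", "FYP11", "fit_grid_panel_regression",
           "regime_contrast"]

DEFAULT_CONTROLS = ["gdppc", "secondary", "tertiary", "urbanrate"]


@dataclass(frozen=True)
class RegimeWindow:
    label: str
    year_start: int
    year_end: int

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ValueError("empty window")

    @property
    def years(self):
        return range(self.year_start, self.year_end + 1)


FYP10 = RegimeWindow("FYP10", 2001, 2005)
FYP11 = RegimeWindow("FYP11", 2006, 2010)


@dataclass
class RegimeFit:
    result: RegressionResult
    pollutant: str
    window: RegimeWindow
    interaction_dropped: bool


def fit_grid_panel_regression(panel: pd.DataFrame, pollutant: str,
                              window: RegimeWindow, with_interaction=True,
                              controls=None,
                              se_type="cluster") -> RegimeFit:
    """Cell-FE trend regression of a pollutant index over one plan window.

    ``panel`` columns: cell_id, year, east, the pollutant index column, and
    the control covariates.  The east main effect is absorbed by the cell
    fixed effects; only the year x east interaction is estimable.  When east
    does not vary across cells the interaction is dropped with a report.
    """
    controls = DEFAULT_CONTROLS if controls is None else list(controls)
    df = panel[(panel["year"] >= window.year_start)
               & (panel["year"] <= window.year_end)].copy()
    if df["year"].nunique() < 2:
        raise ValueError("trend unidentified: window has a single year")
    if df["cell_id"].nunique() < 2:
        raise ValueError("need at least two cells")
    df["year_c"] = df["year"] - window.year_start
    xcols = ["year_c"]
    interaction_dropped = False
    if with_interaction:
        if df.groupby("cell_id")["east"].first().nunique() < 2:
            interaction_dropped = True
        else:
            df["year_c_x_east"] = df["year_c"] * df["east"]
            xcols.append("year_c_x_east")
    xcols += [c for c in controls if c in df.columns]
    res = fit_ols_fe(df, pollutant, xcols, fe_factors=["cell_id"],
                     se_type=se_type,
                     cluster="cell_id" if se_type == "cluster" else None)
    return RegimeFit(result=res, pollutant=pollutant, window=window,
                     interaction_dropped=interaction_dropped)


def regime_contrast(fit_pre: RegimeFit, fit_post: RegimeFit,
                    alpha=0.05) -> dict:
    """Compare trend and interaction terms across the two plan windows.

    A "regime shift" is flagged when the year-trend coefficient is
    significant in both windows with opposite signs; the interaction's sign
    flip is reported separately when present in both fits.
    """
    if fit_pre.pollutant != fit_post.pollutant:
        raise ValueError(
            f"pollutant mismatch: {fit_pre.pollutant!r} vs "
            f"{fit_post.pollutant!r}")

    def term(fit, name):
        r = fit.result
        if name not in r.params.index:
            return None
        import numpy as np
        return {"coef": float(r.params[name]), "p": float(r.pvalues[name]),
                "sign": int(np.sign(r.params[name]))}

    out = {"pollutant": fit_pre.pollutant,
           "windows": (fit_pre.window.label, fit_post.window.label)}
    for name, key in (("year_c", "year"), ("year_c_x_east", "interaction")):
        pre, post = term(fit_pre, name), term(fit_post, name)
        out[key] = {"pre": pre, "post": post}
        if pre and post:
            out[key]["sign_flip"] = (pre["sign"] != 0 and post["sign"] != 0
                                     and pre["sign"] != post["sign"])
            out[key]["both_significant"] = (pre["p"] <= alpha
                                            and post["p"] <= alpha)
        else:
            out[key]["sign_flip"] = False
            out[key]["both_significant"] = False
    out["regime_shift"] = bool(out["year"]["sign_flip"]
                               and out["year"]["both_significant"])
    return out
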