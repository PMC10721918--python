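"""Fixed-effects OLS with plain or cluster-robust (CR1) standard errors.

The estimator is ordinary least squares with fixed-effect factors entered as
dummy sets (first level dropped per factor, single intercept kept), fitted
through statsmodels.  Collinear columns among the named covariates are
detected by pivoted QR and dropped with a report.  Cluster-robust covariance
is the CR1 sandwich with finite-sample factor G/(G-1) * (n-1)/(n-k), the
convention behind "clustered at the grid level" tables in applied work.

``fit_within`` re-estimates the slopes by iterated demeaning over the FE
factors (Frisch-Waugh); it must agree with the dummy estimator to numerical
precision and exists as an internal consistency check and for very
high-dimensional FE sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

__all__ = ["RegressionResult", "fit_ols_fe", "fit_within", "format_table"]


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    nobs: int
    df_resid: int
    se_type: str
    fe_factors: list
    dropped: list = field(default_factory=list)

    def conf_int(self, alpha=0.05) -> pd.DataFrame:
        from scipy.stats import t as tdist
        q = tdist.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame({"low": self.params - q * self.bse,
                             "high": self.params + q * self.bse})

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.params.index,
                             "coef": self.params.to_numpy(),
                             "se": self.bse.to_numpy(),
                             "t": self.tvalues.to_numpy(),
                             "p": self.pvalues.to_numpy()})


def _dummies(df: pd.DataFrame, factors) -> pd.DataFrame:
    parts = []
    for f in factors:
        lv = df[f].astype("category")
        if lv.cat.categories.size < 2:
            raise ValueError(f"fixed-effect factor {f!r} has < 2 levels")
        d = pd.get_dummies(lv, prefix=f, drop_first=True, dtype=float)
        parts.append(d)
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)


def _drop_collinear(X: pd.DataFrame, protect: int):
    """Pivoted-QR pruning; columns past the numerical rank are dropped.

    ``protect`` marks how many leading columns (intercept) must survive.
    """
    A = X.to_numpy(dtype=float)
    if A.shape[1] == 0:
        return X, []
    _, R, piv = scipy.linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [X.columns[i] for i in sorted(piv[rank:])]
    for i in range(protect):
        if i not in keep:
            raise ValueError("intercept column unexpectedly collinear")
    return X.iloc[:, keep], dropped


def fit_ols_fe(df: pd.DataFrame, y: str, xcols, fe_factors=(),
               se_type="plain", cluster=None) -> RegressionResult:
    """OLS of ``y`` on ``xcols`` plus dummy sets for ``fe_factors``.

    Rows with any NaN among the used columns are dropped (listwise deletion).
    Perfect collinearity among the named covariates raises, naming the
    columns; collinear FE dummies are silently pruned and reported in
    ``dropped``.
    """
    xcols = list(xcols)
    fe_factors = list(fe_factors)
    use = [y] + xcols + fe_factors + ([cluster] if cluster else [])
    data = df[list(dict.fromkeys(use))].dropna()
    if data.empty:
        raise ValueError("empty sample after listwise deletion")

    X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
    for c in xcols:
        X[c] = data[c].astype(float)
    _, named_dropped = _drop_collinear(X, protect=1)
    named_dropped = [c for c in named_dropped if c in xcols]
    if named_dropped:
        raise ValueError(f"perfectly collinear covariates: {named_dropped}")
    X = pd.concat([X, _dummies(data, fe_factors)], axis=1)
    X, dropped = _drop_collinear(X, protect=1)

    if se_type == "cluster":
        if cluster is None:
            raise ValueError("cluster factor required for clustered SEs")
        groups = data[cluster]
        res = sm.OLS(data[y].to_numpy(dtype=float), X).fit(
            cov_type="cluster",
            cov_kwds={"groups": groups.to_numpy()})
    elif se_type == "plain":
        res = sm.OLS(data[y].to_numpy(dtype=float), X).fit()
    else:
        raise ValueError("se_type must be 'plain' or 'cluster'")

    return RegressionResult(
        params=res.params, bse=res.bse, tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared), nobs=int(res.nobs),
        df_resid=int(res.df_resid), se_type=se_type,
        fe_factors=fe_factors, dropped=dropped)


def fit_within(df: pd.DataFrame, y: str, xcols, fe_factors,
               tol=1e-12, max_iter=200) -> pd.Series:
    """Slopes via iterated group-demeaning over the FE factors.

    Alternating projections onto the within-spaces of each factor converge to
    the joint projection; slope estimates equal the dummy-variable OLS up to
    numerical precision.  Returns only the slope coefficients.
    """
    xcols = list(xcols)
    data = df[list(dict.fromkeys([y] + xcols + list(fe_factors)))].dropna()
    M = data[[y] + xcols].to_numpy(dtype=float).copy()
    codes = [pd.factorize(data[f])[0] for f in fe_factors]
    M -= M.mean(axis=0)
    for _ in range(max_iter):
        delta = 0.0
        for code in codes:
            gm = np.zeros((code.max() + 1, M.shape[1]))
            cnt = np.bincount(code).astype(float)
            np.add.at(gm, code, M)
            gm /= cnt[:, None]
            M -= gm[code]
            delta = max(delta, float(np.abs(gm).max()))
        if delta < tol:
            break
    yv, Xv = M[:, 0], M[:, 1:]
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    return pd.Series(beta, index=xcols)


_STARS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


def format_table(results: dict, title="") -> str:
    """Journal-style text table: one column per fitted model.

    Stars follow the usual convention: *** p<0.01, ** p<0.05, * p<0.1.
    """
    terms = []
    for res in results.values():
        for t in res.params.index:
            if not any(t.startswith(f + "_") for f in res.fe_factors):
                if t not in terms:
                    terms.append(t)
    lines = [title, "=" * 72] if title else []
    header = f"{'':24s}" + "".join(f"{name:>16s}" for name in results)
    lines += [header, "-" * len(header)]
    for t in terms:
        coefs, ses = f"{t:24s}", f"{'':24s}"
        for res in results.values():
            if t in res.params.index:
                star = next((s for cut, s in _STARS
                             if res.pvalues[t] < cut), "")
                coefs += f"{res.params[t]:13.4f}{star:<3s}"
                ses += f"({res.bse[t]:.4f})".rjust(13) + "   "
            else:
                coefs += f"{'':16s}"
                ses += f"{'':16s}"
        lines += [coefs, ses]
    for f in {f for r in results.values() for f in r.fe_factors}:
        lines.append(f"{f + ' FE':24s}" + "".join(
            f"{'Yes' if f in r.fe_factors else 'No':>16s}"
            for r in results.values()))
    lines.append(f"{'Observations':24s}" + "".join(
        f"{r.nobs:>16,d}" for r in results.values()))
    lines.append(f"{'R-squared':24s}" + "".join(
        f"{r.r2:>16.3f}" for r in results.values()))
    lines.append("*** p<0.01; ** p<0.05; * p<0.1")
    return "\n".join(lines)
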