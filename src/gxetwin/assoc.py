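"""Between-family, within-family and MZ-difference association tests.

All predictors and outcomes are z-standardized on the analysis sample before
fitting, so the reported beta from a covariate-free model is the Pearson
correlation.  The within-family model is the fixed-effects regression

    Y_ij = alpha_j + beta * x_ij + e_ij

with one intercept per family; it is estimated on within-family
mean-deviations, which is algebraically identical to the dummy-variable
regression, and degrees of freedom / model adjusted R^2 count every family
intercept as a parameter.  The MZ-discordance design regresses within-pair
differences of the outcome on within-pair differences of the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["AssociationResult", "standardized_ols",
           "fixed_effects_within_family", "mz_difference_regression",
           "DegenerateVarianceError", "InsufficientDataError"]


class DegenerateVarianceError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class AssociationResult:
    beta: float
    t: float
    df: int
    p: float
    r2: float
    n: int
    adj_r2_model: float | None = None
    model: str = "ols"

    def as_row(self) -> dict:
        return {"model": self.model, "beta": self.beta, "t": self.t,
                "df": self.df, "p": self.p, "r2": self.r2,
                "adj_r2_model": self.adj_r2_model, "n": self.n}


def _zscore(x) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd < 1e-12:
        raise DegenerateVarianceError("variable has (near-)zero variance")
    return (x - x.mean()) / sd


def standardized_ols(y, x, covariates=None) -> AssociationResult:
    """OLS of z-scored y on z-scored x (+ covariates), incremental R^2 for x."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    ok = np.isfinite(y) & np.isfinite(x)
    if C is not None:
        ok &= np.isfinite(C).all(axis=1)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError("need at least 3 complete cases")
    yz, xz = _zscore(y[ok]), _zscore(x[ok])
    X = sm.add_constant(xz if C is None else np.column_stack([xz, C[ok]]))
    fit = sm.OLS(yz, X).fit()
    r2_x = fit.rsquared
    if C is not None:
        base = sm.OLS(yz, sm.add_constant(C[ok])).fit()
        r2_x = fit.rsquared - base.rsquared
    return AssociationResult(
        beta=float(fit.params[1]), t=float(fit.tvalues[1]),
        df=int(fit.df_resid), p=float(fit.pvalues[1]), r2=float(r2_x),
        n=n, adj_r2_model=float(fit.rsquared_adj), model="ols")


def fixed_effects_within_family(y, x, family_ids) -> AssociationResult:
    """Family fixed-effects slope via within-family demeaning.

    Families with any missing value are dropped whole; variables are
    z-scored on the retained analysis sample first, so the beta is
    comparable with the between-family standardized beta.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    fam = pd.Series(np.asarray(family_ids))
    ok_row = np.isfinite(y) & np.isfinite(x)
    bad_fams = set(fam[~ok_row])
    keep = ok_row & ~fam.isin(bad_fams).to_numpy()
    fam = fam[keep]
    k = fam.nunique()
    if k < 2:
        raise InsufficientDataError("need at least 2 complete families")
    yz, xz = _zscore(y[keep]), _zscore(x[keep])
    n = yz.size

    codes = fam.astype("category").cat.codes.to_numpy()
    counts = np.bincount(codes)
    ydm = yz - (np.bincount(codes, weights=yz) / counts)[codes]
    xdm = xz - (np.bincount(codes, weights=xz) / counts)[codes]
    sxx = float(xdm @ xdm)
    if sxx < 1e-12:
        raise DegenerateVarianceError(
            "predictor has zero within-family variance")
    beta = float(xdm @ ydm) / sxx
    resid = ydm - beta * xdm
    df = n - k - 1
    if df < 1:
        raise InsufficientDataError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    tss = float(yz @ yz)  # yz has mean 0
    rss = float(resid @ resid)
    r2_model = 1.0 - rss / tss
    n_params = k + 1  # family intercepts + slope
    adj_r2 = 1.0 - (1.0 - r2_model) * (n - 1) / (n - n_params)
    # variance uniquely explained by x beyond the family intercepts
    r2_x = (float(xdm @ ydm) ** 2 / sxx) / tss
    return AssociationResult(beta=beta, t=float(t), df=int(df), p=float(p),
                             r2=float(r2_x), n=n, adj_r2_model=float(adj_r2),
                             model="fixed_effects")


def mz_difference_regression(trait_outcome, trait_predictor,
                             pair_index) -> AssociationResult:
    """Regression of within-MZ-pair outcome differences on predictor
    differences (twin 1 minus twin 2), standardized OLS on the pair level."""
    d_out, d_pred = [], []
    out = np.asarray(trait_outcome, float)
    pred = np.asarray(trait_predictor, float)
    pairs = pd.Series(np.asarray(pair_index))
    for _, idx in pairs.groupby(pairs).groups.items():
        if len(idx) != 2:
            continue
        i, j = idx[0], idx[1]
        d_out.append(out[i] - out[j])
        d_pred.append(pred[i] - pred[j])
    d_out = np.asarray(d_out)
    d_pred = np.asarray(d_pred)
    okm = np.isfinite(d_out) & np.isfinite(d_pred)
    if okm.sum() < 3:
        raise InsufficientDataError("need at least 3 complete MZ pairs")
    res = standardized_ols(d_out[okm], d_pred[okm])
    res.model = "mz_difference"
    return res
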