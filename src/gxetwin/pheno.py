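"""Phenotype construction: BMI-SDS, exclusions, composites, residualization.

The analysis variables are built in four steps, mirroring standard practice
in paediatric-anthropometry cohorts:

1. child BMI = weight / height^2 is standardized to BMI-SDS against an
   external LMS growth reference (age- and sex-specific);
2. implausible anthropometric values are flagged and excluded (reference-SDS
   beyond +/-5, height outside 105-180 cm, weight outside 12-80 kg); the
   reporting parent's BMI is log-transformed, and set missing below 35 kg or
   beyond +/-3.5 SD of log-BMI;
3. questionnaire scales are scored as the mean of their 5-point Likert items
   (restriction: 6 items, pressure: 4 items), with a minimum-items rule;
4. every analysis variable is regressed on age and sex and replaced by its
   z-standardized residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lms import LmsReference, lms_zscore

__all__ = [
    "CleanPhenotypes",
    "apply_exclusions",
    "composite_score",
    "cronbach_alpha",
    "residualize_standardize",
    "prepare_phenotypes",
]

RESTRICTION_ITEMS = [f"rest_{i}" for i in range(1, 7)]
PRESSURE_ITEMS = [f"press_{i}" for i in range(1, 5)]

CHILD_SDS_LIMIT = 5.0
HEIGHT_CM_RANGE = (105.0, 180.0)
WEIGHT_KG_RANGE = (12.0, 80.0)
PARENT_WEIGHT_MIN_KG = 35.0
PARENT_LOGBMI_SD_LIMIT = 3.5


class SchemaError(KeyError):
    """A required phenotype column is absent."""


class DegenerateVarianceError(ValueError):
    """A variable has (numerically) zero variance where variation is required."""


@dataclass
class CleanPhenotypes:
    """Per-individual analysis variables plus exclusion bookkeeping.

    ``data`` holds one row per individual with identifier/zygosity columns and
    the z-standardized residuals ``bmi_sds``, ``restriction``, ``pressure``,
    ``parent_bmi``; flagged individuals carry NaN in the affected columns.
    ``exclusions`` maps individual_id -> list of reason codes.
    """

    data: pd.DataFrame
    exclusions: pd.DataFrame  # columns: individual_id, reason_code

    def exclusion_report(self, path=None) -> pd.DataFrame:
        if path is not None:
            self.exclusions.to_csv(path, index=False)
        return self.exclusions


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")


def apply_exclusions(table: pd.DataFrame, ref: LmsReference,
                     use_reference_sds: bool = True) -> pd.DataFrame:
    """Flag implausible child anthropometrics and clean parent BMI.

    Returns a copy of ``table`` with added columns ``height_sds``,
    ``weight_sds``, ``bmi``, ``bmi_sds_raw``, ``parent_log_bmi`` (cleaned,
    NaN where excluded), ``child_excluded`` (bool) and ``exclusion_reasons``
    (';'-joined machine-readable codes).

    ``use_reference_sds=False`` falls back to sample z-scores for the +/-5 SD
    rule on height and weight (also the automatic behaviour when the
    reference lacks height/weight rows).
    """
    _require(table, ["individual_id", "sex", "age_years", "height_cm", "weight_kg"])
    out = table.copy()
    age = out["age_years"].to_numpy(float)
    sex = out["sex"].to_numpy(object)
    height = out["height_cm"].to_numpy(float)
    weight = out["weight_kg"].to_numpy(float)
    bmi = weight / (height / 100.0) ** 2
    out["bmi"] = bmi

    ok = np.isfinite(age) & np.isfinite(height) & np.isfinite(weight)

    def _sds(values, measure):
        z = np.full(values.shape, np.nan)
        if use_reference_sds and measure in ref.measures:
            z[ok] = lms_zscore(values[ok], age[ok], sex[ok], ref, measure)
        else:
            mu, sd = np.nanmean(values), np.nanstd(values, ddof=1)
            z = (values - mu) / sd
        return z

    out["height_sds"] = _sds(height, "height")
    out["weight_sds"] = _sds(weight, "weight")
    out["bmi_sds_raw"] = _sds(bmi, "bmi")

    reasons = [[] for _ in range(len(out))]
    rules = [
        (height < HEIGHT_CM_RANGE[0], "height_below_min"),
        (height > HEIGHT_CM_RANGE[1], "height_above_max"),
        (weight < WEIGHT_KG_RANGE[0], "weight_below_min"),
        (weight > WEIGHT_KG_RANGE[1], "weight_above_max"),
        (np.abs(out["height_sds"].to_numpy()) > CHILD_SDS_LIMIT, "height_sds_extreme"),
        (np.abs(out["weight_sds"].to_numpy()) > CHILD_SDS_LIMIT, "weight_sds_extreme"),
        (np.abs(out["bmi_sds_raw"].to_numpy()) > CHILD_SDS_LIMIT, "bmi_sds_extreme"),
    ]
    for mask, code in rules:
        mask = np.asarray(mask) & ok
        for i in np.flatnonzero(mask):
            reasons[i].append(code)
    excluded = np.array([len(r) > 0 for r in reasons])
    out["child_excluded"] = excluded
    out["exclusion_reasons"] = [";".join(r) for r in reasons]
    out.loc[excluded, ["height_sds", "weight_sds", "bmi_sds_raw"]] = np.nan

    # reporting-parent BMI: log transform, remove < 35 kg and +/-3.5 SD outliers
    if {"parent_height_cm", "parent_weight_kg"}.issubset(out.columns):
        ph = out["parent_height_cm"].to_numpy(float)
        pw = out["parent_weight_kg"].to_numpy(float)
        pbmi = pw / (ph / 100.0) ** 2
        log_bmi = np.log(pbmi)
        low = pw < PARENT_WEIGHT_MIN_KG
        log_bmi[low] = np.nan
        mu, sd = np.nanmean(log_bmi), np.nanstd(log_bmi, ddof=1)
        outlier = np.abs(log_bmi - mu) > PARENT_LOGBMI_SD_LIMIT * sd
        log_bmi[outlier] = np.nan
        out["parent_log_bmi"] = log_bmi
        for i in np.flatnonzero(low):
            reasons[i].append("parent_weight_below_min")
        for i in np.flatnonzero(outlier & ~low):
            reasons[i].append("parent_log_bmi_extreme")
        out["exclusion_reasons"] = [";".join(r) for r in reasons]
    return out


def apply_exclusions_clean(table, ref, **kw):
    """Idempotent form: applying exclusions twice flags the same rows."""
    return apply_exclusions(table, ref, **kw)


def composite_score(items: pd.DataFrame, min_items: int) -> pd.Series:
    """Mean of non-missing Likert items, missing when too few are answered."""
    values = items.to_numpy(float)
    finite = np.isfinite(values)
    bad = finite & ((values < 1) | (values > 5))
    if bad.any():
        raise ValueError("item responses must lie in 1..5")
    n_obs = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        score = np.nanmean(np.where(finite, values, np.nan), axis=1)
    score[n_obs < min_items] = np.nan
    return pd.Series(score, index=items.index)


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha over complete rows: (k/(k-1)) (1 - sum var_i / var_total)."""
    values = items.to_numpy(float)
    values = values[np.isfinite(values).all(axis=1)]
    n, k = values.shape
    if k < 2 or n < 3:
        raise ValueError("need >=2 items and >=3 complete rows")
    total = values.sum(axis=1)
    var_total = total.var(ddof=1)
    if var_total <= 0:
        raise DegenerateVarianceError("zero variance of the item sum")
    item_vars = values.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / var_total))


def residualize_standardize(values, covariates=None) -> np.ndarray:
    """OLS residuals of ``values`` on covariates (with intercept), z-scored.

    ``covariates`` is a 2-D array / DataFrame or None; rows with any missing
    value stay NaN in the output and do not enter the fit or the scaling.
    """
    y = np.asarray(values, float).copy()
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if ok.sum() < X.shape[1] + 1:
        raise ValueError("too few complete cases for residualization")
    beta, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = np.full(n, np.nan)
    resid[ok] = y[ok] - X[ok] @ beta
    sd = np.std(resid[ok], ddof=1)
    if not np.isfinite(sd) or sd < 1e-12:
        raise DegenerateVarianceError("residuals have (near-)zero variance")
    resid[ok] = (resid[ok] - resid[ok].mean()) / np.std(resid[ok], ddof=0)
    return resid


def _sex_indicator(sex) -> np.ndarray:
    return (np.asarray(sex, object) == "F").astype(float)


def prepare_phenotypes(table: pd.DataFrame, ref: LmsReference,
                       min_items_restriction: int = 4,
                       min_items_pressure: int = 3,
                       use_reference_sds: bool = True) -> CleanPhenotypes:
    """Full preparation: exclusions, composites, age/sex residualization.

    Produces z-standardized analysis variables ``bmi_sds``, ``restriction``,
    ``pressure`` (age/sex-residualized) and ``parent_bmi`` (log-BMI
    residualized on the reporting parent's sex, i.e. gender-corrected).
    """
    flagged = apply_exclusions(table, ref, use_reference_sds=use_reference_sds)
    covars = np.column_stack([
        flagged["age_years"].to_numpy(float),
        _sex_indicator(flagged["sex"]),
    ])

    data = flagged[[c for c in ("family_id", "individual_id", "zygosity",
                                "sex", "twin_order") if c in flagged.columns]].copy()
    data["bmi_sds"] = residualize_standardize(flagged["bmi_sds_raw"], covars)

    for name, cols, min_items in (
        ("restriction", RESTRICTION_ITEMS, min_items_restriction),
        ("pressure", PRESSURE_ITEMS, min_items_pressure),
    ):
        if set(cols).issubset(flagged.columns):
            raw = composite_score(flagged[cols], min_items=min_items)
            data[name] = residualize_standardize(raw, covars)

    if "parent_log_bmi" in flagged.columns and "parent_sex" in flagged.columns:
        data["parent_bmi"] = residualize_standardize(
            flagged["parent_log_bmi"], _sex_indicator(flagged["parent_sex"])[:, None]
        )

    reasons = []
    for iid, rs in zip(flagged["individual_id"], flagged["exclusion_reasons"]):
        for code in filter(None, rs.split(";")):
            reasons.append((iid, code))
    exclusions = pd.DataFrame(reasons, columns=["individual_id", "reason_code"])
    return CleanPhenotypes(data=data, exclusions=exclusions)
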