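"""LMS growth-reference transforms.

Anthropometric measurements in children are standardized against an external
age- and sex-specific growth reference using the LMS method: each reference
row carries a Box-Cox power (L), a median (M) and a coefficient of variation
(S), and a measurement ``y`` maps to a standard deviation score

    z = ((y / M)**L - 1) / (L * S)        for L != 0
    z = ln(y / M) / S                     for L == 0

The reference is supplied as a table with columns ``sex`` (M/F),
``age_years``, ``L``, ``M``, ``S`` and optionally a leading ``measure``
column (``bmi``, ``height``, ``weight``) when one file carries references
for several measurements.  L, M and S are linearly interpolated between the
bracketing reference ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LmsReference", "lms_zscore", "lms_inverse", "synthetic_lms_reference"]

_L_EPS = 1e-7  # below this |L| the log branch is used (continuous limit)


class LmsRangeError(ValueError):
    """Requested age falls outside the reference table's age span."""


@dataclass
class LmsReference:
    """Age/sex lookup table of L, M, S parameters for one or more measures."""

    table: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        if "measure" not in t.columns:
            t.insert(0, "measure", "bmi")
        required = {"measure", "sex", "age_years", "L", "M", "S"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"LMS reference missing columns: {sorted(missing)}")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("LMS reference requires M > 0 and S > 0")
        self.table = t
        for (measure, sex), grp in t.groupby(["measure", "sex"]):
            grp = grp.sort_values("age_years")
            ages = grp["age_years"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(
                    f"ages must be strictly increasing for measure={measure}, sex={sex}"
                )
            self._index[(measure, sex)] = (
                ages,
                grp[["L", "M", "S"]].to_numpy(float),
            )

    @property
    def measures(self) -> set:
        return set(self.table["measure"].unique())

    def lookup(self, age: np.ndarray, sex: np.ndarray, measure: str = "bmi"):
        """Interpolated (L, M, S) arrays for the requested ages and sexes."""
        age = np.asarray(age, float)
        sex = np.asarray(sex, object)
        out = np.empty((age.size, 3), float)
        for s in np.unique(sex):
            key = (measure, s)
            if key not in self._index:
                raise LmsRangeError(f"no reference rows for measure={measure}, sex={s}")
            ages, lms = self._index[key]
            sel = sex == s
            a = age[sel]
            if np.any(a < ages[0]) or np.any(a > ages[-1]):
                raise LmsRangeError(
                    f"age outside reference range [{ages[0]}, {ages[-1]}] "
                    f"for measure={measure}, sex={s}"
                )
            for j in range(3):
                out[sel, j] = np.interp(a, ages, lms[:, j])
        return out[:, 0], out[:, 1], out[:, 2]

    @classmethod
    def from_csv(cls, path) -> "LmsReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def lms_zscore(value, age, sex, ref: LmsReference, measure: str = "bmi"):
    """SDS of ``value`` against the reference; scalar in, scalar out."""
    scalar = np.isscalar(value) or np.ndim(value) == 0
    value = np.atleast_1d(np.asarray(value, float))
    age = np.atleast_1d(np.asarray(age, float))
    sex = np.atleast_1d(np.asarray(sex, object))
    if np.any(value[np.isfinite(value)] <= 0):
        raise ValueError("measurements must be positive")
    age_b, sex_b = np.broadcast_arrays(age, sex)
    if age_b.size != value.size:
        age_b = np.broadcast_to(age_b, value.shape)
        sex_b = np.broadcast_to(sex_b, value.shape)
    L, M, S = ref.lookup(age_b, sex_b, measure)
    with np.errstate(invalid="ignore"):
        z = np.where(
            np.abs(L) > _L_EPS,
            ((value / M) ** L - 1.0) / (L * S),
            np.log(value / M) / S,
        )
    return float(z[0]) if scalar else z


def lms_inverse(z, age, sex, ref: LmsReference, measure: str = "bmi"):
    """Back-transform an SDS to the raw measurement scale (inverse of lms_zscore)."""
    scalar = np.isscalar(z) or np.ndim(z) == 0
    z = np.atleast_1d(np.asarray(z, float))
    age = np.broadcast_to(np.atleast_1d(np.asarray(age, float)), z.shape)
    sex = np.broadcast_to(np.atleast_1d(np.asarray(sex, object)), z.shape)
    L, M, S = ref.lookup(age, sex, measure)
    with np.errstate(invalid="ignore"):
        y = np.where(
            np.abs(L) > _L_EPS,
            M * (1.0 + L * S * z) ** (1.0 / np.where(np.abs(L) > _L_EPS, L, 1.0)),
            M * np.exp(S * z),
        )
    return float(y[0]) if scalar else y


def synthetic_lms_reference(age_min: float = 7.0, age_max: float = 13.0,
                            step: float = 0.25) -> LmsReference:
    """A smooth synthetic reference for BMI, height and weight in late childhood.

    Shapes loosely follow published childhood growth curves (BMI median rising
    ~0.35 kg/m^2 per year around age 10, mild negative skew captured by L < 0);
    the values are synthetic and serve only to give the simulation a realistic
    raw-measurement scale that round-trips exactly through the SDS transform.
    """
    rows = []
    ages = np.arange(age_min, age_max + 1e-9, step)
    for sex in ("M", "F"):
        for a in ages:
            rows.append(("bmi", sex, round(float(a), 4),
                         -1.6 if sex == "M" else -1.4,
                         16.0 + 0.35 * (a - 10.0) + (0.0 if sex == "M" else 0.3),
                         0.105 if sex == "M" else 0.115))
            rows.append(("height", sex, round(float(a), 4),
                         1.0,
                         138.0 + 5.6 * (a - 10.0) + (0.5 if sex == "M" else 0.0),
                         0.045))
            rows.append(("weight", sex, round(float(a), 4),
                         -0.6,
                         32.0 + 3.2 * (a - 10.0) + (0.3 if sex == "M" else 0.0),
                         0.16))
    table = pd.DataFrame(rows, columns=["measure", "sex", "age_years", "L", "M", "S"])
    return LmsReference(table)
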