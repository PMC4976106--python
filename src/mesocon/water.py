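"""Leaf water status, intrinsic WUE, group summaries and empirical fits.

Relative water content is RWC = 100*(FW - DW)/(TW - DW) from fresh, turgid
and dry leaf-disc masses, binned into the drought classes

    WW (well-watered)  RWC in [80, 100]
    MS (mild stress)   RWC in [60, 80)
    SS (severe stress) RWC in [40, 60)

with boundary values assigned to the wetter class and RWC < 40 flagged as
out of range.  Intrinsic water-use efficiency is WUEi = A_N/gs (umol CO2
per mol H2O).

``group_summary`` produces the per-class/per-genotype means, dispersions,
coefficients of variation and between-class fold changes of the campaign
variables; ``EmpiricalRegression`` fits the empirical families used for the
conductance relations (quadratic, through-origin cubic, logarithmic).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class StressClass(str, enum.Enum):
    WW = "WW"
    MS = "MS"
    SS = "SS"
    OUT_OF_RANGE = "OUT_OF_RANGE"


@dataclass(frozen=True)
class LeafWaterSample:
    """Fresh, turgid and dry masses (g) of one leaf disc."""

    FW: float
    TW: float
    DW: float

    def __post_init__(self) -> None:
        if not (self.TW >= self.FW >= self.DW > 0):
            raise ValueError("mass ordering TW >= FW >= DW > 0 violated")


def rwc(sample: LeafWaterSample) -> float:
    """Relative water content in percent."""
    denom = sample.TW - sample.DW
    if denom == 0:
        raise ValueError("degenerate sample: TW == DW")
    return 100.0 * (sample.FW - sample.DW) / denom


def classify(rwc_percent) -> StressClass:
    """Drought class from RWC; boundary ties go to the wetter class."""
    r = float(rwc_percent)
    if 80.0 <= r <= 100.0:
        return StressClass.WW
    if 60.0 <= r < 80.0:
        return StressClass.MS
    if 40.0 <= r < 60.0:
        return StressClass.SS
    return StressClass.OUT_OF_RANGE


def classify_series(rwc_values) -> pd.Series:
    return pd.Series([classify(v).value for v in np.asarray(rwc_values)])


def wue_intrinsic(An, gs_h2o):
    """Intrinsic water-use efficiency A_N/gs (umol CO2 mol-1 H2O)."""
    gs = np.asarray(gs_h2o, dtype=float)
    if np.any(gs <= 0):
        raise ValueError("gs_h2o must be > 0")
    out = np.asarray(An, dtype=float) / gs
    return float(out) if out.ndim == 0 else out


def group_summary(records: pd.DataFrame, variables,
                  by=("stress_class",), cv_basis: str = "sd") -> pd.DataFrame:
    """Means, dispersions, c.v. and fold changes by stress class.

    cv_basis selects the dispersion entering the c.v.: "sd" (standard
    deviation, the conventional coefficient of variation) or "se" (standard
    error of the mean).  Cells with fewer than 2 observations are reported
    with missing statistics, never imputed.
    """
    if cv_basis not in ("sd", "se"):
        raise ValueError("cv_basis must be 'sd' or 'se'")
    by = list(by)
    rows = []
    for keys, grp in records.groupby(by, observed=True, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for var in variables:
            vals = grp[var].dropna().to_numpy(dtype=float)
            base = dict(zip(by, keys)) | {"variable": var, "n": int(vals.size)}
            if vals.size < 2:
                rows.append(base | {"mean": np.nan, "dispersion": np.nan,
                                    "cv": np.nan})
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            disp = sd if cv_basis == "sd" else sd / np.sqrt(vals.size)
            rows.append(base | {
                "mean": mean, "dispersion": disp,
                "cv": disp / mean if mean != 0 else np.nan,
            })
    return pd.DataFrame(rows)


def cv_from_summary(mean: float, dispersion: float) -> float:
    """Coefficient of variation recomputed from a printed mean/dispersion
    summary row (dispersion/mean)."""
    return dispersion / mean


def fold_change(mean_from: float, mean_to: float) -> float:
    """Fold reduction between class means (WW mean / stressed mean)."""
    return mean_from / mean_to


def class_fold_changes(summary: pd.DataFrame,
                       variable: str) -> dict:
    """WW->MS and WW->SS fold ratios of class means from a group_summary
    frame indexed by stress_class."""
    sub = summary[summary["variable"] == variable].set_index("stress_class")
    out = {}
    for target in ("MS", "SS"):
        if "WW" in sub.index and target in sub.index:
            out[f"WW_to_{target}"] = fold_change(
                sub.loc["WW", "mean"], sub.loc[target, "mean"])
    return out


_FAMILIES = ("polynomial2", "polynomial3_through_origin", "logarithmic")


class EmpiricalRegression(RegressorMixin, BaseEstimator):
    """Least-squares fit of an empirical x-y family.

    family : {"polynomial2", "polynomial3_through_origin", "logarithmic"}
        polynomial2                : y = c0 + c1*x + c2*x^2
        polynomial3_through_origin : y = c1*x + c2*x^2 + c3*x^3
        logarithmic                : y = c0 + c1*ln(x)

    coef_ holds the coefficients in the order written above; r_squared_ is
    computed against the family-appropriate null (the mean for families with
    an intercept, zero for the through-origin family).
    """

    def __init__(self, family: str = "polynomial2"):
        self.family = family

    def _design(self, x):
        if self.family == "polynomial2":
            return np.column_stack([np.ones_like(x), x, x ** 2])
        if self.family == "polynomial3_through_origin":
            return np.column_stack([x, x ** 2, x ** 3])
        if self.family == "logarithmic":
            if np.any(x <= 0):
                raise ValueError("logarithmic family needs x > 0")
            return np.column_stack([np.ones_like(x), np.log(x)])
        raise ValueError(f"unknown family {self.family!r}; "
                         f"choose from {_FAMILIES}")

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        yy = np.asarray(y, dtype=float).reshape(-1)
        M = self._design(x)
        if x.size < M.shape[1] + 1:
            raise ValueError(
                f"{self.family} needs >= {M.shape[1] + 1} points")
        coef, _, rank, _ = np.linalg.lstsq(M, yy, rcond=None)
        if rank < M.shape[1]:
            raise ValueError("rank-deficient design: fit failed")
        resid = yy - M @ coef
        rss = float(resid @ resid)
        if self.family == "polynomial3_through_origin":
            tss = float(yy @ yy)
        else:
            tss = float(((yy - yy.mean()) ** 2).sum())
        self.coef_ = coef
        self.rss_ = rss
        self.r_squared_ = 1.0 - rss / tss if tss > 0 else 1.0
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self._design(x) @ self.coef_


def fit_empirical(x, y, family: str = "polynomial2") -> EmpiricalRegression:
    """Functional wrapper around :class:`EmpiricalRegression`."""
    return EmpiricalRegression(family=family).fit(np.asarray(x), np.asarray(y))
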