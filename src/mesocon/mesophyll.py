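"""Variable-J (Harley) estimation of mesophyll conductance.

The estimator inverts the combination of the Fick mesophyll drawdown
A = gm*(Ci - Cc) with the electron-transport expression of the chloroplast
CO2 level,

    Cc = Gamma* * (Jf + 8*(An + Rd)) / (Jf - 4*(An + Rd)),

giving the point-by-point estimate

    gm = An / (Ci - Gamma* * (Jf + 8*(An + Rd)) / (Jf - 4*(An + Rd))).

The estimator is singular where Jf approaches 4*(An + Rd); estimates in
that neighbourhood, or with a non-positive Ci - Cc drawdown, or above a
configurable ceiling, are flagged with a reason code and never silently
dropped.

Also provided: the gm(Ci) rapid-response scan along an A/Ci curve and the
linear cuvette-leak correction fitted on photosynthetically inactive
(heat-killed) leaf records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PhotoParams

#: estimates above this ceiling (mol m-2 s-1) are treated as unphysical
DEFAULT_GM_CEILING = 10.0

#: reason codes for invalid estimates
J_DEFICIT = "J_DEFICIT"
NEGATIVE_DRAWDOWN = "NEGATIVE_DRAWDOWN"
CEILING = "CEILING"
OK = "OK"


@dataclass(frozen=True)
class MesophyllEstimate:
    gm: float
    Cc: float
    valid: bool
    reason: str = OK


class EmptyResponseError(RuntimeError):
    """Raised when no point of a response curve yields a valid estimate."""


def harley_gm(An, Ci, Jf, params: PhotoParams,
              gm_ceiling: float = DEFAULT_GM_CEILING):
    """Variable-J mesophyll conductance for one observation.

    Returns a :class:`MesophyllEstimate`; scalar inputs only (see
    :func:`harley_gm_table` for the vectorised form).
    """
    gm, cc, valid, reason = _harley_arrays(
        np.atleast_1d(float(An)), np.atleast_1d(float(Ci)),
        np.atleast_1d(float(Jf)), params, gm_ceiling)
    return MesophyllEstimate(gm=float(gm[0]), Cc=float(cc[0]),
                             valid=bool(valid[0]), reason=str(reason[0]))


def _harley_arrays(An, Ci, Jf, params, gm_ceiling):
    if np.any(Ci <= 0) or np.any(Jf <= 0):
        raise ValueError("Ci and Jf must be > 0")
    x = An + params.Rd
    denom = Jf - 4.0 * x
    gm = np.full_like(An, np.nan)
    cc = np.full_like(An, np.nan)
    valid = np.zeros(An.shape, dtype=bool)
    reason = np.full(An.shape, OK, dtype=object)

    deficit = denom <= 0
    reason[deficit] = J_DEFICIT

    ok = ~deficit
    bracket = np.empty_like(An)
    bracket[ok] = (Jf[ok] + 8.0 * x[ok]) / denom[ok]
    drawdown = np.empty_like(An)
    drawdown[ok] = Ci[ok] - params.gamma_star * bracket[ok]

    # zero-flux limit: gm -> 0 cleanly when An == 0
    zero = ok & (An == 0.0)
    gm[zero] = 0.0
    cc[zero] = params.gamma_star * bracket[zero]
    valid[zero] = drawdown[zero] > 0
    reason[zero & ~valid] = NEGATIVE_DRAWDOWN

    pos = ok & (An != 0.0)
    bad_draw = pos & (drawdown <= 0)
    reason[bad_draw] = NEGATIVE_DRAWDOWN
    good = pos & (drawdown > 0)
    gm[good] = An[good] / drawdown[good]
    cc[good] = Ci[good] - An[good] / gm[good]
    over = good & (gm > gm_ceiling)
    reason[over] = CEILING
    neg = good & (gm < 0)
    reason[neg] = NEGATIVE_DRAWDOWN
    valid[good & ~over & ~neg] = True
    return gm, cc, valid, reason


def harley_gm_table(records: pd.DataFrame, params: PhotoParams,
                    gm_ceiling: float = DEFAULT_GM_CEILING) -> pd.DataFrame:
    """Vectorised Harley estimates appended to a record table.

    ``records`` must carry columns A, Ci, Jf.  Returns a copy with added
    columns gm, Cc, valid, reason.
    """
    An = records["A"].to_numpy(dtype=float)
    Ci = records["Ci"].to_numpy(dtype=float)
    Jf = records["Jf"].to_numpy(dtype=float)
    gm, cc, valid, reason = _harley_arrays(An, Ci, Jf, params, gm_ceiling)
    out = records.copy()
    out["gm"] = gm
    out["Cc"] = cc
    out["valid"] = valid
    out["reason"] = reason.astype(str)
    return out


def harley_gm_day(An, Ci, Jf, params: PhotoParams,
                  gm_ceiling: float = DEFAULT_GM_CEILING,
                  jackknife: bool = True) -> MesophyllEstimate:
    """Day-level estimate from replicate instrument readings.

    The readings are averaged per channel and inverted once; because the
    inversion is a smooth nonlinear function of the channel means, the
    plain estimate carries an O(1/n) bias, which the leave-one-out
    jackknife over the n readings removes:

        gm_jack = n * gm(all) - (n-1) * mean_i gm(without reading i).

    Falls back to the plain day-mean estimate when fewer than 3 readings
    are available or any leave-one-out estimate is invalid.
    """
    An = np.asarray(An, dtype=float)
    Ci = np.asarray(Ci, dtype=float)
    Jf = np.asarray(Jf, dtype=float)
    n = An.size
    full = harley_gm(An.mean(), Ci.mean(), Jf.mean(), params, gm_ceiling)
    if not jackknife or n < 3 or not full.valid:
        return full
    loo = []
    for i in range(n):
        keep = np.arange(n) != i
        est = harley_gm(An[keep].mean(), Ci[keep].mean(), Jf[keep].mean(),
                        params, gm_ceiling)
        if not est.valid:
            return full
        loo.append(est.gm)
    gm = n * full.gm - (n - 1) * float(np.mean(loo))
    if not (0 < gm <= gm_ceiling):
        return full
    return MesophyllEstimate(gm=gm, Cc=Ci.mean() - An.mean() / gm,
                             valid=True, reason=OK)


class VariableJEstimator:
    """Transformer-style wrapper: record table -> table with gm columns.

    Follows the fit/transform convention: ``fit`` stores the leaf parameter
    set (Gamma*, Rd from a Laisk fit; alpha*beta from calibration);
    ``transform`` appends per-point estimates.
    """

    def __init__(self, params: PhotoParams | None = None,
                 gm_ceiling: float = DEFAULT_GM_CEILING):
        self.params = params
        self.gm_ceiling = gm_ceiling

    def get_params(self, deep: bool = True):
        return {"params": self.params, "gm_ceiling": self.gm_ceiling}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None, params: PhotoParams | None = None):
        self.params_ = params if params is not None else self.params
        if self.params_ is None:
            raise ValueError("leaf parameters (PhotoParams) are required")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            self.fit()
        return harley_gm_table(X, self.params_, self.gm_ceiling)

    def fit_transform(self, X: pd.DataFrame, y=None, **kw) -> pd.DataFrame:
        return self.fit(X, y, **kw).transform(X)


@dataclass(frozen=True)
class GmCiSummary:
    peak_gm: float
    ci_at_peak: float
    plateau_gm: float
    fold_drop: float
    n_valid: int


def gm_ci_response(curve: pd.DataFrame, params: PhotoParams,
                   gm_ceiling: float = DEFAULT_GM_CEILING):
    """Per-point Harley estimates along an A/Ci curve with per-point Jf.

    ``curve`` must be ordered by Ca setpoint and carry A, Ci, Jf.  Returns
    ``(table, summary)`` where the table is the per-point estimate frame and
    the summary holds the peak gm, the Ci at the peak, the high-Ci plateau
    (the valid estimate at the largest Ci) and the peak-to-plateau fold drop.
    """
    table = harley_gm_table(curve, params, gm_ceiling)
    valid = table[table["valid"]]
    if valid.empty:
        raise EmptyResponseError("no valid mesophyll estimate on the curve")
    peak_idx = valid["gm"].idxmax()
    plateau = valid.loc[valid["Ci"].idxmax()]
    peak_gm = float(valid.loc[peak_idx, "gm"])
    plateau_gm = float(plateau["gm"])
    summary = GmCiSummary(
        peak_gm=peak_gm,
        ci_at_peak=float(valid.loc[peak_idx, "Ci"]),
        plateau_gm=plateau_gm,
        fold_drop=peak_gm / plateau_gm if plateau_gm > 0 else np.inf,
        n_valid=int(valid.shape[0]),
    )
    return table, summary


@dataclass(frozen=True)
class LeakCorrection:
    """Linear cuvette-flux correction A_corrected = A_raw - (k0 + k1*Ca)."""

    k0: float = 0.0
    k1: float = 0.0

    def apply(self, A_raw, Ca):
        return (np.asarray(A_raw, dtype=float)
                - (self.k0 + self.k1 * np.asarray(Ca, dtype=float)))


def fit_leak(inactive_records: pd.DataFrame) -> LeakCorrection:
    """Fit the leak line on photosynthetically inactive (heat-killed) leaf
    records carrying columns A and Ca."""
    ca = inactive_records["Ca"].to_numpy(dtype=float)
    a = inactive_records["A"].to_numpy(dtype=float)
    if ca.size < 2 or np.ptp(ca) <= 0:
        raise ValueError("leak fit needs >= 2 records spanning a Ca range")
    k1, k0 = np.polyfit(ca, a, 1)
    return LeakCorrection(k0=float(k0), k1=float(k1))
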