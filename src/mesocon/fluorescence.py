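"""PSII operating efficiency, electron transport and the alpha-beta calibration.

Saturating-pulse chlorophyll-a fluorescence gives the PSII operating
efficiency  Phi_PSII = (Fm' - Fs)/Fm',  from which the linear electron
transport rate is  Jf = Phi_PSII * PPFD * alpha*beta,  with alpha the leaf
absorbance (0.85 by convention) and beta the fraction of absorbed quanta
reaching PSII.  Only the product alpha*beta is carried.

Under non-photorespiratory conditions (< 1% O2) all electrons serve
carboxylation, Jf = 4*(An + Rd), so regressing Phi_CO2 = (An + Rd)/PPFD on
Phi_PSII gives a slope of alpha*beta/4: the slope-based calibration
implemented by :class:`AlphaBetaCalibrator`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm

#: conventional leaf absorbance
DEFAULT_ALPHA = 0.85


class FluorescenceError(ValueError):
    """Raised on physically impossible fluorescence input (e.g. Fs > Fm')."""


class CalibrationError(RuntimeError):
    """Raised when the alpha-beta calibration is underdetermined or invalid."""


@dataclass(frozen=True)
class FluorescencePoint:
    Fs: float
    Fm_prime: float
    PPFD: float

    def __post_init__(self) -> None:
        if self.Fs <= 0 or self.Fm_prime <= 0:
            raise FluorescenceError("fluorescence signals must be > 0")
        if self.PPFD < 0:
            raise FluorescenceError("PPFD must be >= 0")


def phi_psii(Fs, Fm_prime):
    """Operating efficiency of PSII, (Fm' - Fs)/Fm', in [0, 1).

    Accepts scalars or arrays.  Fs > Fm' indicates a failed saturating pulse
    and raises rather than clipping.
    """
    Fs = np.asarray(Fs, dtype=float)
    Fm_prime = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm_prime <= 0):
        raise FluorescenceError("Fm' must be > 0")
    if np.any(Fs > Fm_prime):
        raise FluorescenceError("Fs exceeds Fm' (saturating-pulse failure)")
    out = (Fm_prime - Fs) / Fm_prime
    return float(out) if out.ndim == 0 else out


def electron_transport(phi, PPFD, alpha_beta):
    """Linear electron transport rate Jf = Phi_PSII * PPFD * alpha*beta."""
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(np.asarray(PPFD) < 0) or alpha_beta < 0:
        raise ValueError("inputs must be non-negative")
    out = phi * np.asarray(PPFD, dtype=float) * alpha_beta
    return float(out) if out.ndim == 0 else out


def phi_co2(An, Rd, PPFD):
    """Quantum yield of CO2 fixation, (An + Rd)/PPFD."""
    PPFD = np.asarray(PPFD, dtype=float)
    if np.any(PPFD <= 0):
        raise ValueError("PPFD must be > 0")
    out = (np.asarray(An, dtype=float) + Rd) / PPFD
    return float(out) if out.ndim == 0 else out


class AlphaBetaCalibrator(BaseEstimator):
    """Slope calibration of the alpha*beta product from low-O2 yield pairs.

    Parameters
    ----------
    fit_intercept : bool, default True
        Include an intercept in the Phi_CO2 ~ Phi_PSII regression.  The
        intercept is reported and a warning recorded when its magnitude
        exceeds two standard errors; a through-origin variant is selected
        with ``fit_intercept=False``.

    Attributes
    ----------
    alpha_beta_ : float
        4 x slope of the least-squares regression.
    alpha_beta_se_ : float
        Standard error of alpha_beta_.
    intercept_, intercept_se_ : float
        Fitted intercept and its SE (0 when fit_intercept=False).
    warnings_ : list of str
    r_squared_ : float
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y=None):
        """Fit from pairs.

        X : array-like of shape (n, 2) with columns (Phi_PSII, Phi_CO2),
            or shape (n,) of Phi_PSII with ``y`` the Phi_CO2 values.
        """
        X = np.asarray(X, dtype=float)
        if y is None:
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("expected (n, 2) pairs of (Phi_PSII, Phi_CO2)")
            phi_p, phi_c = X[:, 0], X[:, 1]
        else:
            phi_p = X.ravel()
            phi_c = np.asarray(y, dtype=float).ravel()
        if phi_p.size < 3:
            raise CalibrationError("calibration needs >= 3 pairs")
        if np.ptp(phi_p) <= 0:
            raise CalibrationError("Phi_PSII values span no range")
        if np.any((phi_p < 0) | (phi_p >= 1)) or np.any(phi_c < 0):
            raise CalibrationError("quantum yields outside [0, 1)")

        design = sm.add_constant(phi_p) if self.fit_intercept else phi_p[:, None]
        res = sm.OLS(phi_c, design).fit()
        if self.fit_intercept:
            intercept, slope = res.params
            intercept_se, slope_se = res.bse
        else:
            intercept, intercept_se = 0.0, 0.0
            slope, slope_se = res.params[0], res.bse[0]

        ab = 4.0 * slope
        if slope <= 0 or not (0 < ab <= 1):
            raise CalibrationError(
                f"calibration failed: slope={slope:.5g}, alpha*beta={ab:.5g} "
                "outside (0, 1]"
            )
        self.warnings_ = []
        if self.fit_intercept and abs(intercept) > 2 * intercept_se > 0:
            self.warnings_.append(
                f"calibration intercept {intercept:.4g} exceeds 2 SE "
                f"({intercept_se:.4g}); consider the through-origin variant"
            )
        self.slope_ = float(slope)
        self.alpha_beta_ = float(ab)
        self.alpha_beta_se_ = float(4.0 * slope_se)
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(intercept_se)
        self.r_squared_ = float(res.rsquared)
        self.n_pairs_ = int(phi_p.size)
        return self

    def predict(self, X):
        """Predicted Phi_CO2 for Phi_PSII values."""
        check_is_fitted(self, "alpha_beta_")
        phi_p = np.asarray(X, dtype=float).ravel()
        return self.intercept_ + self.alpha_beta_ / 4.0 * phi_p


def calibrate_alpha_beta(phi_psii_values, phi_co2_values, fit_intercept: bool = True):
    """Functional wrapper: returns a fitted :class:`AlphaBetaCalibrator`."""
    return AlphaBetaCalibrator(fit_intercept=fit_intercept).fit(
        np.asarray(phi_psii_values), np.asarray(phi_co2_values)
    )
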