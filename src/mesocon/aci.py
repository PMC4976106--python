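"""Carboxylation capacity from the initial slope of the A/Ci curve.

With Gamma*, Rd and the Rubisco kinetic constants fixed, the Rubisco-limited
demand  A = Vcmax * (Cx - Gamma*)/(Cx + Km)  is linear in Vcmax, so the
least-squares estimate over the initial-slope points (Cx < 300 umol mol-1 by
default) is the exact one-parameter projection

    Vcmax = sum(f_i * y_i) / sum(f_i^2),   f_i = (Cx_i - Gamma*)/(Cx_i + Km),

computed in closed form — no iteration.  ``y`` is the measured net
assimilation, with Rd added by default so the gross demand is fitted
consistently (``use_rd=False`` fits net A directly).

The fit basis is Ci (the conventional reporting basis); ``basis="cc"``
substitutes chloroplast CO2 (e.g. from the variable-J stage), which removes
the finite-gm bias of the Ci-basis estimate and is the basis under which a
simulated campaign's generating Vcmax is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import PhotoParams

DEFAULT_CI_CEILING = 300.0


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class VcmaxFit:
    vcmax: float
    se: float
    n_points: int
    rss: float
    failed: bool


class VcmaxRegression(RegressorMixin, BaseEstimator):
    """Closed-form estimator of Vcmax on the A/Ci initial slope.

    Parameters
    ----------
    params : PhotoParams
        Supplies Gamma*, Rd and the kinetics; its Vcmax field is ignored.
    ci_ceiling : float, default 300
        Upper CO2 bound of the initial-slope region.
    use_rd : bool, default True
        Add Rd to measured A before fitting (gross-demand fit).
    basis : {"ci", "cc"}, default "ci"
        Which CO2 column the demand is evaluated at.

    Attributes
    ----------
    vcmax_ : float
    vcmax_se_ : float
    n_points_ : int
    rss_ : float
    failed_ : bool   set when the estimate is non-positive
    """

    def __init__(self, params: PhotoParams | None = None,
                 ci_ceiling: float = DEFAULT_CI_CEILING,
                 use_rd: bool = True, basis: str = "ci"):
        self.params = params
        self.ci_ceiling = ci_ceiling
        self.use_rd = use_rd
        self.basis = basis

    def _validate(self):
        if self.params is None:
            raise ValueError("params (PhotoParams) is required")
        if self.basis not in ("ci", "cc"):
            raise ValueError("basis must be 'ci' or 'cc'")

    def fit(self, X, y):
        """X : (n, 1) or (n,) CO2 mole fractions on the chosen basis;
        y : measured net assimilation."""
        self._validate()
        cx = np.asarray(X, dtype=float).reshape(-1)
        a = np.asarray(y, dtype=float).reshape(-1)
        if cx.size != a.size:
            raise ValueError("X and y must have equal length")
        p = self.params
        keep = (cx < self.ci_ceiling) & (cx > p.gamma_star) & np.isfinite(a)
        cx, a = cx[keep], a[keep]
        if cx.size < 3:
            raise InsufficientDataError(
                f"need >= 3 points with {self.basis} in "
                f"(gamma_star, {self.ci_ceiling}); got {cx.size}"
            )
        f = (cx - p.gamma_star) / (cx + p.kinetics.effective_km)
        yy = a + p.Rd if self.use_rd else a
        sff = float(f @ f)
        v = float(f @ yy) / sff
        resid = yy - v * f
        rss = float(resid @ resid)
        dof = max(cx.size - 1, 1)
        se = float(np.sqrt(rss / dof / sff))
        self.vcmax_ = v
        self.vcmax_se_ = se
        self.n_points_ = int(cx.size)
        self.rss_ = rss
        self.failed_ = bool(v <= 0)
        return self

    def predict(self, X):
        """Net assimilation predicted by the fitted demand."""
        check_is_fitted(self, "vcmax_")
        cx = np.asarray(X, dtype=float).reshape(-1)
        p = self.params
        f = (cx - p.gamma_star) / (cx + p.kinetics.effective_km)
        out = self.vcmax_ * f
        return out - p.Rd if self.use_rd else out

    def result(self) -> VcmaxFit:
        check_is_fitted(self, "vcmax_")
        return VcmaxFit(vcmax=self.vcmax_, se=self.vcmax_se_,
                        n_points=self.n_points_, rss=self.rss_,
                        failed=self.failed_)


def fit_vcmax(cx, a, params: PhotoParams,
              ci_ceiling: float = DEFAULT_CI_CEILING,
              use_rd: bool = True, basis: str = "ci") -> VcmaxFit:
    """Functional wrapper around :class:`VcmaxRegression`."""
    reg = VcmaxRegression(params=params, ci_ceiling=ci_ceiling,
                          use_rd=use_rd, basis=basis)
    return reg.fit(np.asarray(cx), np.asarray(a)).result()
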