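"""Common-intersection estimation of Ci* and Rd from low-Ci response lines.

A/Ci responses measured at several irradiances are each linear at low Ci,
and the lines share a common point: its abscissa is the apparent CO2
compensation point Ci* (used as a proxy for the chloroplastic compensation
point Gamma*) and its ordinate is minus the daytime respiration Rd.

Each curve is fitted by ordinary least squares, A = a_k + b_k * Ci, and the
joint intersection (x, y) minimises  sum_k (a_k + b_k x - y)^2  — a linear
least-squares problem.  Pairwise line intersections are retained as a
dispersion diagnostic, not as the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

#: points with Ci above this ceiling are outside the linear region
DEFAULT_CI_CEILING = 300.0


class IllConditionedError(RuntimeError):
    """Raised when the response lines are too close to parallel."""


@dataclass
class LaiskCurve:
    """One low-Ci response series at a fixed irradiance."""

    ppfd: float
    ci: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.ci.size != self.a.size:
            raise ValueError("ci and a must have equal length")
        if self.ci.size < 3:
            raise ValueError("each curve needs >= 3 points")
        if np.ptp(self.ci) <= 0:
            raise ValueError("ci values span no range")


@dataclass(frozen=True)
class LaiskResult:
    ci_star: float
    rd: float
    slopes: tuple
    intercepts: tuple
    ppfd_levels: tuple
    dispersion: float
    warnings: tuple = field(default_factory=tuple)


class LaiskRegression(BaseEstimator):
    """Joint-intersection estimator for Ci* and Rd.

    Parameters
    ----------
    ci_ceiling : float, default 300
        Points with Ci above this value are excluded to stay within the
        linear region of the response.
    min_slope_spread : float, default 1e-6
        Minimum spread between the largest and smallest fitted slope; below
        it the intersection is ill-conditioned.

    Attributes
    ----------
    ci_star_ : float     apparent CO2 compensation point (umol mol-1)
    rd_ : float          daytime respiration, positive magnitude (umol m-2 s-1)
    slopes_, intercepts_ : ndarray, per curve (ordered by input)
    dispersion_ : float  RMS distance of pairwise intersections from the
                         joint solution
    warnings_ : list of str
    """

    def __init__(self, ci_ceiling: float = DEFAULT_CI_CEILING,
                 min_slope_spread: float = 1e-6):
        self.ci_ceiling = ci_ceiling
        self.min_slope_spread = min_slope_spread

    def fit(self, X, y=None):
        """Fit from curves.

        X : sequence of :class:`LaiskCurve`, or array of shape (n, 3) with
            columns (ppfd, ci, a) pooled over curves (``y`` ignored).
        """
        curves = self._coerce_curves(X)
        if len(curves) < 2:
            raise ValueError("need >= 2 curves at distinct PPFD")
        ppfd = np.array([c.ppfd for c in curves], dtype=float)
        if np.unique(ppfd).size != ppfd.size:
            raise ValueError("curves must be at distinct PPFD levels")

        slopes, intercepts = [], []
        for c in curves:
            keep = c.ci <= self.ci_ceiling
            ci, a = c.ci[keep], c.a[keep]
            if ci.size < 3:
                raise ValueError(
                    f"curve at PPFD {c.ppfd} has < 3 points below the Ci "
                    f"ceiling {self.ci_ceiling}"
                )
            b, a0 = np.polyfit(ci, a, 1)
            slopes.append(b)
            intercepts.append(a0)
        slopes = np.asarray(slopes)
        intercepts = np.asarray(intercepts)

        if np.ptp(slopes) < self.min_slope_spread:
            raise IllConditionedError(
                f"slope spread {np.ptp(slopes):.3g} below tolerance "
                f"{self.min_slope_spread}: lines are near-parallel"
            )
        self.warnings_ = []
        order = np.argsort(ppfd)
        if np.any(np.diff(slopes[order]) <= 0):
            self.warnings_.append(
                "fitted slopes are not strictly increasing with PPFD"
            )

        # joint least squares: minimise sum_k (a_k + b_k x - y)^2 over (x, y)
        M = np.column_stack([slopes, -np.ones_like(slopes)])
        sol, *_ = np.linalg.lstsq(M, -intercepts, rcond=None)
        x, yy = sol

        # pairwise intersections as a concurrency diagnostic
        pair_d2 = []
        k = len(curves)
        for i in range(k):
            for j in range(i + 1, k):
                db = slopes[i] - slopes[j]
                if abs(db) < self.min_slope_spread:
                    continue
                xi = -(intercepts[i] - intercepts[j]) / db
                yi = intercepts[i] + slopes[i] * xi
                pair_d2.append((xi - x) ** 2 + (yi - yy) ** 2)
        dispersion = float(np.sqrt(np.mean(pair_d2))) if pair_d2 else 0.0

        self.ci_star_ = float(x)
        self.rd_ = float(max(-yy, 0.0))
        self.intersection_y_ = float(yy)
        self.slopes_ = slopes
        self.intercepts_ = intercepts
        self.ppfd_levels_ = ppfd
        self.dispersion_ = dispersion
        return self

    def result(self) -> LaiskResult:
        check_is_fitted(self, "ci_star_")
        return LaiskResult(
            ci_star=self.ci_star_,
            rd=self.rd_,
            slopes=tuple(self.slopes_),
            intercepts=tuple(self.intercepts_),
            ppfd_levels=tuple(self.ppfd_levels_),
            dispersion=self.dispersion_,
            warnings=tuple(self.warnings_),
        )

    @staticmethod
    def _coerce_curves(X):
        if isinstance(X, np.ndarray) and X.ndim == 2 and X.shape[1] == 3:
            curves = []
            for level in np.unique(X[:, 0]):
                rows = X[X[:, 0] == level]
                curves.append(LaiskCurve(ppfd=float(level),
                                         ci=rows[:, 1], a=rows[:, 2]))
            return curves
        return list(X)


def fit_laisk(curves, ci_ceiling: float = DEFAULT_CI_CEILING) -> LaiskResult:
    """Functional wrapper around :class:`LaiskRegression`."""
    return LaiskRegression(ci_ceiling=ci_ceiling).fit(curves).result()
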