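"""Rubisco-limited C3 demand model and the Fick's-law CO2 supply chain.

The demand side is the Rubisco-limited branch of the Farquhar–von Caemmerer–
Berry model,

    A(Cx) = Vcmax * (Cx - Gamma*) / (Cx + Kc * (1 + O/Ko)),

valid in the initial-slope region of an A/Ci curve (no RuBP-regeneration or
TPU branch is implemented).  The supply side is the two-resistor diffusion
chain

    A = gs_co2 * (Ca - Ci) = gm_co2 * (Ci - Cc),

with stomatal conductance converted from its H2O basis by the 1.6
diffusivity ratio.  ``solve_assimilation`` intersects the two, analytically
through a quadratic in A; ``solve_assimilation_bisect`` is an independent
bracketing solver retained for verification and never called by the
analytic path.

Kinetic constants default to their 25 degC literature values and are used
as-is (no temperature response functions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

#: diffusivity ratio of water vapour to CO2 in air; converts gs(H2O) -> gs(CO2)
GS_H2O_TO_CO2 = 1.6

#: default ambient CO2 mole fraction used for steady-state comparisons (umol mol-1)
CA_REFERENCE = 380.0


class InfeasibleSupplyError(ValueError):
    """Raised when the supply chain cannot sustain the demanded flux."""


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco Michaelis constants and chloroplast oxygen level.

    Kc is in umol mol-1, Ko and O in mmol mol-1, so the effective Michaelis
    constant ``Kc * (1 + O/Ko)`` is in umol mol-1.
    """

    Kc: float = 404.9
    Ko: float = 278.4
    O: float = 210.0

    def __post_init__(self) -> None:
        if not (self.Kc > 0 and self.Ko > 0 and self.O > 0):
            raise ValueError("kinetic constants must be strictly positive")

    @property
    def effective_km(self) -> float:
        """Kc * (1 + O/Ko), the effective Michaelis constant (umol mol-1)."""
        return self.Kc * (1.0 + self.O / self.Ko)


@dataclass(frozen=True)
class PhotoParams:
    """Leaf-level photosynthetic parameter set.

    gamma_star : chloroplastic CO2 compensation point (umol mol-1)
    Rd         : daytime mitochondrial respiration (umol m-2 s-1), >= 0
    Vcmax      : maximal carboxylation rate (umol m-2 s-1)
    alpha_beta : product of leaf absorbance and PSII partitioning, in (0, 1]
    """

    gamma_star: float = 35.0
    Rd: float = 2.1
    Vcmax: float = 98.0
    alpha_beta: float = 0.425
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        if self.gamma_star <= 0:
            raise ValueError("gamma_star must be > 0")
        if self.Rd < 0:
            raise ValueError("Rd must be >= 0")
        if self.Vcmax <= 0:
            raise ValueError("Vcmax must be > 0")
        if not (0 < self.alpha_beta <= 1):
            raise ValueError("alpha_beta must be in (0, 1]")

    def with_(self, **kwargs) -> "PhotoParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ConductancePair:
    """Stomatal (H2O basis) and mesophyll (CO2 basis) conductances.

    Either member may be ``math.inf`` to model a vanishing drawdown.
    """

    gs_h2o: float
    gm_co2: float

    def __post_init__(self) -> None:
        if self.gs_h2o < 0 or self.gm_co2 < 0:
            raise ValueError("conductances must be >= 0")

    @property
    def gs_co2(self) -> float:
        return self.gs_h2o / GS_H2O_TO_CO2

    @property
    def total_co2(self) -> float:
        """Series combination of the stomatal and mesophyll CO2 conductances."""
        gs, gm = self.gs_co2, self.gm_co2
        if math.isinf(gs) and math.isinf(gm):
            return math.inf
        if math.isinf(gs):
            return gm
        if math.isinf(gm):
            return gs
        if gs == 0 or gm == 0:
            return 0.0
        return 1.0 / (1.0 / gs + 1.0 / gm)


def rubisco_limited_assimilation(Cx, params: PhotoParams):
    """Rubisco-limited demand at CO2 mole fraction ``Cx`` (umol mol-1).

    Vectorised over ``Cx``.  Negative below the compensation point
    (the demand line crosses zero at gamma_star).
    """
    Cx = np.asarray(Cx, dtype=float)
    if np.any(Cx <= 0):
        raise ValueError("Cx must be > 0")
    km = params.kinetics.effective_km
    out = params.Vcmax * (Cx - params.gamma_star) / (Cx + km)
    return float(out) if out.ndim == 0 else out


def supply_chain_ci(An, Ca, gs_co2):
    """Sub-stomatal CO2 from the stomatal drawdown: Ci = Ca - An/gs_co2."""
    An = np.asarray(An, dtype=float)
    if np.isinf(gs_co2):
        out = np.broadcast_to(np.asarray(Ca, dtype=float), An.shape).copy()
        return float(out) if out.ndim == 0 else out
    if gs_co2 <= 0:
        if np.all(An == 0):
            out = np.broadcast_to(np.asarray(Ca, dtype=float), An.shape).copy()
            return float(out) if out.ndim == 0 else out
        raise InfeasibleSupplyError("gs_co2 = 0 with nonzero flux")
    out = np.asarray(Ca, dtype=float) - An / gs_co2
    return float(out) if out.ndim == 0 else out


def supply_chain_cc(An, Ci, gm_co2):
    """Chloroplast CO2 from the mesophyll drawdown.

    Returns ``(Cc, feasible)`` where ``feasible`` flags Cc > 0; Cc is never
    clipped.
    """
    An = np.asarray(An, dtype=float)
    if np.isinf(gm_co2):
        cc = np.broadcast_to(np.asarray(Ci, dtype=float), An.shape).copy()
    else:
        if gm_co2 <= 0:
            if np.all(An == 0):
                cc = np.broadcast_to(np.asarray(Ci, dtype=float), An.shape).copy()
            else:
                raise InfeasibleSupplyError("gm_co2 = 0 with nonzero flux")
        else:
            cc = np.asarray(Ci, dtype=float) - An / gm_co2
    feasible = cc > 0
    if cc.ndim == 0:
        return float(cc), bool(feasible)
    return cc, feasible


@dataclass(frozen=True)
class AssimilationSolution:
    A: float
    Ci: float
    Cc: float


def solve_assimilation(
    Ca: float, conductances: ConductancePair, params: PhotoParams
) -> AssimilationSolution:
    """Intersect the Rubisco-limited demand curve with the supply chain.

    With both conductances finite the intersection is the physically
    meaningful (smaller) root of

        A^2 - A * (g*(Ca + Km) + Vcmax) + g*Vcmax*(Ca - Gamma*) = 0,

    where g is the series conductance; with one conductance infinite the
    corresponding drawdown vanishes, and with both infinite the closed-form
    demand at Ca is returned exactly.
    """
    if Ca <= params.gamma_star:
        raise ValueError("Ca must exceed gamma_star")
    g = conductances.total_co2
    km = params.kinetics.effective_km
    if math.isinf(g):
        a = rubisco_limited_assimilation(Ca, params)
        return AssimilationSolution(A=a, Ci=Ca, Cc=Ca)
    if g <= 0:
        raise InfeasibleSupplyError("total conductance is zero")
    b = g * (Ca + km) + params.Vcmax
    c = g * params.Vcmax * (Ca - params.gamma_star)
    disc = b * b - 4.0 * c
    if disc < 0:
        raise InfeasibleSupplyError(
            f"no real supply-demand intersection (Ca={Ca}, g={g}, "
            f"Vcmax={params.Vcmax})"
        )
    # smaller root, evaluated in the numerically stable form
    A = 2.0 * c / (b + math.sqrt(disc))
    Ci = supply_chain_ci(A, Ca, conductances.gs_co2)
    Cc, feasible = supply_chain_cc(A, Ci, conductances.gm_co2)
    if not feasible:
        raise InfeasibleSupplyError(
            f"selected root gives Cc <= 0 (Ca={Ca}, g={g})"
        )
    return AssimilationSolution(A=A, Ci=Ci, Cc=Cc)


def solve_assimilation_bisect(
    Ca: float,
    conductances: ConductancePair,
    params: PhotoParams,
    xtol: float = 1e-12,
) -> AssimilationSolution:
    """Bracketing solver for the same intersection, independent of the
    quadratic path; used for cross-verification."""
    if Ca <= params.gamma_star:
        raise ValueError("Ca must exceed gamma_star")
    g = conductances.total_co2
    if math.isinf(g):
        a = rubisco_limited_assimilation(Ca, params)
        return AssimilationSolution(A=a, Ci=Ca, Cc=Ca)
    if g <= 0:
        raise InfeasibleSupplyError("total conductance is zero")

    def residual(A: float) -> float:
        Cc = Ca - A / g
        return A - rubisco_limited_assimilation(max(Cc, 1e-12), params)

    hi = min(params.Vcmax, g * (Ca - 1e-9))
    A = brentq(residual, 0.0, hi, xtol=xtol, rtol=8.881784197001252e-16)
    Ci = supply_chain_ci(A, Ca, conductances.gs_co2)
    Cc, feasible = supply_chain_cc(A, Ci, conductances.gm_co2)
    if not feasible:
        raise InfeasibleSupplyError("bisection root gives Cc <= 0")
    return AssimilationSolution(A=A, Ci=Ci, Cc=Cc)
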