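"""Partition of the photosynthesis decline into stomatal and mesophyll parts.

Raw partition (per-leaf-state, reference CO2 Ca = 380 umol mol-1):

    A_Ca : both conductances as measured
    A_Ci : gs infinite, gm measured  (so Ci = Ca = 380)
    A_Cc : gm infinite, gs measured  (so Cc = Ci by construction; the
           ambiguous reference level is resolved by solving at Ca = 380
           with infinite gm)

    L_S = 100 * (A_Ci - A_Ca) / A_Ci
    L_M = 100 * (A_Cc - A_Ca) / A_Cc

Rates come either from the supply-demand model (mode="model", deterministic)
or from monotone interpolation of a measured curve (mode="interpolate").

WW-normalised partition: drought campaigns usually express limitations as a
percentage of the well-watered maximum.  The sequential decomposition here
restores the measured state to the well-watered reference one factor at a
time (stomata first, then the mesophyll/biochemical remainder) and divides
by the well-watered rate:

    A0 = A(gs, gm, Vcmax)          measured state
    A1 = A(gs_ww, gm, Vcmax)       stomata restored
    A3 = A(gs_ww, gm_ww, Vcmax_ww) well-watered maximum

    L_S = 100 * (A1 - A0) / A3,   L_M = 100 * (A3 - A1) / A3

so L_S + L_M equals the total percentage loss versus the well-watered
maximum, and L_M absorbs the joint mesophyll-diffusion and biochemical
(non-stomatal) component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .model import (CA_REFERENCE, ConductancePair, PhotoParams,
                    solve_assimilation)


@dataclass(frozen=True)
class LimitationPartition:
    A_Ca: float
    A_Ci: float
    A_Cc: float
    L_S: float
    L_M: float


@dataclass(frozen=True)
class LeafState:
    """Measured conductances plus the leaf parameter set for one leaf-state."""

    gs_h2o: float
    gm_co2: float
    params: PhotoParams


def _solve(gs_h2o, gm_co2, params, ca):
    return solve_assimilation(ca, ConductancePair(gs_h2o, gm_co2), params).A


def partition_limitations(state: LeafState, mode: str = "model",
                          curve: pd.DataFrame | None = None,
                          ca_ref: float = CA_REFERENCE) -> LimitationPartition:
    """Raw stomatal/mesophyll partition for one leaf-state.

    mode="model" solves the supply-demand system with each conductance at
    its measured value or infinity; mode="interpolate" reads the rates from
    a measured A/Ci curve (columns Ca, Ci, Cc, A) by monotone piecewise
    interpolation.
    """
    if mode == "model":
        a_ca = _solve(state.gs_h2o, state.gm_co2, state.params, ca_ref)
        a_ci = _solve(math.inf, state.gm_co2, state.params, ca_ref)
        a_cc = _solve(state.gs_h2o, math.inf, state.params, ca_ref)
    elif mode == "interpolate":
        if curve is None:
            raise ValueError("interpolate mode requires a measured curve")
        a_ca, a_ci, a_cc = _interpolated_rates(curve, ca_ref)
    else:
        raise ValueError("mode must be 'model' or 'interpolate'")
    return partition_from_rates(a_ca, a_ci, a_cc)


def partition_from_rates(a_ca: float, a_ci: float,
                         a_cc: float) -> LimitationPartition:
    """Percentages from already-known potential rates:
    L_S = 100*(A_Ci - A_Ca)/A_Ci, L_M = 100*(A_Cc - A_Ca)/A_Cc."""
    ls = 100.0 * (a_ci - a_ca) / a_ci
    lm = 100.0 * (a_cc - a_ca) / a_cc
    return LimitationPartition(A_Ca=a_ca, A_Ci=a_ci, A_Cc=a_cc,
                               L_S=ls, L_M=lm)


def _monotone_interp(x, y, x0: float) -> float:
    order = np.argsort(x)
    x, y = np.asarray(x, float)[order], np.asarray(y, float)[order]
    x, idx = np.unique(x, return_index=True)
    y = y[idx]
    if not (x[0] <= x0 <= x[-1]):
        raise ValueError(
            f"curve range [{x[0]:.3g}, {x[-1]:.3g}] does not span {x0}")
    return float(PchipInterpolator(x, y)(x0))


def _interpolated_rates(curve: pd.DataFrame, ca_ref: float):
    from scipy.optimize import brentq

    a_ca = _monotone_interp(curve["Ca"], curve["A"], ca_ref)
    a_ci = _monotone_interp(curve["Ci"], curve["A"], ca_ref)
    # gm infinite, gs measured: Cc = Ci by construction, so the rate is the
    # intersection of the measured A(Cc) demand relation with the stomatal
    # supply line Cc = Ca - A/gs; gs is inferred from the ambient point
    ci_amb = _monotone_interp(curve["Ca"], curve["Ci"], ca_ref)
    gs_co2 = a_ca / (ca_ref - ci_amb)
    cc = np.asarray(curve["Cc"], dtype=float)
    cc_lo, cc_hi = cc.min(), cc.max()

    def residual(a):
        target = float(np.clip(ca_ref - a / gs_co2, cc_lo, cc_hi))
        return a - _monotone_interp(curve["Cc"], curve["A"], target)

    hi = gs_co2 * (ca_ref - cc_lo)
    a_cc = brentq(residual, 0.0, hi, xtol=1e-10)
    return a_ca, a_ci, a_cc


def partition_limitations_normalized(
    state: LeafState, ww_state: LeafState, ca_ref: float = CA_REFERENCE
) -> LimitationPartition:
    """Sequential partition of the loss versus the well-watered maximum.

    The reported A_Ca/A_Ci/A_Cc fields hold A0 (measured), A1 (stomata
    restored to the well-watered value) and A3 (well-watered maximum).
    """
    a0 = _solve(state.gs_h2o, state.gm_co2, state.params, ca_ref)
    a1 = _solve(ww_state.gs_h2o, state.gm_co2, state.params, ca_ref)
    a3 = _solve(ww_state.gs_h2o, ww_state.gm_co2, ww_state.params, ca_ref)
    ls = 100.0 * (a1 - a0) / a3
    lm = 100.0 * (a3 - a1) / a3
    return LimitationPartition(A_Ca=a0, A_Ci=a1, A_Cc=a3, L_S=ls, L_M=lm)


def plot_limitations(table: pd.DataFrame, path=None, normalized: bool = False):
    """Stacked per-genotype time series of L_S (black) and L_M (gray).

    ``table`` is the output of :func:`limitation_table`.  Returns the
    matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ls_col, lm_col = (("L_S_norm", "L_M_norm") if normalized
                      else ("L_S", "L_M"))
    genotypes = sorted(table["genotype"].unique())
    fig, axes = plt.subplots(len(genotypes), 1, sharex=True,
                             figsize=(6, 2.2 * len(genotypes)))
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, genotypes):
        sub = table[table["genotype"] == g].sort_values("day")
        ax.bar(sub["day"], sub[ls_col], color="black", width=0.4,
               label="stomatal")
        ax.bar(sub["day"] + 0.4, sub[lm_col], color="0.6", width=0.4,
               label="mesophyll")
        ax.set_ylabel("%")
        ax.set_title(g, fontsize=9)
    axes[-1].set_xlabel("day of dehydration")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def limitation_table(states: pd.DataFrame, ca_ref: float = CA_REFERENCE,
                     ww_reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-row partitions for a frame of leaf states.

    ``states`` needs columns genotype, day, gs_h2o, gm, gamma_star, Rd,
    Vcmax (and optionally alpha_beta).  When ``ww_reference`` (one row per
    genotype with gs_h2o, gm, Vcmax) is given, WW-normalised L_S/L_M columns
    are appended.
    """
    rows = []
    for _, r in states.iterrows():
        params = PhotoParams(gamma_star=r["gamma_star"], Rd=r["Rd"],
                             Vcmax=r["Vcmax"],
                             alpha_beta=r.get("alpha_beta", 0.425))
        st = LeafState(gs_h2o=r["gs_h2o"], gm_co2=r["gm"], params=params)
        part = partition_limitations(st, mode="model", ca_ref=ca_ref)
        row = {
            "genotype": r["genotype"], "day": r["day"],
            "A_Ca": part.A_Ca, "A_Ci": part.A_Ci, "A_Cc": part.A_Cc,
            "L_S": part.L_S, "L_M": part.L_M,
        }
        if ww_reference is not None:
            ww = ww_reference.loc[ww_reference["genotype"] == r["genotype"]]
            if not ww.empty:
                w = ww.iloc[0]
                ww_params = params.with_(Vcmax=w["Vcmax"])
                norm = partition_limitations_normalized(
                    st, LeafState(w["gs_h2o"], w["gm"], ww_params), ca_ref)
                row["L_S_norm"] = norm.L_S
                row["L_M_norm"] = norm.L_M
        rows.append(row)
    return pd.DataFrame(rows)
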