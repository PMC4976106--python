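"""Built-in reference summaries from a published four-genotype winter-wheat
progressive-drought campaign.

These are the class-level summary statistics (per stress class and
genotype) of the field campaign the synthetic generator emulates: net
assimilation A_N (umol m-2 s-1), stomatal conductance gs (mol H2O m-2 s-1),
mesophyll conductance gm (mol CO2 m-2 s-1) and intrinsic WUE (umol CO2
mol-1 H2O), together with the per-genotype Laisk estimates (Gamma*, Rd),
the well-watered Vcmax range, and the pooled through-origin cubic relating
gm to gs.  They serve as generator defaults and as the reference values the
summary utilities are checked against.
"""

from __future__ import annotations

import io

import pandas as pd

GENOTYPES = ("GK-Forras", "Pehlivan", "Piopio-4", "Samorinska")

#: per-genotype apparent CO2 compensation point (umol mol-1) and daytime
#: respiration (umol m-2 s-1) from the well-watered Laisk fits (mean, se)
_LAISK = """genotype,gamma_star,gamma_star_se,rd,rd_se
GK-Forras,36.38,2.58,2.18,0.07
Pehlivan,34.86,2.61,2.13,0.05
Piopio-4,35.15,1.01,2.14,0.06
Samorinska,34.08,1.70,2.08,0.04
"""

#: class-by-genotype means and dispersions of the campaign variables
_CLASS_BY_GENOTYPE = """genotype,stress_class,A_mean,A_disp,gs_mean,gs_disp,gm_mean,gm_disp,wue_mean,wue_disp
GK-Forras,WW,27.61,1.67,0.43,0.06,0.45,0.04,64.52,8.45
GK-Forras,MS,16.01,2.25,0.39,0.08,0.16,0.06,42.18,5.51
GK-Forras,SS,7.12,2.11,0.09,0.06,0.06,0.02,124.22,30.79
Pehlivan,WW,28.64,1.82,0.50,0.04,0.73,0.09,56.87,6.32
Pehlivan,MS,19.35,3.38,0.42,0.04,0.16,0.08,48.63,9.83
Pehlivan,SS,4.98,2.19,0.15,0.04,0.06,0.03,52.61,18.67
Piopio-4,WW,25.85,1.74,0.46,0.06,0.24,0.03,57.00,3.79
Piopio-4,MS,16.16,2.25,0.37,0.04,0.09,0.02,46.26,9.01
Piopio-4,SS,5.65,2.32,0.11,0.08,0.05,0.01,33.88,6.45
Samorinska,WW,26.39,1.10,0.45,0.06,0.44,0.07,58.79,6.72
Samorinska,MS,17.00,2.43,0.29,0.08,0.12,0.03,64.11,18.00
Samorinska,SS,8.44,2.11,0.13,0.04,0.06,0.01,61.42,11.97
"""

#: pooled (all genotypes) class-level means and dispersions
_CLASS_POOLED = """stress_class,variable,mean,dispersion,cv_printed
WW,A,27.26,1.93,0.07
WW,gs,0.47,0.06,0.12
WW,gm,0.49,0.19,0.39
MS,A,17.22,3.10,0.18
MS,gs,0.37,0.08,0.21
MS,gm,0.14,0.06,0.41
SS,A,6.57,2.60,0.12
SS,gs,0.12,0.06,0.49
SS,gm,0.06,0.02,0.34
"""

#: well-watered Vcmax extremes across genotypes (umol m-2 s-1) and the
#: pooled stressed-class means
VCMAX_WW_RANGE = (88.14, 108.44)
VCMAX_MS_MEAN = 74.8
VCMAX_SS_MEAN = 39.12

#: per-genotype well-watered Vcmax used as generator anchors: the printed
#: extremes for Samorinska/Pehlivan, mid-range values for the two genotypes
#: whose means were reported only graphically
VCMAX_WW_BY_GENOTYPE = {
    "GK-Forras": 98.0,
    "Pehlivan": 108.44,
    "Piopio-4": 95.0,
    "Samorinska": 88.14,
}

#: pooled through-origin cubic gm = c1*gs + c2*gs^2 + c3*gs^3 (n = 161)
GM_OF_GS_CUBIC = (0.426, -2.129, 6.189)


def load_laisk_reference() -> pd.DataFrame:
    """Per-genotype Gamma* and Rd reference table."""
    return pd.read_csv(io.StringIO(_LAISK))


def load_class_by_genotype() -> pd.DataFrame:
    """Class-by-genotype means/dispersions of A, gs, gm and WUEi."""
    return pd.read_csv(io.StringIO(_CLASS_BY_GENOTYPE))


def load_class_pooled() -> pd.DataFrame:
    """Pooled class-level means, dispersions and printed c.v. values."""
    return pd.read_csv(io.StringIO(_CLASS_POOLED))
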