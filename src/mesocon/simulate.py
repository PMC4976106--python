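"""Synthetic drought-campaign generator with a known ground-truth ledger.

The generator emulates a 21-day progressive-drought campaign on four winter
wheat genotypes: daily steady-state gas-exchange + fluorescence records at
ambient CO2 (Ca = 380 umol mol-1, saturating light), daily 12-setpoint
A/Ci response curves, well-watered low-Ci sub-curves at three irradiances
for the compensation-point regression, low-O2 calibration series for the
alpha*beta product, and heat-killed-leaf records for the cuvette-leak line.

Latent trajectories are phenomenological: relative water content declines
monotonically from ~100% to ~40% at a genotype-specific speed, and the
conductances and carboxylation capacity follow monotone shape-preserving
(PCHIP) curves over RWC anchored at the published class-level means of the
emulated campaign (see :mod:`mesocon.datasets`), so the configured truth of
each stress class is the printed class mean.  Observations are generated by
the forward supply-demand model plus the fluorescence equations; electron
transport is generated consistently with the variable-J inversion,

    Jf = 4*(An + Rd) * (Cc + 2*Gamma*) / (Cc - Gamma*),

so that every estimator recovers its ledger truth exactly in the noiseless
case.  Noise is additive Gaussian on the measured channels (A, gs, Fs,
Fm', RWC) — instrument error, not parameter scatter — and the sub-stomatal
CO2 of a record is recomputed from its noisy A and gs the way an open
gas-exchange system would.  The steady-state protocol takes ``n_reps``
instrument readings per leaf-day (the emulated campaign reports means of
four replicates); analyses of day-level values average the readings first.

A fixed seed makes the output byte-identical between runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from . import datasets
from .model import (GS_H2O_TO_CO2, ConductancePair, InfeasibleSupplyError,
                    PhotoParams, rubisco_limited_assimilation,
                    solve_assimilation)

RECORD_COLUMNS = [
    "record_id", "genotype", "day", "protocol_tag", "Ca", "Ci", "A",
    "gs_h2o", "PPFD", "Tleaf", "Fs", "Fm_prime", "RWC", "O2_condition",
]


class GenerationError(RuntimeError):
    pass


@dataclass
class DroughtCampaignConfig:
    """Study-design parameters of a synthetic drought campaign."""

    genotypes: tuple = datasets.GENOTYPES
    days: int = 21
    n_reps: int = 4
    seed: int = 0

    # water-status trajectory
    rwc_start: float = 100.0
    rwc_end: float = 40.0
    rwc_exponent: float = 1.3
    #: days to reach the RWC endpoint, per genotype (faster dehydration for
    #: the Mexican and Slovak genotypes, as in the emulated campaign)
    days_to_endpoint: dict = field(default_factory=lambda: {
        "GK-Forras": 21, "Pehlivan": 20, "Piopio-4": 16, "Samorinska": 16,
    })

    #: conductance coupling: "anchors" drives gm from the published class
    #: means over RWC; "cubic" derives gm from gs through the pooled
    #: through-origin cubic
    gm_mode: str = "anchors"
    gm_gs_cubic: tuple = datasets.GM_OF_GS_CUBIC

    alpha_beta: float = 0.425
    ppfd_sat: float = 1500.0
    tleaf: float = 21.0
    ca_ref: float = 380.0
    fm_prime_ref: float = 2000.0

    aci_setpoints: tuple = (50, 100, 150, 200, 250, 300, 380,
                            500, 700, 900, 1200, 1500)
    laisk_ppfd: tuple = (50.0, 150.0, 300.0)
    #: replicate sub-curves per irradiance (several response curves were
    #: measured per PPFD in the emulated campaign)
    laisk_reps: int = 4
    laisk_ca: tuple = (250.0, 210.0, 170.0, 130.0, 90.0, 50.0)
    laisk_slopes: dict = field(default_factory=lambda: {
        50.0: 0.02, 150.0: 0.05, 300.0: 0.10})
    lowo2_ca: tuple = (100, 240, 380, 520, 660, 800, 940,
                       1080, 1220, 1360, 1500)

    # cuvette leak line A_leak = k0 + k1*Ca, added to measured A when active
    leak_k0: float = 0.2
    leak_k1: float = 0.0003
    apply_leak: bool = True

    # additive Gaussian instrument noise per channel; magnitudes calibrated
    # so simulated class-level dispersions match the reference campaign's
    # printed dispersions (the well-watered gm cells are the binding ones)
    sigma_A: float = 0.25
    sigma_gs: float = 0.015
    sigma_Fs: float = 5.0
    sigma_Fm: float = 5.0
    sigma_rwc: float = 1.0

    def noiseless(self) -> "DroughtCampaignConfig":
        return replace(self, sigma_A=0.0, sigma_gs=0.0, sigma_Fs=0.0,
                       sigma_Fm=0.0, sigma_rwc=0.0)


@dataclass
class GenotypeTemplate:
    name: str
    gamma_star: float
    rd: float
    vcmax_ww: float
    gs_curve: PchipInterpolator
    gm_curve: PchipInterpolator
    v_curve: PchipInterpolator
    t_end: float


@dataclass(frozen=True)
class TruthState:
    genotype: str
    day: int
    rwc: float
    gs_h2o: float
    gm: float
    vcmax: float
    params: PhotoParams


def _class_anchor_curve(ww: float, ms: float, ss: float) -> PchipInterpolator:
    """Monotone RWC->value curve holding each stress class near its mean,
    with narrow transition bands at the class boundaries (RWC 60 and 80)."""
    r = np.array([35.0, 50.0, 58.0, 62.0, 70.0, 78.0, 82.0, 90.0, 100.0])
    v = np.array([0.85 * ss, ss, ss, ms, ms, ms, ww, ww, 1.02 * ww])
    return PchipInterpolator(r, v)


def build_templates(config: DroughtCampaignConfig) -> dict:
    """Per-genotype latent-trajectory templates from the reference tables."""
    ref = datasets.load_class_by_genotype()
    laisk_ref = datasets.load_laisk_reference().set_index("genotype")
    templates = {}
    for g in config.genotypes:
        sub = ref[ref["genotype"] == g].set_index("stress_class")
        if sub.empty:
            raise GenerationError(f"no reference template for genotype {g!r}")
        v_ww = datasets.VCMAX_WW_BY_GENOTYPE[g]
        templates[g] = GenotypeTemplate(
            name=g,
            gamma_star=float(laisk_ref.loc[g, "gamma_star"]),
            rd=float(laisk_ref.loc[g, "rd"]),
            vcmax_ww=v_ww,
            gs_curve=_class_anchor_curve(*(sub.loc[c, "gs_mean"]
                                           for c in ("WW", "MS", "SS"))),
            gm_curve=_class_anchor_curve(*(sub.loc[c, "gm_mean"]
                                           for c in ("WW", "MS", "SS"))),
            v_curve=_class_anchor_curve(v_ww, datasets.VCMAX_MS_MEAN,
                                        datasets.VCMAX_SS_MEAN),
            t_end=float(config.days_to_endpoint.get(g, config.days)),
        )
    return templates


def _rwc_at(day: int, config: DroughtCampaignConfig, t_end: float) -> float:
    frac = min(day / t_end, 1.0)
    span = config.rwc_start - config.rwc_end
    return config.rwc_start - span * frac ** config.rwc_exponent


def _gm_from_cubic(gs_h2o: float, coefs) -> float:
    c1, c2, c3 = coefs
    return c1 * gs_h2o + c2 * gs_h2o ** 2 + c3 * gs_h2o ** 3


def truth_state(template: GenotypeTemplate, day: int,
                config: DroughtCampaignConfig) -> TruthState:
    return truth_state_at_rwc(template, _rwc_at(day, config, template.t_end),
                              config, day=day)


def truth_state_at_rwc(template: GenotypeTemplate, rwc: float,
                       config: DroughtCampaignConfig,
                       day: int = -1) -> TruthState:
    gs = float(template.gs_curve(rwc))
    if config.gm_mode == "cubic":
        gm = _gm_from_cubic(gs, config.gm_gs_cubic)
    elif config.gm_mode == "anchors":
        gm = float(template.gm_curve(rwc))
    else:
        raise GenerationError(f"unknown gm_mode {config.gm_mode!r}")
    vc = float(template.v_curve(rwc))
    params = PhotoParams(gamma_star=template.gamma_star, Rd=template.rd,
                         Vcmax=vc, alpha_beta=config.alpha_beta)
    return TruthState(genotype=template.name, day=day, rwc=rwc,
                      gs_h2o=gs, gm=gm, vcmax=vc, params=params)


def electron_transport_truth(An: float, Cc: float, params: PhotoParams) -> float:
    """Jf consistent with the variable-J model at the chloroplast CO2 level."""
    if Cc <= params.gamma_star:
        raise GenerationError("Cc at or below the compensation point")
    x = An + params.Rd
    return 4.0 * x * (Cc + 2.0 * params.gamma_star) / (Cc - params.gamma_star)


@dataclass
class Campaign:
    """Simulated record table plus its ground-truth ledger."""

    records: pd.DataFrame
    truth: pd.DataFrame
    config: DroughtCampaignConfig


def _noise(rng, sigma, size=None):
    if sigma == 0:
        return 0.0 if size is None else np.zeros(size)
    return rng.normal(0.0, sigma, size=size)


def _fluor_pair(phi: float, config, rng):
    if not (0 <= phi < 1):
        raise GenerationError(f"generated Phi_PSII {phi:.3f} outside [0, 1)")
    fm = config.fm_prime_ref + _noise(rng, config.sigma_Fm)
    fs = config.fm_prime_ref * (1.0 - phi) + _noise(rng, config.sigma_Fs)
    fs = min(fs, fm)  # a reading cannot exceed its own saturating pulse
    return max(fs, 1.0), max(fm, 1.0)


def _measured_row(truth: TruthState, sol, jf_true, ca, ppfd, config, rng,
                  leak_active=True):
    """Apply the instrument model (leak + channel noise) to one forward
    solution and return the measured columns."""
    p = truth.params
    a_true = sol.A
    leak = (config.leak_k0 + config.leak_k1 * ca) if (
        config.apply_leak and leak_active) else 0.0
    a_meas_clean = a_true + _noise(rng, config.sigma_A)
    a_rec = a_meas_clean + leak
    gs_meas = max(truth.gs_h2o + _noise(rng, config.sigma_gs), 1e-4)
    ci_rec = ca - a_meas_clean / (gs_meas / GS_H2O_TO_CO2)
    phi = jf_true / (ppfd * p.alpha_beta)
    fs, fm = _fluor_pair(phi, config, rng)
    rwc_rec = float(np.clip(truth.rwc + _noise(rng, config.sigma_rwc),
                            0.0, 100.0))
    return {
        "Ca": ca, "Ci": ci_rec, "A": a_rec, "gs_h2o": gs_meas,
        "PPFD": ppfd, "Tleaf": config.tleaf, "Fs": fs, "Fm_prime": fm,
        "RWC": rwc_rec,
    }


def simulate_campaign(config: DroughtCampaignConfig | None = None) -> Campaign:
    """Generate the full campaign: steady-state records, A/Ci curves, Laisk
    sub-curves, low-O2 calibration pairs, leak records and the truth ledger."""
    config = config or DroughtCampaignConfig()
    rng = np.random.default_rng(config.seed)
    templates = build_templates(config)
    records, truths = [], []

    def add(rid, genotype, day, tag, o2, row, truth_row):
        records.append({"record_id": rid, "genotype": genotype, "day": day,
                        "protocol_tag": tag, "O2_condition": o2} | row)
        truths.append({"record_id": rid} | truth_row)

    for g in config.genotypes:
        tpl = templates[g]

        # heat-killed leaf records for the leak line (day 0)
        for ca in config.aci_setpoints:
            a_rec = (config.leak_k0 + config.leak_k1 * ca
                     + _noise(rng, config.sigma_A))
            add(f"{g}_leak_ca{int(ca)}", g, 0, "leak", "ambient",
                {"Ca": ca, "Ci": ca, "A": a_rec, "gs_h2o": 0.01,
                 "PPFD": config.ppfd_sat, "Tleaf": config.tleaf,
                 "Fs": config.fm_prime_ref, "Fm_prime": config.fm_prime_ref,
                 "RWC": 100.0},
                {"genotype": g, "day": 0, "protocol_tag": "leak",
                 "leak_k0": config.leak_k0, "leak_k1": config.leak_k1})

        # well-watered low-O2 alpha*beta calibration series (day 1)
        t0 = truth_state(tpl, 1, config)
        lowo2_params = t0.params.with_(gamma_star=1.0)
        for ca in config.lowo2_ca:
            try:
                sol = solve_assimilation(
                    ca, ConductancePair(t0.gs_h2o, t0.gm), lowo2_params)
            except (InfeasibleSupplyError, ValueError) as exc:
                raise GenerationError(
                    f"low-O2 series infeasible at Ca={ca} ({g})") from exc
            jf = 4.0 * (sol.A + lowo2_params.Rd)  # non-photorespiratory
            row = _measured_row(t0, sol, jf, ca, config.ppfd_sat, config,
                                rng, leak_active=False)
            add(f"{g}_lowo2_ca{int(ca)}", g, 1, "lowo2", "low", row,
                {"genotype": g, "day": 1, "protocol_tag": "lowo2",
                 "A_true": sol.A, "Jf_true": jf,
                 "alpha_beta": config.alpha_beta})

        # well-watered Laisk sub-curves (day 1): lines concurrent at
        # (Ci*, -Rd) realised through the stomatal supply chain
        gs_co2 = t0.gs_h2o / GS_H2O_TO_CO2
        for ppfd in config.laisk_ppfd:
            b = config.laisk_slopes[float(ppfd)]
            for rep in range(1, config.laisk_reps + 1):
                for ca in config.laisk_ca:
                    a_true = (b * (ca - tpl.gamma_star) - tpl.rd) / (
                        1.0 + b / gs_co2)
                    a_meas = a_true + _noise(rng, config.sigma_A)
                    gs_meas = max(t0.gs_h2o + _noise(rng, config.sigma_gs),
                                  1e-4)
                    ci_rec = ca - a_meas / (gs_meas / GS_H2O_TO_CO2)
                    add(f"{g}_laisk_p{int(ppfd)}_ca{int(ca)}_r{rep}", g, 1,
                        "laisk", "ambient",
                        {"Ca": ca, "Ci": ci_rec, "A": a_meas,
                         "gs_h2o": gs_meas, "PPFD": ppfd,
                         "Tleaf": config.tleaf,
                         "Fs": 0.3 * config.fm_prime_ref,
                         "Fm_prime": config.fm_prime_ref, "RWC": t0.rwc},
                        {"genotype": g, "day": 1, "protocol_tag": "laisk",
                         "ci_star": tpl.gamma_star, "rd": tpl.rd,
                         "laisk_slope": b})

        # daily steady-state replicates and A/Ci curves
        for day in range(1, config.days + 1):
            truth = truth_state(tpl, day, config)
            pair = ConductancePair(truth.gs_h2o, truth.gm)
            try:
                sol = solve_assimilation(config.ca_ref, pair, truth.params)
            except (InfeasibleSupplyError, ValueError) as exc:
                raise GenerationError(
                    f"infeasible steady state on day {day} ({g})") from exc
            jf = electron_transport_truth(sol.A, sol.Cc, truth.params)
            for rep in range(1, config.n_reps + 1):
                row = _measured_row(truth, sol, jf, config.ca_ref,
                                    config.ppfd_sat, config, rng)
                add(f"{g}_d{day:02d}_steady_r{rep}", g, day, "steady",
                    "ambient", row,
                    _truth_row(truth, sol, jf, "steady", config))

            for ca in config.aci_setpoints:
                try:
                    sol_c = solve_assimilation(ca, pair, truth.params)
                except (InfeasibleSupplyError, ValueError) as exc:
                    raise GenerationError(
                        f"infeasible A/Ci setpoint Ca={ca} on day {day} "
                        f"({g})") from exc
                jf_c = electron_transport_truth(sol_c.A, sol_c.Cc,
                                               truth.params)
                row = _measured_row(truth, sol_c, jf_c, ca, config.ppfd_sat,
                                    config, rng)
                add(f"{g}_d{day:02d}_aci_ca{int(ca)}", g, day, "aci",
                    "ambient", row,
                    _truth_row(truth, sol_c, jf_c, "aci", config))

    records_df = pd.DataFrame(records)[RECORD_COLUMNS]
    truth_df = pd.DataFrame(truths)
    return Campaign(records=records_df, truth=truth_df, config=config)


def _truth_row(truth: TruthState, sol, jf, tag, config):
    return {
        "genotype": truth.genotype, "day": truth.day, "protocol_tag": tag,
        "rwc_true": truth.rwc, "gs_h2o_true": truth.gs_h2o,
        "gm_true": truth.gm, "vcmax_true": truth.vcmax,
        "gamma_star": truth.params.gamma_star, "rd": truth.params.Rd,
        "alpha_beta": truth.params.alpha_beta,
        "A_true": sol.A, "Ci_true": sol.Ci, "Cc_true": sol.Cc,
        "Jf_true": jf,
        "leak_k0": config.leak_k0 if config.apply_leak else 0.0,
        "leak_k1": config.leak_k1 if config.apply_leak else 0.0,
    }


def simulate_day_observation(state: TruthState,
                             config: DroughtCampaignConfig, rng):
    """One steady-state leaf-day: ``n_reps`` noisy instrument readings.

    Returns ``(A, Ci, Jf)`` arrays of length ``n_reps`` — the measured
    channels after the instrument model (channel noise, Ci recomputed from
    the noisy A and gs, electron transport reconstructed from the noisy
    fluorescence pair with the true alpha*beta) — for estimator-ensemble
    studies.
    """
    sol = solve_assimilation(config.ca_ref,
                             ConductancePair(state.gs_h2o, state.gm),
                             state.params)
    jf = electron_transport_truth(sol.A, sol.Cc, state.params)
    phi = jf / (config.ppfd_sat * state.params.alpha_beta)
    n = config.n_reps
    a = sol.A + _noise(rng, config.sigma_A, n)
    gs = np.maximum(state.gs_h2o + _noise(rng, config.sigma_gs, n), 1e-4)
    ci = config.ca_ref - a / (gs / GS_H2O_TO_CO2)
    fm = config.fm_prime_ref + _noise(rng, config.sigma_Fm, n)
    fs = np.minimum(config.fm_prime_ref * (1.0 - phi)
                    + _noise(rng, config.sigma_Fs, n), fm)
    jf_meas = ((fm - fs) / fm) * config.ppfd_sat * state.params.alpha_beta
    return a, ci, jf_meas


def gm_ci_template(ci, gm_peak: float, ci_peak: float = 300.0,
                   shape_exp: float = 1.35):
    """Three-phase mesophyll response to intercellular CO2.

    A gamma-shaped pulse: rises over low Ci, peaks at ``ci_peak`` and
    declines exponentially at high Ci.  ``shape_exp`` ~1.35 gives a ~16-fold
    peak-to-plateau drop at the Ci realised at the highest CO2 setpoint
    (~1400 umol mol-1 for an open-stomata leaf).
    """
    x = np.asarray(ci, dtype=float) / ci_peak
    out = gm_peak * (x * np.exp(1.0 - x)) ** shape_exp
    return float(out) if out.ndim == 0 else out


def simulate_gm_ci_curve(params: PhotoParams, gs_h2o: float,
                         gm_peak: float, ci_peak: float = 300.0,
                         shape_exp: float = 1.35,
                         setpoints=None,
                         config: DroughtCampaignConfig | None = None,
                         rng=None) -> pd.DataFrame:
    """A/Ci curve whose generating gm varies with the realised Ci.

    At each Ca setpoint the assimilation solves the fixed-point system
    A = demand(Cc),  Ci = Ca - A/gs_co2,  Cc = Ci - A/gm(Ci),  by scalar
    bracketing.  Returns a frame with Ca, Ci, Cc, A, Jf, gm_true (noise-free
    unless a config with nonzero sigmas and an rng are supplied).
    """
    config = config or DroughtCampaignConfig().noiseless()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    setpoints = setpoints if setpoints is not None else config.aci_setpoints
    gs_co2 = gs_h2o / GS_H2O_TO_CO2
    rows = []
    for ca in setpoints:
        def residual(a):
            ci = ca - a / gs_co2
            gm = gm_ci_template(max(ci, 1e-9), gm_peak, ci_peak, shape_exp)
            cc = ci - a / max(gm, 1e-12)
            return a - rubisco_limited_assimilation(max(cc, 1e-12), params)

        hi = min(params.Vcmax, gs_co2 * (ca - 1e-9))
        a = brentq(residual, 0.0, hi, xtol=1e-12)
        ci = ca - a / gs_co2
        gm = gm_ci_template(ci, gm_peak, ci_peak, shape_exp)
        cc = ci - a / gm
        jf = electron_transport_truth(a, cc, params)
        a_meas = a + _noise(rng, config.sigma_A)
        rows.append({"Ca": ca, "Ci": ci, "Cc": cc, "A": a_meas,
                     "Jf": jf, "gm_true": gm})
    return pd.DataFrame(rows)
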