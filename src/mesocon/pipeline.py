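"""End-to-end analysis pipeline over a record table.

Stage order: cuvette-leak correction -> compensation-point regression
(Ci*, Rd per genotype) -> alpha*beta calibration (which needs Rd, hence
runs after the Laisk stage) -> per-point variable-J mesophyll conductance
-> Vcmax fits -> limitation partitioning -> water-status summaries and
empirical regressions.  Each stage failure halts the run naming the stage
and the offending records.

The steady-state protocol takes replicate instrument readings per leaf-day;
day-level analyses (mesophyll inversion, limitation partitioning,
summaries) run on the day means of the measured channels.

A run is fully determined by its inputs and options: re-running writes
byte-identical report files, and the JSON manifest records package
versions, the seed of a simulated input and every option used.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aci import VcmaxRegression
from .fluorescence import AlphaBetaCalibrator, electron_transport, phi_co2, phi_psii
from .laisk import LaiskCurve, LaiskRegression
from .limitations import limitation_table
from .mesophyll import (LeakCorrection, fit_leak, harley_gm_day,
                        harley_gm_table)
from .model import GS_H2O_TO_CO2, PhotoParams
from .water import classify_series, fit_empirical, group_summary, wue_intrinsic
from .io import write_records, write_table


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, record_ids=()):
        self.stage = stage
        self.record_ids = list(record_ids)
        ids = f" [records: {', '.join(self.record_ids[:5])}...]" if record_ids else ""
        super().__init__(f"stage {stage!r} failed: {message}{ids}")


@dataclass
class PipelineOptions:
    ca_ref: float = 380.0
    gm_ceiling: float = 10.0
    #: jackknife the day-level variable-J estimate over replicate readings
    gm_jackknife: bool = True
    laisk_ci_ceiling: float = 300.0
    vcmax_ci_ceiling: float = 300.0
    vcmax_basis: str = "ci"
    vcmax_use_rd: bool = True
    cv_basis: str = "sd"
    calibration_intercept: bool = True
    #: skip the Laisk stage and use these per-genotype (gamma_star, Rd)
    #: values instead, e.g. {"Pehlivan": (34.86, 2.13)}
    gamma_star_rd: dict | None = None
    #: skip the calibration stage and use this alpha*beta product
    alpha_beta: float | None = None
    seed: int | None = None


@dataclass
class PipelineResult:
    leak: dict
    laisk: dict
    calibration: dict
    params: dict
    records: pd.DataFrame
    day_table: pd.DataFrame
    vcmax_table: pd.DataFrame
    limitations: pd.DataFrame
    summary_pooled: pd.DataFrame
    summary_by_genotype: pd.DataFrame
    regressions: dict
    manifest: dict
    recovery: pd.DataFrame | None = None


def run_pipeline(records: pd.DataFrame, options: PipelineOptions | None = None,
                 outdir=None, truth: pd.DataFrame | None = None) -> PipelineResult:
    opts = options or PipelineOptions()
    genotypes = sorted(records["genotype"].unique())

    # ---- leak correction (heat-killed leaf records) -----------------------
    leak = {}
    for g in genotypes:
        rows = records[(records["genotype"] == g)
                       & (records["protocol_tag"] == "leak")]
        try:
            leak[g] = fit_leak(rows) if len(rows) >= 2 else LeakCorrection()
        except Exception as exc:
            raise StageError("leak", str(exc), rows["record_id"]) from exc

    corrected = records.copy()
    gas = corrected["protocol_tag"].isin(["steady", "aci"])
    for g in genotypes:
        m = gas & (corrected["genotype"] == g)
        corrected.loc[m, "A"] = leak[g].apply(
            corrected.loc[m, "A"], corrected.loc[m, "Ca"])

    # ---- Laisk stage: Ci* (proxy for Gamma*) and Rd per genotype ----------
    laisk = {}
    if opts.gamma_star_rd is None:
        for g in genotypes:
            rows = corrected[(corrected["genotype"] == g)
                             & (corrected["protocol_tag"] == "laisk")]
            if rows.empty:
                raise StageError("laisk", f"no laisk records for {g}")
            curves = [LaiskCurve(ppfd=lvl, ci=grp["Ci"].to_numpy(),
                                 a=grp["A"].to_numpy())
                      for lvl, grp in rows.groupby("PPFD")]
            try:
                laisk[g] = (LaiskRegression(ci_ceiling=opts.laisk_ci_ceiling)
                            .fit(curves).result())
            except Exception as exc:
                raise StageError("laisk", f"{g}: {exc}",
                                 rows["record_id"]) from exc
        gamma_rd = {g: (laisk[g].ci_star, laisk[g].rd) for g in genotypes}
    else:
        gamma_rd = opts.gamma_star_rd

    # ---- alpha*beta calibration (low-O2 series; uses Rd) ------------------
    calibration = {}
    if opts.alpha_beta is None:
        for g in genotypes:
            rows = corrected[(corrected["genotype"] == g)
                             & (corrected["protocol_tag"] == "lowo2")]
            if rows.empty:
                raise StageError("calibration", f"no low-O2 records for {g}")
            rd = gamma_rd[g][1]
            phi_p = phi_psii(rows["Fs"].to_numpy(), rows["Fm_prime"].to_numpy())
            phi_c = phi_co2(rows["A"].to_numpy(), rd, rows["PPFD"].to_numpy())
            try:
                calibration[g] = AlphaBetaCalibrator(
                    fit_intercept=opts.calibration_intercept).fit(phi_p, phi_c)
            except Exception as exc:
                raise StageError("calibration", f"{g}: {exc}",
                                 rows["record_id"]) from exc
        alpha_beta = {g: calibration[g].alpha_beta_ for g in genotypes}
    else:
        alpha_beta = {g: opts.alpha_beta for g in genotypes}

    params = {
        g: PhotoParams(gamma_star=gamma_rd[g][0], Rd=gamma_rd[g][1],
                       Vcmax=100.0, alpha_beta=alpha_beta[g])
        for g in genotypes
    }

    # ---- per-point variable-J mesophyll conductance -----------------------
    out_frames = []
    for g in genotypes:
        rows = corrected[(corrected["genotype"] == g)
                         & corrected["protocol_tag"].isin(["steady", "aci"])]
        if rows.empty:
            continue
        rows = rows.copy()
        phi = phi_psii(rows["Fs"].to_numpy(), rows["Fm_prime"].to_numpy())
        rows["Jf"] = electron_transport(phi, rows["PPFD"].to_numpy(),
                                        alpha_beta[g])
        try:
            out_frames.append(harley_gm_table(rows, params[g],
                                              opts.gm_ceiling))
        except Exception as exc:
            raise StageError("gm", f"{g}: {exc}", rows["record_id"]) from exc
    gm_records = (pd.concat(out_frames, ignore_index=True) if out_frames
                  else corrected.iloc[0:0].copy())

    # ---- day-level table: mean channels per leaf-day, then inversion ------
    day_rows = []
    steady = gm_records[gm_records["protocol_tag"] == "steady"]
    for (g, day), grp in steady.groupby(["genotype", "day"]):
        mean = grp[["A", "Ci", "Jf", "gs_h2o", "RWC"]].mean()
        est = harley_gm_day(grp["A"].to_numpy(), grp["Ci"].to_numpy(),
                            grp["Jf"].to_numpy(), params[g],
                            opts.gm_ceiling, jackknife=opts.gm_jackknife)
        day_rows.append({
            "genotype": g, "day": day, "RWC": mean["RWC"],
            "A": mean["A"], "Ci": mean["Ci"], "gs_h2o": mean["gs_h2o"],
            "Jf": mean["Jf"], "gm": est.gm, "Cc": est.Cc,
            "valid": est.valid, "reason": est.reason,
            "WUEi": wue_intrinsic(mean["A"], mean["gs_h2o"]),
        })
    day_table = pd.DataFrame(day_rows).sort_values(
        ["genotype", "day"]).reset_index(drop=True)
    day_table["stress_class"] = classify_series(
        day_table["RWC"].to_numpy()).to_numpy()

    # ---- Vcmax fits on the A/Ci initial slope -----------------------------
    vc_rows = []
    aci = gm_records[gm_records["protocol_tag"] == "aci"]
    for (g, day), grp in aci.groupby(["genotype", "day"]):
        reg = VcmaxRegression(params=params[g],
                              ci_ceiling=opts.vcmax_ci_ceiling,
                              use_rd=opts.vcmax_use_rd,
                              basis=opts.vcmax_basis)
        if opts.vcmax_basis == "cc":
            sub = grp[grp["valid"]]
            cx = sub["Cc"].to_numpy()
            a = sub["A"].to_numpy()
        else:
            cx = grp["Ci"].to_numpy()
            a = grp["A"].to_numpy()
        try:
            reg.fit(cx, a)
        except Exception as exc:
            raise StageError("vcmax", f"{g} day {day}: {exc}",
                             grp["record_id"]) from exc
        vc_rows.append({"genotype": g, "day": day, "vcmax": reg.vcmax_,
                        "vcmax_se": reg.vcmax_se_, "n_points": reg.n_points_,
                        "failed": reg.failed_})
    vcmax_table = pd.DataFrame(vc_rows).sort_values(
        ["genotype", "day"]).reset_index(drop=True)

    # ---- limitation partitioning ------------------------------------------
    states = day_table.merge(vcmax_table[["genotype", "day", "vcmax"]],
                             on=["genotype", "day"], how="inner")
    states = states[states["valid"]].copy()
    states["gamma_star"] = [params[g].gamma_star for g in states["genotype"]]
    states["Rd"] = [params[g].Rd for g in states["genotype"]]
    states = states.rename(columns={"vcmax": "Vcmax"})
    ww_ref = (states.sort_values("day").groupby("genotype", as_index=False)
              .first()[["genotype", "gs_h2o", "gm", "Vcmax"]])
    try:
        limits = limitation_table(states, ca_ref=opts.ca_ref,
                                  ww_reference=ww_ref)
    except Exception as exc:
        raise StageError("limits", str(exc)) from exc

    # ---- summaries and empirical regressions ------------------------------
    try:
        pooled = group_summary(day_table, ["A", "gs_h2o", "gm", "WUEi"],
                               by=("stress_class",), cv_basis=opts.cv_basis)
        by_gen = group_summary(day_table, ["A", "gs_h2o", "gm", "WUEi"],
                               by=("stress_class", "genotype"),
                               cv_basis=opts.cv_basis)
    except Exception as exc:
        raise StageError("summarize", str(exc)) from exc

    regressions = {}
    valid_days = day_table[day_table["valid"]]
    for g in genotypes:
        sub = valid_days[valid_days["genotype"] == g]
        if len(sub) >= 4:
            regressions[f"gs_vs_rwc_{g}"] = fit_empirical(
                sub["RWC"], sub["gs_h2o"], family="polynomial2")
            regressions[f"a_vs_gm_{g}"] = fit_empirical(
                sub["gm"], sub["A"], family="logarithmic")
    if len(valid_days) >= 5:
        regressions["gm_vs_gs_pooled"] = fit_empirical(
            valid_days["gs_h2o"], valid_days["gm"],
            family="polynomial3_through_origin")

    manifest = _manifest(opts, genotypes, leak, gamma_rd, alpha_beta,
                         n_records=len(records))
    recovery = _recovery(gm_records, day_table, vcmax_table, laisk,
                         alpha_beta, truth) if truth is not None else None

    result = PipelineResult(
        leak={g: asdict(leak[g]) for g in leak},
        laisk=laisk, calibration=calibration, params=params,
        records=gm_records, day_table=day_table, vcmax_table=vcmax_table,
        limitations=limits, summary_pooled=pooled,
        summary_by_genotype=by_gen, regressions=regressions,
        manifest=manifest, recovery=recovery,
    )
    if outdir is not None:
        _write_report(result, outdir)
    return result


def _manifest(opts, genotypes, leak, gamma_rd, alpha_beta, n_records):
    versions = {"mesocon": __version__,
                "numpy": np.__version__, "pandas": pd.__version__}
    return {
        "versions": versions,
        "options": asdict(opts),
        "genotypes": list(genotypes),
        "n_records": n_records,
        "leak": {g: asdict(leak[g]) for g in leak},
        "gamma_star_rd": {g: list(v) for g, v in gamma_rd.items()},
        "alpha_beta": dict(alpha_beta),
    }


def _recovery(gm_records, day_table, vcmax_table, laisk, alpha_beta, truth):
    """Parameter-recovery scores against a simulation's ground-truth ledger."""
    rows = []
    merged = gm_records.merge(truth, on="record_id", suffixes=("", "_t"))
    steady = merged[(merged["protocol_tag"] == "steady") & merged["valid"]]
    if not steady.empty:
        rel = np.abs(steady["gm"] - steady["gm_true"]) / steady["gm_true"]
        rows.append({"parameter": "gm", "n": len(steady),
                     "max_rel_error": float(rel.max()),
                     "mean_rel_error": float(rel.mean())})
    truth_gd = truth.dropna(subset=["vcmax_true"]).groupby(
        ["genotype", "day"])["vcmax_true"].first().reset_index()
    vc = vcmax_table.merge(truth_gd, on=["genotype", "day"])
    if not vc.empty:
        rel = np.abs(vc["vcmax"] - vc["vcmax_true"]) / vc["vcmax_true"]
        rows.append({"parameter": "vcmax", "n": len(vc),
                     "max_rel_error": float(rel.max()),
                     "mean_rel_error": float(rel.mean())})
    lt = truth[truth["protocol_tag"] == "laisk"]
    if laisk and not lt.empty:
        errs_ci, errs_rd = [], []
        for g, res in laisk.items():
            sub = lt[lt["genotype"] == g]
            if sub.empty:
                continue
            errs_ci.append(abs(res.ci_star - sub["ci_star"].iloc[0])
                           / sub["ci_star"].iloc[0])
            errs_rd.append(abs(res.rd - sub["rd"].iloc[0])
                           / sub["rd"].iloc[0])
        if errs_ci:
            rows.append({"parameter": "ci_star", "n": len(errs_ci),
                         "max_rel_error": float(np.max(errs_ci)),
                         "mean_rel_error": float(np.mean(errs_ci))})
            rows.append({"parameter": "rd", "n": len(errs_rd),
                         "max_rel_error": float(np.max(errs_rd)),
                         "mean_rel_error": float(np.mean(errs_rd))})
    ab_t = truth.dropna(subset=["alpha_beta"]) if "alpha_beta" in truth else None
    if ab_t is not None and not ab_t.empty:
        errs = [abs(alpha_beta[g] - ab_t[ab_t["genotype"] == g]
                    ["alpha_beta"].iloc[0]) / ab_t[ab_t["genotype"] == g]
                ["alpha_beta"].iloc[0]
                for g in alpha_beta if not ab_t[ab_t["genotype"] == g].empty]
        if errs:
            rows.append({"parameter": "alpha_beta", "n": len(errs),
                         "max_rel_error": float(np.max(errs)),
                         "mean_rel_error": float(np.mean(errs))})
    return pd.DataFrame(rows)


def _write_report(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_records(result.records, outdir / "records_with_gm.tsv")
    write_table(result.day_table, outdir / "day_table.tsv")
    write_table(result.vcmax_table, outdir / "vcmax.tsv")
    write_table(result.limitations, outdir / "limitations.tsv")
    write_table(result.summary_pooled, outdir / "summary_pooled.tsv")
    write_table(result.summary_by_genotype, outdir / "summary_by_genotype.tsv")
    if result.recovery is not None:
        write_table(result.recovery, outdir / "recovery.tsv")
    laisk_rows = [{"genotype": g, "ci_star": r.ci_star, "rd": r.rd,
                   "dispersion": r.dispersion,
                   "slopes": ";".join(f"{s:.8g}" for s in r.slopes)}
                  for g, r in result.laisk.items()]
    if laisk_rows:
        write_table(pd.DataFrame(laisk_rows), outdir / "laisk.tsv")
    reg_rows = [{"name": name,
                 "family": reg.family,
                 "coefficients": ";".join(f"{c:.10g}" for c in reg.coef_),
                 "r_squared": reg.r_squared_}
                for name, reg in result.regressions.items()]
    if reg_rows:
        write_table(pd.DataFrame(reg_rows), outdir / "regressions.tsv")
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
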