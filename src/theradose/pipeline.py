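"""End-to-end orchestration: synthetic cohort (or CSV inputs) to reports.

Stages: biodistribution summary -> time-activity fits -> absorbed-dose
table -> efficacy/survival report, plus a provenance manifest.  Stages are
pure with respect to files: each reads its inputs and writes its own
outputs without mutating anything upstream.  Outputs are deterministic for
a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biodistribution import (records_from_frame, records_to_frame, summarize,
                              tumour_to_organ_ratio)
from .config import RunConfig, SyntheticConfig, default_config
from .dosimetry import (assemble_dose_table, blood_local_dose, organ_dose,
                        sphere_self_svalue)
from .efficacy import doubling_time, km_estimator, logrank_test, max_volume_reduction
from .kinetics import cumulated_activity, fit_tac, select_model
from .nuclide import cu64
from .simulate import gen_biodistribution, gen_survival, gen_tumour_growth

__all__ = ["run_pipeline"]

log = logging.getLogger("theradose")

_ALL_STAGES = ("simulate", "biodist", "kinetics", "dosimetry", "efficacy", "report")


def _fit_organ(df: pd.DataFrame, organ: str, seed: int):
    """Candidate fits (mono, plateau, bi where identifiable) + AICc selection."""
    sub = df[df["organ"] == organ].sort_values("timepoint_h")
    t = sub["timepoint_h"].to_numpy()
    y = sub["mean_pid_g"].to_numpy()
    candidates = []
    for model in ("mono", "plateau_uptake", "bi"):
        need = 4 if model == "bi" else 2
        if t.size < need:
            continue
        try:
            tac = fit_tac((t, y), model, seed=seed)
        except (RuntimeError, ValueError):
            continue
        tac.organ = organ
        candidates.append(tac)
    return select_model(candidates)


def run_pipeline(config: RunConfig,
                 synthetic_config: SyntheticConfig | None = None,
                 stages: set[str] | None = None) -> dict[str, str]:
    """Run the analysis end to end; returns {output name: file path}.

    ``stages`` restricts which report files are written; prerequisites are
    always computed.  Any stage failure raises with a stage-tagged message.
    """
    stages = set(_ALL_STAGES) if stages is None else stages
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    nuclide = cu64()
    scfg = synthetic_config or default_config(seed=config.seed)
    written: dict[str, str] = {}

    def _stage(name):
        log.info("stage %s", name)

    # --- inputs -------------------------------------------------------------
    _stage("biodist")
    try:
        if config.synthetic:
            records = (gen_biodistribution(scfg, config.seed, "healthy", nuclide)
                       + gen_biodistribution(scfg, config.seed, "tumour_bearing", nuclide))
        else:
            if not config.biodist_csv:
                raise ValueError("biodist_csv required when synthetic=False")
            records = records_from_frame(pd.read_csv(config.biodist_csv))
    except Exception as exc:
        raise RuntimeError(f"[biodist] {exc}") from exc

    if "simulate" in stages and config.synthetic:
        p = out / "biodistribution_records.csv"
        records_to_frame(records).to_csv(p, index=False)
        written["biodistribution_records"] = str(p)

    summary = summarize(records, nuclide)
    if "biodist" in stages:
        p = out / "biodistribution_summary.csv"
        summary.to_csv(p, index=False)
        written["biodistribution_summary"] = str(p)

    # --- kinetics -----------------------------------------------------------
    _stage("kinetics")
    tb = summary[summary["group"] == "tumour_bearing"]
    fits = {}
    a_tilde = {}
    try:
        for organ in sorted(tb["organ"].unique()):
            tac = _fit_organ(tb, organ, seed=config.seed)
            fits[organ] = tac
            t_last = float(tb[tb["organ"] == organ]["timepoint_h"].max())
            a_tilde[organ] = cumulated_activity(
                tac, nuclide, extrapolation=config.extrapolation,
                t_last_h=t_last if config.extrapolation != "model" else None)
    except Exception as exc:
        raise RuntimeError(f"[kinetics] {exc}") from exc

    if "kinetics" in stages:
        p = out / "tac_fits.json"
        payload = {
            organ: {
                "model": tac.model, "a1": tac.a1, "lambda1": tac.lambda1,
                "a2": tac.a2, "lambda2": tac.lambda2, "rss": tac.rss,
                "n_points": tac.n_points,
                "a_tilde_mbq_s_per_g": a_tilde[organ].a_tilde_mbq_s_per_g,
            }
            for organ, tac in fits.items()
        }
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written["tac_fits"] = str(p)

    # --- dosimetry ----------------------------------------------------------
    _stage("dosimetry")
    try:
        masses = dict(scfg.biodist.organ_masses_g)
        masses["tumour"] = config.tumour_mass_g
        doses = {}
        for organ, at in a_tilde.items():
            if organ == "blood":
                doses[organ] = blood_local_dose(
                    at.a_tilde_mbq_s_per_g, nuclide, energy_mode=config.energy_mode)
            else:
                sv = sphere_self_svalue(masses[organ], nuclide,
                                        method=config.svalue_method,
                                        mc_params={"seed": config.seed})
                doses[organ] = organ_dose(at, sv)
        report = assemble_dose_table(doses, config.administered_activity_mbq)
    except Exception as exc:
        raise RuntimeError(f"[dosimetry] {exc}") from exc

    if "dosimetry" in stages:
        p = out / "dose_table.tsv"
        df = report.to_dataframe()
        df.to_csv(p, sep="\t", index=False)
        written["dose_table"] = str(p)
        pj = out / "dose_table.json"
        pj.write_text(json.dumps({
            "administered_activity_mbq": config.administered_activity_mbq,
            "self_dose_only": True,
            "svalue_method": config.svalue_method,
            "energy_mode_blood": config.energy_mode,
            "rows": report.rows,
            "tumour_to_liver_ratio": tumour_to_organ_ratio(
                report.row("tumour")["gy_at_admin_unrounded"],
                report.row("liver")["gy_at_admin_unrounded"]),
        }, indent=1, sort_keys=True))
        written["dose_table_json"] = str(pj)

    # --- efficacy / survival --------------------------------------------------
    _stage("efficacy")
    try:
        eff: dict = {"groups": {}}
        for group in scfg.growth:
            series = gen_tumour_growth(scfg, config.seed, group)
            gp = scfg.growth[group]
            window = (gp.first_dose_day, gp.second_dose_day)
            dts = []
            for s in series:
                try:
                    dt = doubling_time(s, window)
                except ValueError:
                    continue
                if np.isfinite(dt):
                    dts.append(dt)
            entry = {"n": gp.n,
                     "mean_doubling_time_days": float(np.mean(dts)) if dts else None}
            if gp.regression_fraction > 0:
                reds = [max_volume_reduction(s, gp.second_dose_day) for s in series]
                entry["mean_max_volume_reduction_pct"] = float(np.mean(reds))
            eff["groups"][group] = entry
        surv = {}
        km_records = {}
        for group in scfg.survival:
            recs = gen_survival(scfg, config.seed, group)
            km_records[group] = recs
            _, median = km_estimator(recs)
            surv[group] = {"n": scfg.survival[group].n,
                           "km_median_days": None if np.isnan(median) else median}
        chi2, pval = logrank_test(km_records["repeated_35"], km_records["saline"])
        eff["survival"] = surv
        eff["logrank_repeated_35_vs_saline"] = {"chi2": chi2, "p": pval}
    except Exception as exc:
        raise RuntimeError(f"[efficacy] {exc}") from exc

    if "efficacy" in stages:
        p = out / "efficacy_report.json"
        p.write_text(json.dumps(eff, indent=1, sort_keys=True))
        written["efficacy_report"] = str(p)

    # --- manifest -------------------------------------------------------------
    if "report" in stages:
        p = out / "manifest.json"
        p.write_text(json.dumps({
            "package": "theradose",
            "version": __version__,
            "seed": config.seed,
            "administered_activity_mbq": config.administered_activity_mbq,
            "energy_mode": config.energy_mode,
            "svalue_method": config.svalue_method,
            "extrapolation": config.extrapolation,
            "tumour_mass_g": config.tumour_mass_g,
            "nuclide": nuclide.name,
            "decay_data_citation": nuclide.source_citation,
            "self_dose_only": True,
            "outputs": sorted(written),
        }, indent=1, sort_keys=True))
        written["manifest"] = str(p)

    return written
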