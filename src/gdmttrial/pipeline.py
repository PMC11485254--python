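"""End-to-end analysis: score every snapshot, then run the pre-specified
statistics and assemble a report mirroring the trial's tables.

The pipeline is deterministic given the data, the dose table and the seed
(the seed only feeds the subgroup bootstrap).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, EstimationError
from .scoring import (
    Basis,
    Component,
    DoseTable,
    default_dose_table,
    delta_gdmt,
    gdmt_score,
    time_to_omt,
)
from .simulate import TrialDataset
from .io import load_dataset
from .stats import (
    EffectEstimate,
    chi_square_2x2,
    consult_rate_test,
    cox_time_to_omt,
    cumulative_incidence,
    nps_summary,
    percent,
    rank_sum_effect,
    subgroup_analysis,
)

log = logging.getLogger("gdmttrial")

__all__ = ["RunConfig", "AnalysisReport", "score_dataset", "analyze_dataset",
           "run_pipeline", "DEFAULT_SUBGROUPS"]

#: label -> column of the per-patient score frame used for subgroup splits
DEFAULT_SUBGROUPS = {
    "new-onset HF": "new_onset",
    "eGFR >= median": "egfr_ge_median",
    "age >= median": "age_ge_median",
    "NYHA III": "nyha3",
    "ischemic etiology": "ischemic",
    "nurse support": "nurse_support",
    "academic center": "academic",
}

_CONTINUOUS = (Component.RASI_DOSE, Component.BB_DOSE, Component.MRA_DOSE)
_BINARY = (Component.ARNI_SWITCH, Component.SGLT2I, Component.IRON)


@dataclass(frozen=True)
class RunConfig:
    """Paths, seed and analysis toggles for one pipeline run."""

    data_dir: str
    out_dir: Optional[str] = None
    dose_table_path: Optional[str] = None
    seed: int = 0
    alpha: float = 0.05
    bootstrap_b: int = 1000
    continuity_correction: bool = False
    omt_components: Optional[tuple] = None  # None = all six
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.bootstrap_b < 2:
            raise ConfigError("bootstrap_b must be >= 2")
        if not Path(self.data_dir).exists():
            raise ConfigError(f"data_dir does not exist: {self.data_dir}")
        if self.dose_table_path is not None and not Path(self.dose_table_path).exists():
            raise ConfigError(f"dose table not found: {self.dose_table_path}")


def score_dataset(dataset: TrialDataset, table: Optional[DoseTable] = None,
                  omt_components=None) -> pd.DataFrame:
    """One row per patient: scores, endpoints and analysis covariates."""
    if table is None:
        table = default_dose_table()
    rows = []
    for p in dataset.patients:
        base = gdmt_score(p.trajectory[0], table)
        final = gdmt_score(p.trajectory[-1], table)
        horizon = p.censor_day
        t_omt, omt_event = time_to_omt(p.trajectory, table, horizon=horizon,
                                       omt_components=omt_components)
        row = {
            "patient_id": p.id, "arm": p.arm, "new_onset": p.new_onset,
            "hospital": p.hospital, "academic": p.hospital.startswith("academic"),
            "age": p.age, "nyha3": p.nyha_class >= 3, "ischemic": p.ischemic,
            "nurse_support": p.nurse_support,
            "egfr_baseline": p.trajectory[0].labs.egfr,
            "baseline_score": base.total, "final_score": final.total,
            "delta_gdmt": delta_gdmt(base, final),
            "omt_time": t_omt, "omt_event": omt_event,
            "omt_baseline": all(c.value == 1.0 for c in base.components),
            "n_remote": sum(c.type == "remote" for c in p.consults),
            "n_physical": sum(c.type == "physical" for c in p.consults),
            "hospitalizations": p.hospitalizations,
            "hyperkalemia_events": p.hyperkalemia_events,
            "low_egfr_events": p.low_egfr_events,
            "kccq_delta": p.kccq_12wk - p.kccq_baseline,
            "nps_delta": p.nps_12wk - p.nps_baseline,
            "nps_12wk": p.nps_12wk,
            "time_spent_h": p.time_spent_h,
            "completed": p.completed,
        }
        for c in base.components:
            row[f"base_{c.component.value}"] = c.value
        for c in final.components:
            row[f"final_{c.component.value}"] = c.value
            row[f"final_basis_{c.component.value}"] = c.basis.value
        rows.append(row)
    df = pd.DataFrame(rows)
    df["egfr_ge_median"] = df["egfr_baseline"] >= df["egfr_baseline"].median()
    df["age_ge_median"] = df["age"] >= df["age"].median()
    return df


def _component_table(scores: pd.DataFrame, alpha: float) -> list:
    """Per-component arm summaries in the layout of the trial's score table."""
    out = []
    dc = scores[scores.arm == "DC"]
    uc = scores[scores.arm == "USUAL"]
    for comp in Component:
        name = comp.value
        inc_dc = dc[f"final_{name}"] - dc[f"base_{name}"]
        inc_uc = uc[f"final_{name}"] - uc[f"base_{name}"]
        eff = rank_sum_effect(inc_uc, inc_dc, alpha=alpha)
        entry = {"component": name, "p_value": eff.p_value}
        if comp in _CONTINUOUS:
            for label, arm in (("dc", dc), ("usual", uc)):
                entry[label] = {
                    "baseline_mean": float(arm[f"base_{name}"].mean()),
                    "baseline_sd": float(arm[f"base_{name}"].std(ddof=1)),
                    "followup_mean": float(arm[f"final_{name}"].mean()),
                    "followup_sd": float(arm[f"final_{name}"].std(ddof=1)),
                    "increase_mean": float((arm[f"final_{name}"] - arm[f"base_{name}"]).mean()),
                    "increase_sd": float((arm[f"final_{name}"] - arm[f"base_{name}"]).std(ddof=1)),
                }
        else:
            for label, arm in (("dc", dc), ("usual", uc)):
                n = len(arm)
                b = int((arm[f"base_{name}"] == 1.0).sum())
                f = int((arm[f"final_{name}"] == 1.0).sum())
                newly = int(((arm[f"base_{name}"] < 1.0)
                             & (arm[f"final_{name}"] == 1.0)).sum())
                entry[label] = {
                    "baseline_n": b, "baseline_pct": percent(b, n),
                    "followup_n": f, "followup_pct": percent(f, n),
                    "increase_n": newly, "increase_pct": percent(newly, n),
                }
        out.append(entry)
    return out


def _safety_row(scores: pd.DataFrame, col: str, continuity: bool) -> dict:
    dc = scores[scores.arm == "DC"]
    uc = scores[scores.arm == "USUAL"]
    a = int((dc[col] > 0).sum())
    c = int((uc[col] > 0).sum())
    try:
        stat, p = chi_square_2x2(a, len(dc) - a, c, len(uc) - c,
                                 continuity=continuity)
    except EstimationError:
        stat, p = float("nan"), float("nan")
    return {"dc_n": a, "usual_n": c, "dc_events": int(dc[col].sum()),
            "usual_events": int(uc[col].sum()), "chi2": stat, "p_value": p}


@dataclass(frozen=True)
class AnalysisReport:
    primary: EffectEstimate
    component_table: list
    omt: dict
    time_to_omt: dict
    consult_rates: dict
    safety: dict
    patient_reported: dict
    nps_patients: dict
    subgroups: list
    provenance: dict

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="list")
            return obj
        return enc(dataclasses.asdict(self))

    def to_json(self, path=None, indent: int = 1) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        pr = self.primary
        lines = [
            "# Trial analysis report",
            "",
            "## Primary endpoint: change in GDMT score (follow-up - baseline)",
            "",
            f"- DC arm: median {pr.median_b:.2f} (IQR {pr.iqr_b[0]:.2f}, "
            f"{pr.iqr_b[1]:.2f}), n={pr.n_b}",
            f"- Usual care: median {pr.median_a:.2f} (IQR {pr.iqr_a[0]:.2f}, "
            f"{pr.iqr_a[1]:.2f}), n={pr.n_a}",
            f"- Hodges-Lehmann shift {pr.shift:.2f} "
            f"(95% CI {pr.ci_low:.2f}, {pr.ci_high:.2f}); "
            f"Mann-Whitney p = {pr.p_value:.4g}",
            "",
            "## Score components (baseline / follow-up / increase)",
            "",
            "| Component | Arm | Baseline | Follow-up | Increase | p |",
            "|---|---|---|---|---|---|",
        ]
        for entry in self.component_table:
            for label, arm in (("dc", "DC"), ("usual", "usual care")):
                e = entry[label]
                if "baseline_mean" in e:
                    cells = (f"{e['baseline_mean']:.2f} (±{e['baseline_sd']:.2f})",
                             f"{e['followup_mean']:.2f} (±{e['followup_sd']:.2f})",
                             f"{e['increase_mean']:.2f} (±{e['increase_sd']:.2f})")
                else:
                    cells = (f"{e['baseline_n']} ({e['baseline_pct']}%)",
                             f"{e['followup_n']} ({e['followup_pct']}%)",
                             f"{e['increase_n']} ({e['increase_pct']}%)")
                ptxt = f"{entry['p_value']:.3f}" if label == "usual" else ""
                lines.append(f"| {entry['component']} | {arm} | "
                             + " | ".join(cells) + f" | {ptxt} |")
        omt = self.omt
        lines += [
            "",
            "## Secondary endpoints",
            "",
            f"- OMT at 12 weeks: DC {omt['dc_n']} ({omt['dc_pct']}%) vs usual "
            f"care {omt['usual_n']} ({omt['usual_pct']}%), p = {omt['p_value']:.4g}",
        ]
        tt = self.time_to_omt
        if "hazard_ratio" in tt:
            lines.append(
                f"- Time to OMT: HR {tt['hazard_ratio']:.2f} "
                f"(95% CI {tt['ci_low']:.2f}, {tt['ci_high']:.2f}), "
                f"p = {tt['p_value']:.4g} ({tt['n_events']} events)")
        else:
            lines.append(f"- Time to OMT: {tt['note']}")
        for kind, res in self.consult_rates.items():
            lines.append(
                f"- {kind.capitalize()} consults: rate ratio "
                f"{res['rate_ratio']:.2f} (95% CI {res['ci_low']:.2f}, "
                f"{res['ci_high']:.2f}), p = {res['p_value']:.3f} "
                f"[{res['model_used']}]")
        for label, row in self.safety.items():
            lines.append(
                f"- Safety, {label}: DC {row['dc_n']} vs usual {row['usual_n']} "
                f"patients (p = {row['p_value']:.3f})")
        for label, eff in self.patient_reported.items():
            lines.append(
                f"- {label}: DC median {eff['median_b']:.2f} vs usual "
                f"{eff['median_a']:.2f}, p = {eff['p_value']:.3f}")
        np_ = self.nps_patients
        lines += [
            f"- Patient NPS at 12 weeks: {np_['nps']:.1f} "
            f"({np_['promoters']} promoters / {np_['passives']} passives / "
            f"{np_['detractors']} detractors; mean rating "
            f"{np_['mean_score']:.1f})",
            "",
            "## Subgroups (Hodges-Lehmann shift in / out; interaction p)",
            "",
            "| Subgroup | Shift in | Shift out | Interaction p |",
            "|---|---|---|---|",
        ]
        for sg in self.subgroups:
            lines.append(
                f"| {sg.label} | {sg.effect_in.shift:.2f} | "
                f"{sg.effect_out.shift:.2f} | {sg.interaction_p:.3f} |")
        lines += ["", "## Provenance", ""]
        for k in ("seed", "alpha", "bootstrap_b", "package_version",
                  "config_sha256"):
            lines.append(f"- {k}: {self.provenance.get(k)}")
        return "\n".join(lines) + "\n"


def analyze_dataset(dataset: TrialDataset, table: Optional[DoseTable] = None,
                    seed: int = 0, alpha: float = 0.05,
                    bootstrap_b: int = 1000,
                    continuity_correction: bool = False,
                    omt_components=None,
                    subgroups: Optional[dict] = None) -> AnalysisReport:
    """The full pre-specified analysis on an in-memory dataset."""
    if table is None:
        table = default_dose_table()
    scores = score_dataset(dataset, table, omt_components=omt_components)
    log.info("scored %d patients (%d DC / %d usual care)", len(scores),
             (scores.arm == "DC").sum(), (scores.arm == "USUAL").sum())
    dc = scores[scores.arm == "DC"]
    uc = scores[scores.arm == "USUAL"]

    primary = rank_sum_effect(uc["delta_gdmt"], dc["delta_gdmt"], alpha=alpha)
    log.info("primary endpoint: shift %.3f p %.4g", primary.shift,
             primary.p_value)
    components = _component_table(scores, alpha)

    omt_dc = int(dc["omt_event"].sum())
    omt_uc = int(uc["omt_event"].sum())
    try:
        _, omt_p = chi_square_2x2(omt_dc, len(dc) - omt_dc,
                                  omt_uc, len(uc) - omt_uc,
                                  continuity=continuity_correction)
    except EstimationError:
        omt_p = float("nan")
    omt = {"dc_n": omt_dc, "dc_pct": percent(omt_dc, len(dc)),
           "usual_n": omt_uc, "usual_pct": percent(omt_uc, len(uc)),
           "p_value": omt_p}

    # patients already at OMT on day 0 were never at risk of the event
    at_risk = scores[~scores["omt_baseline"]]
    try:
        cox = cox_time_to_omt(
            np.maximum(at_risk["omt_time"].to_numpy(dtype=float), 0.5),
            at_risk["omt_event"].to_numpy(dtype=bool),
            (at_risk["arm"] == "DC").to_numpy(dtype=float), alpha=alpha)
        tt = {"hazard_ratio": cox.hazard_ratio, "ci_low": cox.ci_low,
              "ci_high": cox.ci_high, "p_value": cox.p_value,
              "log_hr": cox.log_hr, "se": cox.se, "n_events": cox.n_events,
              "n_at_risk": len(at_risk)}
        incidence = {
            arm: cumulative_incidence(
                np.maximum(grp["omt_time"].to_numpy(dtype=float), 0.5),
                grp["omt_event"], alpha=alpha).to_dict(orient="list")
            for arm, grp in at_risk.groupby("arm")}
        tt["cumulative_incidence"] = incidence
    except EstimationError as err:
        tt = {"note": f"not estimable: {err}"}
    consult_rates = {}
    for kind, col in (("remote", "n_remote"), ("physical", "n_physical")):
        try:
            r = consult_rate_test(uc[col], dc[col], alpha=alpha)
            consult_rates[kind] = dataclasses.asdict(r)
        except EstimationError as err:
            consult_rates[kind] = {"note": f"not estimable: {err}"}
    safety = {
        "hyperkalemia (K > 5.0)": _safety_row(scores, "hyperkalemia_events",
                                              continuity_correction),
        "eGFR < 30": _safety_row(scores, "low_egfr_events",
                                 continuity_correction),
        "hospitalization": _safety_row(scores, "hospitalizations",
                                       continuity_correction),
    }
    patient_reported = {
        label: dataclasses.asdict(rank_sum_effect(uc[col], dc[col], alpha=alpha))
        for label, col in (("KCCQ-12 change", "kccq_delta"),
                           ("satisfaction (NPS) change", "nps_delta"),
                           ("time spent on healthcare (h)", "time_spent_h"))
    }
    nps_pat = dataclasses.asdict(nps_summary(scores["nps_12wk"]))
    sg = subgroup_analysis(scores, "delta_gdmt", "arm",
                           subgroups or DEFAULT_SUBGROUPS,
                           n_boot=bootstrap_b, seed=seed, alpha=alpha)
    log.info("subgroup analysis: %d splits evaluated", len(sg))
    config_text = json.dumps(dataset.config.to_dict(), sort_keys=True)
    provenance = {
        "seed": seed, "alpha": alpha, "bootstrap_b": bootstrap_b,
        "continuity_correction": continuity_correction,
        "omt_components": (None if omt_components is None
                           else [c.value for c in omt_components]),
        "package_version": __version__,
        "n_patients": len(dataset.patients),
        "sim_config": dataset.config.to_dict(),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
    }
    return AnalysisReport(
        primary=primary, component_table=components, omt=omt, time_to_omt=tt,
        consult_rates=consult_rates, safety=safety,
        patient_reported=patient_reported, nps_patients=nps_pat,
        subgroups=sg, provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Load a dataset directory, analyze it, and (optionally) write outputs."""
    logging.basicConfig(level=config.log_level)
    table = (DoseTable.from_json(config.dose_table_path)
             if config.dose_table_path else default_dose_table())
    dataset = load_dataset(config.data_dir)
    log.info("loaded %d patients from %s", len(dataset.patients),
             config.data_dir)
    omt_components = (None if config.omt_components is None
                      else tuple(Component(c) for c in config.omt_components))
    report = analyze_dataset(
        dataset, table, seed=config.seed, alpha=config.alpha,
        bootstrap_b=config.bootstrap_b,
        continuity_correction=config.continuity_correction,
        omt_components=omt_components)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        (out / "report.md").write_text(report.to_markdown())
        rows = []
        for sg in report.subgroups:
            rows.append({
                "subgroup": sg.label,
                "shift_in": sg.effect_in.shift, "se_in": sg.se_in,
                "ci_low_in": sg.effect_in.ci_low, "ci_high_in": sg.effect_in.ci_high,
                "p_in": sg.effect_in.p_value,
                "shift_out": sg.effect_out.shift, "se_out": sg.se_out,
                "ci_low_out": sg.effect_out.ci_low,
                "ci_high_out": sg.effect_out.ci_high,
                "p_out": sg.effect_out.p_value,
                "interaction_t": sg.interaction_t,
                "interaction_p": sg.interaction_p,
            })
        pd.DataFrame(rows).to_csv(out / "subgroups.csv", index=False)
        log.info("wrote report.json, report.md, subgroups.csv to %s", out)
    return report
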