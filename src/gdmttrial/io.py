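"""Tidy on-disk schema for trial datasets.

A dataset directory holds six CSV files plus a JSON provenance record:

``patients.csv``
    one row per patient: allocation, stratum, covariates, questionnaires,
    safety counters, completion status.
``labs.csv``
    one row per snapshot (its ``day`` defines the snapshot grid).
``prescriptions.csv``
    rows keyed by (patient_id, day) matching snapshot days.
``vitals.csv``
    home/office readings; a snapshot's history is every reading <= its day.
``iron.csv``
    iron screening state attached to each snapshot day.
``consults.csv``
    one row per consult (remote/physical).
``config.json``
    the full simulation/provenance configuration.

Day indices are integers with day 0 = baseline.  All loaders re-validate
the type invariants and raise :class:`~gdmttrial.errors.DataError` naming
the file, row and field at fault.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError
from .scoring import (
    DrugClass,
    IronStatus,
    LabPanel,
    PatientSnapshot,
    Prescription,
    VitalsReading,
)
from .simulate import Consult, SimConfig, TrialDataset, TrialPatient

__all__ = ["write_dataset", "load_dataset", "FILES"]

FILES = (
    "patients.csv",
    "labs.csv",
    "prescriptions.csv",
    "vitals.csv",
    "iron.csv",
    "consults.csv",
    "config.json",
)

_PATIENT_COLUMNS = [
    "patient_id", "arm", "new_onset", "hospital", "age", "nyha_class",
    "ischemic", "nurse_support", "completed", "censor_day",
    "hospitalizations", "hyperkalemia_events", "low_egfr_events",
    "kccq_baseline", "kccq_12wk", "nps_baseline", "nps_12wk",
    "time_spent_h", "allergies", "symptomatic_hypotension",
]


def _none_if_nan(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def write_dataset(dataset: TrialDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, labs, rx, vitals, iron, consults = [], [], [], [], [], []
    for p in dataset.patients:
        patients.append({
            "patient_id": p.id, "arm": p.arm, "new_onset": p.new_onset,
            "hospital": p.hospital, "age": p.age, "nyha_class": p.nyha_class,
            "ischemic": p.ischemic, "nurse_support": p.nurse_support,
            "completed": p.completed, "censor_day": p.censor_day,
            "hospitalizations": p.hospitalizations,
            "hyperkalemia_events": p.hyperkalemia_events,
            "low_egfr_events": p.low_egfr_events,
            "kccq_baseline": p.kccq_baseline, "kccq_12wk": p.kccq_12wk,
            "nps_baseline": p.nps_baseline, "nps_12wk": p.nps_12wk,
            "time_spent_h": p.time_spent_h,
            "allergies": ";".join(sorted(c.value for c in p.trajectory[0].allergies)),
            "symptomatic_hypotension": p.trajectory[0].symptomatic_hypotension,
        })
        seen_vitals = set()
        for snap in p.trajectory:
            labs.append({
                "patient_id": p.id, "day": snap.day,
                "potassium": snap.labs.potassium, "egfr": snap.labs.egfr,
                "ferritin": snap.labs.ferritin, "tsat": snap.labs.tsat,
                "hb": snap.labs.hb, "measured_on": snap.labs.measured_on,
            })
            for presc in snap.prescriptions:
                rx.append({
                    "patient_id": p.id, "day": snap.day,
                    "drug_name": presc.drug_name,
                    "drug_class": presc.drug_class.value,
                    "daily_dose_mg": presc.daily_dose,
                })
            for v in snap.vitals_history:
                key = (v.day, v.systolic_bp, v.diastolic_bp, v.heart_rate, v.weight)
                if key not in seen_vitals:
                    seen_vitals.add(key)
                    vitals.append({
                        "patient_id": p.id, "day": v.day,
                        "systolic_bp": v.systolic_bp, "diastolic_bp": v.diastolic_bp,
                        "heart_rate": v.heart_rate, "weight": v.weight,
                    })
            iron.append({
                "patient_id": p.id, "day": snap.day,
                "screened_on": snap.iron.screened_on,
                "ferritin": snap.iron.ferritin, "tsat": snap.iron.tsat,
                "iv_iron_given": snap.iron.iv_iron_given,
            })
        for c in p.consults:
            consults.append({
                "patient_id": p.id, "day": c.day, "type": c.type,
                "summary_sent": c.summary_sent,
            })
    pd.DataFrame(patients, columns=_PATIENT_COLUMNS).to_csv(
        out / "patients.csv", index=False)
    pd.DataFrame(labs).to_csv(out / "labs.csv", index=False)
    pd.DataFrame(
        rx, columns=["patient_id", "day", "drug_name", "drug_class", "daily_dose_mg"]
    ).to_csv(out / "prescriptions.csv", index=False)
    pd.DataFrame(
        vitals, columns=["patient_id", "day", "systolic_bp", "diastolic_bp",
                         "heart_rate", "weight"]
    ).to_csv(out / "vitals.csv", index=False)
    pd.DataFrame(iron).to_csv(out / "iron.csv", index=False)
    pd.DataFrame(
        consults, columns=["patient_id", "day", "type", "summary_sent"]
    ).to_csv(out / "consults.csv", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataset.config.to_dict(), fh, indent=1)


def _read_csv(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise DataError(f"{name}: file missing from {directory}")
    return pd.read_csv(path)


def _require_columns(df: pd.DataFrame, name: str, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{name}: missing required column(s) {missing}")


def load_dataset(directory) -> TrialDataset:
    """Load and fully validate a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    patients_df = _read_csv(directory, "patients.csv")
    labs_df = _read_csv(directory, "labs.csv")
    rx_df = _read_csv(directory, "prescriptions.csv")
    vitals_df = _read_csv(directory, "vitals.csv")
    iron_df = _read_csv(directory, "iron.csv")
    consults_df = _read_csv(directory, "consults.csv")
    _require_columns(patients_df, "patients.csv", _PATIENT_COLUMNS)
    _require_columns(labs_df, "labs.csv",
                     ["patient_id", "day", "potassium", "egfr", "measured_on"])
    _require_columns(rx_df, "prescriptions.csv",
                     ["patient_id", "day", "drug_name", "drug_class", "daily_dose_mg"])
    _require_columns(vitals_df, "vitals.csv",
                     ["patient_id", "day", "systolic_bp", "diastolic_bp",
                      "heart_rate", "weight"])
    _require_columns(iron_df, "iron.csv",
                     ["patient_id", "day", "screened_on", "ferritin", "tsat",
                      "iv_iron_given"])
    _require_columns(consults_df, "consults.csv",
                     ["patient_id", "day", "type", "summary_sent"])
    config_path = directory / "config.json"
    if not config_path.exists():
        raise DataError(f"config.json: file missing from {directory}")
    config = SimConfig.from_json(config_path)

    labs_by = dict(tuple(labs_df.groupby("patient_id", sort=False)))
    rx_by = dict(tuple(rx_df.groupby("patient_id", sort=False)))
    vitals_by = dict(tuple(vitals_df.groupby("patient_id", sort=False)))
    iron_by = dict(tuple(iron_df.groupby("patient_id", sort=False)))
    consults_by = dict(tuple(consults_df.groupby("patient_id", sort=False)))

    patients = []
    for ridx, row in patients_df.iterrows():
        pid = row["patient_id"]
        if row["arm"] not in ("DC", "USUAL"):
            raise DataError(
                f"patients.csv row {ridx}: field 'arm' must be DC or USUAL, "
                f"got {row['arm']!r}")
        for q in ("nps_baseline", "nps_12wk"):
            if not 1 <= int(row[q]) <= 10:
                raise DataError(f"patients.csv row {ridx}: field {q!r} outside 1..10")
        for q in ("kccq_baseline", "kccq_12wk"):
            if not 0.0 <= float(row[q]) <= 100.0:
                raise DataError(f"patients.csv row {ridx}: field {q!r} outside 0..100")
        allergies = frozenset(
            DrugClass(a) for a in str(row["allergies"]).split(";")
            if a and a != "nan")
        symptomatic = bool(row["symptomatic_hypotension"])

        plabs = labs_by.get(pid)
        if plabs is None:
            raise DataError(f"labs.csv: no snapshots for patient {pid}")
        days = plabs["day"].tolist()
        if days != sorted(days) or len(set(days)) != len(days):
            raise DataError(
                f"labs.csv: snapshot days for patient {pid} must be strictly "
                f"increasing; got {days}")
        prx = rx_by.get(pid)
        pvit = vitals_by.get(pid)
        piron = iron_by.get(pid)
        if piron is None or len(piron) != len(plabs):
            raise DataError(
                f"iron.csv: patient {pid} must have one row per snapshot day")
        vitals_all = []
        if pvit is not None:
            for vidx, v in pvit.iterrows():
                try:
                    vitals_all.append(VitalsReading(
                        day=int(v["day"]), systolic_bp=float(v["systolic_bp"]),
                        diastolic_bp=float(v["diastolic_bp"]),
                        heart_rate=float(v["heart_rate"]),
                        weight=float(v["weight"])))
                except DataError as err:
                    raise DataError(f"vitals.csv row {vidx}: {err}") from None
        trajectory = []
        iron_rows = piron.reset_index(drop=True)
        for sidx, (lidx, lab) in enumerate(plabs.iterrows()):
            day = int(lab["day"])
            try:
                panel = LabPanel(
                    potassium=float(lab["potassium"]), egfr=float(lab["egfr"]),
                    ferritin=_none_if_nan(lab.get("ferritin")),
                    tsat=_none_if_nan(lab.get("tsat")),
                    hb=_none_if_nan(lab.get("hb")),
                    measured_on=int(lab["measured_on"]))
            except DataError as err:
                raise DataError(f"labs.csv row {lidx}: {err}") from None
            prescriptions = []
            if prx is not None:
                for xidx, x in prx[prx["day"] == day].iterrows():
                    try:
                        prescriptions.append(Prescription(
                            drug_name=str(x["drug_name"]),
                            drug_class=DrugClass(x["drug_class"]),
                            daily_dose=float(x["daily_dose_mg"])))
                    except (DataError, ValueError) as err:
                        raise DataError(
                            f"prescriptions.csv row {xidx}: {err}") from None
            irow = iron_rows.iloc[sidx]
            screened_on = _none_if_nan(irow["screened_on"])
            iron_state = IronStatus(
                screened_on=None if screened_on is None else int(screened_on),
                ferritin=_none_if_nan(irow["ferritin"]),
                tsat=_none_if_nan(irow["tsat"]),
                iv_iron_given=bool(irow["iv_iron_given"]))
            try:
                trajectory.append(PatientSnapshot(
                    day=day, prescriptions=tuple(prescriptions), labs=panel,
                    vitals_history=tuple(v for v in vitals_all if v.day <= day),
                    iron=iron_state, allergies=allergies,
                    symptomatic_hypotension=symptomatic))
            except DataError as err:
                raise DataError(
                    f"patient {pid} snapshot day {day}: {err}") from None
        consults = []
        pcon = consults_by.get(pid)
        if pcon is not None:
            for cidx, c in pcon.iterrows():
                day = int(c["day"])
                if not 0 <= day <= config.horizon:
                    raise DataError(
                        f"consults.csv row {cidx}: field 'day' outside "
                        f"[0, {config.horizon}]")
                if c["type"] not in ("remote", "physical"):
                    raise DataError(
                        f"consults.csv row {cidx}: field 'type' must be "
                        f"remote or physical")
                consults.append(Consult(day=day, type=str(c["type"]),
                                        summary_sent=bool(c["summary_sent"])))
        patients.append(TrialPatient(
            id=str(pid), arm=str(row["arm"]),
            stratum=(bool(row["new_onset"]), str(row["hospital"])),
            trajectory=tuple(trajectory), consults=tuple(consults),
            hospitalizations=int(row["hospitalizations"]),
            hyperkalemia_events=int(row["hyperkalemia_events"]),
            low_egfr_events=int(row["low_egfr_events"]),
            kccq_baseline=float(row["kccq_baseline"]),
            kccq_12wk=float(row["kccq_12wk"]),
            nps_baseline=int(row["nps_baseline"]),
            nps_12wk=int(row["nps_12wk"]),
            time_spent_h=float(row["time_spent_h"]),
            completed=bool(row["completed"]),
            censor_day=int(row["censor_day"]),
            age=float(row["age"]), nyha_class=int(row["nyha_class"]),
            ischemic=bool(row["ischemic"]),
            nurse_support=bool(row["nurse_support"]),
        ))
    return TrialDataset(patients=tuple(patients), config=config)
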