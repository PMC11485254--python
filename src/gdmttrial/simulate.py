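"""Seed-reproducible synthetic two-arm HFrEF titration trials.

The generator emulates the design of a pragmatic 150-patient, 12-week,
1:1 randomized trial of remote digital consults (DC) versus usual care:
stratified variable-block randomization (blocks of 2, 4 and 6, strata =
new-onset status x hospital), baseline pharmacotherapy and labs drawn from
published cohort distributions, and follow-up dynamics in which each
consult gives every sub-target medication group a chance to move one step
up a discrete dose grid unless a contraindication (valid reason) applies.
Contraindications are induced by the drawn labs and vitals themselves, so
the scoring engine sees them exactly as it would in real data.

Randomness is split per patient from the dataset seed, so enlarging a
cohort never perturbs already-generated patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .scoring import (
    Component,
    DoseTable,
    DrugClass,
    IronStatus,
    LabPanel,
    PatientSnapshot,
    Prescription,
    RASI_FAMILY,
    VitalsReading,
    default_dose_table,
    gdmt_score,
    is_omt,
    valid_reasons,
)

__all__ = [
    "SimConfig",
    "TrialPatient",
    "TrialDataset",
    "Consult",
    "randomize",
    "simulate_cohort",
    "simulate_followup",
    "simulate_trial",
]

ARMS = ("DC", "USUAL")

#: spawn-key offset reserved for the randomization stream (never a patient index)
_RANDOMIZATION_STREAM = 1_000_003


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0, 1]; got {p}")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of one synthetic trial.

    The shipped defaults (``SimConfig.default()``) are calibrated to the
    published baseline tables of the trial being emulated: prescription
    rates per medication group, dose-fraction mixes on the grid
    {1/4, 1/2, 1}, lab and vital-sign distributions, per-arm consult rates
    and per-consult uptitration/iron-screening probabilities.  All
    calibration constants live in ``data/default_sim_config.json``.
    """

    n_patients: int = 150
    horizon: int = 84
    block_sizes: tuple = (2, 4, 6)
    hospitals: tuple = ("academic_A", "academic_B", "community_A", "community_B")
    hospital_weights: tuple = (0.35, 0.3, 0.2, 0.15)
    new_onset_prob: float = 0.3
    dropout_prob: float = 0.05
    baseline_medication_rates: dict = field(default_factory=dict)
    dose_fraction_grid: tuple = (0.25, 0.5, 1.0)
    dose_fraction_weights: dict = field(default_factory=dict)
    iron: dict = field(default_factory=dict)
    lab_distributions: dict = field(default_factory=dict)
    vitals_distributions: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    consult_rate: dict = field(default_factory=dict)
    uptitration_prob_per_consult: dict = field(default_factory=dict)
    iron_screening_prob_per_consult: dict = field(default_factory=dict)
    allergy_prob_per_class: float = 0.01
    symptomatic_hypotension_prob: float = 0.03
    hospitalization_rate: float = 0.11
    questionnaires: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.horizon <= 0:
            raise ConfigError("horizon must be > 0")
        for b in self.block_sizes:
            if b % 2 != 0 or b <= 0:
                raise ConfigError(
                    f"block sizes must be positive and even for 1:1 allocation; got {b}"
                )
        _check_prob("new_onset_prob", self.new_onset_prob)
        _check_prob("dropout_prob", self.dropout_prob)
        _check_prob("allergy_prob_per_class", self.allergy_prob_per_class)
        _check_prob("symptomatic_hypotension_prob", self.symptomatic_hypotension_prob)
        for name, p in self.baseline_medication_rates.items():
            _check_prob(f"baseline_medication_rates[{name}]", p)
        for arm, p in self.uptitration_prob_per_consult.items():
            _check_prob(f"uptitration_prob_per_consult[{arm}]", p)
        for arm, p in self.iron_screening_prob_per_consult.items():
            _check_prob(f"iron_screening_prob_per_consult[{arm}]", p)
        for group, w in self.dose_fraction_weights.items():
            if len(w) != len(self.dose_fraction_grid):
                raise ConfigError(
                    f"dose_fraction_weights[{group}] length must match the grid"
                )
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigError(f"dose_fraction_weights[{group}] must sum to 1")

    @classmethod
    def default(cls, **overrides) -> "SimConfig":
        with resources.files("gdmttrial.data").joinpath(
            "default_sim_config.json"
        ).open() as fh:
            return cls.from_dict({**json.load(fh), **overrides})

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("block_sizes", "hospitals", "hospital_weights", "dose_fraction_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            v = getattr(self, name)
            out[name] = list(v) if isinstance(v, tuple) else v
        return out

    def with_equal_arms(self) -> "SimConfig":
        """Null configuration: both arms get the usual-care dynamics."""
        usual_rate = self.consult_rate["USUAL"]
        return replace(
            self,
            consult_rate={"DC": dict(usual_rate), "USUAL": dict(usual_rate)},
            uptitration_prob_per_consult={
                a: self.uptitration_prob_per_consult["USUAL"] for a in ARMS
            },
            iron_screening_prob_per_consult={
                a: self.iron_screening_prob_per_consult["USUAL"] for a in ARMS
            },
        )


@dataclass(frozen=True)
class Consult:
    day: int
    type: str  # "remote" | "physical"
    summary_sent: bool


@dataclass(frozen=True)
class TrialPatient:
    id: str
    arm: str  # "DC" | "USUAL"
    stratum: tuple  # (new_onset: bool, hospital: str)
    trajectory: tuple = ()  # PatientSnapshot, time-ordered
    consults: tuple = ()
    hospitalizations: int = 0
    hyperkalemia_events: int = 0
    low_egfr_events: int = 0
    kccq_baseline: float = 0.0
    kccq_12wk: float = 0.0
    nps_baseline: int = 5
    nps_12wk: int = 5
    time_spent_h: float = 0.0
    completed: bool = True
    censor_day: int = 84
    age: float = 65.0
    nyha_class: int = 2
    ischemic: bool = False
    nurse_support: bool = False

    @property
    def new_onset(self) -> bool:
        return self.stratum[0]

    @property
    def hospital(self) -> str:
        return self.stratum[1]


@dataclass(frozen=True)
class TrialDataset:
    patients: tuple
    config: SimConfig

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# randomization


def randomize(
    patient_ids: Sequence,
    strata_labels: Sequence,
    block_sizes: Sequence = (2, 4, 6),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Stratified 1:1 permuted-block assignment with variable block sizes.

    Within each stratum the assignment sequence is a concatenation of
    shuffled blocks, each block half "DC" and half "USUAL"; the size of
    each block is drawn uniformly from ``block_sizes``.  Patients keep
    their enrolment order within the stratum, so the worst stratum
    imbalance is half the largest block (the partial final block).
    """
    if len(patient_ids) != len(strata_labels):
        raise ConfigError("patient_ids and strata_labels must align")
    for b in block_sizes:
        if b % 2 != 0 or b <= 0:
            raise ConfigError(f"block size {b} incompatible with 1:1 allocation")
    if rng is None:
        rng = np.random.default_rng(seed)
    by_stratum: dict = {}
    for pid, stratum in zip(patient_ids, strata_labels):
        by_stratum.setdefault(stratum, []).append(pid)
    sizes = np.asarray(block_sizes)
    assignment: dict = {}
    for stratum in by_stratum:
        members = by_stratum[stratum]
        seq: list = []
        while len(seq) < len(members):
            size = int(rng.choice(sizes))
            block = ["DC"] * (size // 2) + ["USUAL"] * (size // 2)
            rng.shuffle(block)
            seq.extend(block)
        for pid, arm in zip(members, seq):
            assignment[pid] = arm
    return assignment


# ---------------------------------------------------------------------------
# baseline cohort


def _patient_rng(seed: int, index: int, stage: int) -> np.random.Generator:
    # Dedicated stream per (patient, stage); stage 0 = baseline, 1 = follow-up,
    # 2 = questionnaires/consumption.  Adding patients never reuses a stream.
    return np.random.default_rng(np.random.SeedSequence([seed, index, stage]))


def _draw_fraction(rng: np.random.Generator, config: SimConfig, group: str) -> float:
    grid = config.dose_fraction_grid
    weights = config.dose_fraction_weights[group]
    return float(rng.choice(grid, p=weights))


def _pick_drug(rng: np.random.Generator, table: DoseTable, cls: DrugClass) -> str:
    options = table.drugs_in_class(cls)
    return options[int(rng.integers(len(options)))]


class _MedState:
    """Mutable medication state walked forward during follow-up."""

    __slots__ = (
        "rasi_drug", "rasi_class", "rasi_fraction",
        "bb_drug", "bb_fraction", "mra_drug", "mra_fraction",
        "sglt2i_drug", "iron",
    )

    def __init__(self) -> None:
        self.rasi_drug = None
        self.rasi_class = None
        self.rasi_fraction = 0.0
        self.bb_drug = None
        self.bb_fraction = 0.0
        self.mra_drug = None
        self.mra_fraction = 0.0
        self.sglt2i_drug = None
        self.iron = IronStatus()

    def prescriptions(self, table: DoseTable) -> tuple:
        out = []
        if self.rasi_drug is not None:
            out.append(Prescription(
                self.rasi_drug, self.rasi_class,
                self.rasi_fraction * table.target_dose(self.rasi_drug),
            ))
        if self.bb_drug is not None:
            out.append(Prescription(
                self.bb_drug, DrugClass.BETA_BLOCKER,
                self.bb_fraction * table.target_dose(self.bb_drug),
            ))
        if self.mra_drug is not None:
            out.append(Prescription(
                self.mra_drug, DrugClass.MRA,
                self.mra_fraction * table.target_dose(self.mra_drug),
            ))
        if self.sglt2i_drug is not None:
            out.append(Prescription(
                self.sglt2i_drug, DrugClass.SGLT2I,
                table.target_dose(self.sglt2i_drug),
            ))
        return tuple(out)


def _next_fraction(grid: tuple, current: float) -> float:
    for g in grid:
        if g > current + 1e-12:
            return g
    return current


class _Latent:
    """Per-patient latent means for labs/vitals (kept outside the dataset)."""

    __slots__ = ("potassium", "log_egfr", "sbp", "dbp", "hr", "weight",
                 "deficient", "allergies", "symptomatic_hypotension")


def _draw_latent(rng: np.random.Generator, config: SimConfig) -> _Latent:
    labd, vitd = config.lab_distributions, config.vitals_distributions
    lat = _Latent()
    lat.potassium = rng.normal(labd["potassium"]["mean"], labd["potassium"]["sd"])
    lat.log_egfr = rng.normal(labd["egfr_log"]["mean"], labd["egfr_log"]["sd"])
    lat.sbp = rng.normal(vitd["systolic_bp"]["mean"], vitd["systolic_bp"]["sd"])
    lat.dbp = rng.normal(vitd["diastolic_bp"]["mean"], vitd["diastolic_bp"]["sd"])
    lat.dbp = min(lat.dbp, lat.sbp - 15.0)
    lat.hr = rng.normal(vitd["heart_rate"]["mean"], vitd["heart_rate"]["sd"])
    lat.weight = max(40.0, rng.normal(vitd["weight"]["mean"], vitd["weight"]["sd"]))
    lat.deficient = bool(rng.random() < config.iron["deficiency_prob"])
    lat.allergies = frozenset(
        cls for cls in DrugClass if rng.random() < config.allergy_prob_per_class
    )
    lat.symptomatic_hypotension = bool(
        rng.random() < config.symptomatic_hypotension_prob
    )
    return lat


def _draw_labs(rng: np.random.Generator, config: SimConfig, lat: _Latent,
               day: int) -> LabPanel:
    labd = config.lab_distributions
    k = max(2.5, lat.potassium + rng.normal(0.0, labd["potassium"]["visit_sd"]))
    egfr = float(np.exp(lat.log_egfr + rng.normal(0.0, labd["egfr_log"]["visit_sd"])))
    return LabPanel(potassium=round(k, 2), egfr=round(egfr, 1), measured_on=day)


def _draw_vitals(rng: np.random.Generator, config: SimConfig, lat: _Latent,
                 day: int) -> VitalsReading:
    vitd = config.vitals_distributions
    sbp = max(62.0, lat.sbp + rng.normal(0.0, vitd["systolic_bp"]["reading_sd"]))
    dbp = max(30.0, min(sbp - 10.0,
                        lat.dbp + rng.normal(0.0, vitd["diastolic_bp"]["reading_sd"])))
    hr = max(35.0, lat.hr + rng.normal(0.0, vitd["heart_rate"]["reading_sd"]))
    wt = max(38.0, lat.weight + rng.normal(0.0, vitd["weight"]["reading_sd"]))
    return VitalsReading(day=day, systolic_bp=round(sbp, 0),
                         diastolic_bp=round(dbp, 0), heart_rate=round(hr, 0),
                         weight=round(wt, 1))


def _draw_iron_screen(rng: np.random.Generator, config: SimConfig, lat: _Latent,
                      day: int, iv_given_prob: float) -> IronStatus:
    # ferritin/tsat drawn consistent with the latent deficiency state
    labd = config.lab_distributions
    if lat.deficient:
        ferritin = float(np.exp(rng.normal(labd["ferritin_log"]["mean"] - 0.9, 0.5)))
        ferritin = min(ferritin, 95.0) if rng.random() < 0.7 else min(
            max(ferritin, 100.0), 295.0)
        tsat = float(np.clip(rng.normal(14.0, 4.0), 2.0, 19.5))
    else:
        ferritin = float(np.clip(np.exp(rng.normal(labd["ferritin_log"]["mean"] + 0.6, 0.4)), 300.0, 2000.0))
        tsat = float(np.clip(rng.normal(30.0, 6.0), 20.5, 60.0))
    iv = bool(lat.deficient and rng.random() < iv_given_prob)
    return IronStatus(screened_on=day, ferritin=round(ferritin, 1),
                      tsat=round(tsat, 1), iv_iron_given=iv)


def _baseline_meds(rng: np.random.Generator, config: SimConfig,
                   table: DoseTable) -> _MedState:
    rates = config.baseline_medication_rates
    med = _MedState()
    if rng.random() < rates["RASI"]:
        if rng.random() < rates["ARNI_given_RASI"]:
            med.rasi_class = DrugClass.ARNI
        else:
            med.rasi_class = DrugClass.ACE if rng.random() < 0.7 else DrugClass.ARB
        med.rasi_drug = _pick_drug(rng, table, med.rasi_class)
        med.rasi_fraction = _draw_fraction(rng, config, "RASI")
    if rng.random() < rates["BETA_BLOCKER"]:
        med.bb_drug = _pick_drug(rng, table, DrugClass.BETA_BLOCKER)
        med.bb_fraction = _draw_fraction(rng, config, "BETA_BLOCKER")
    if rng.random() < rates["MRA"]:
        med.mra_drug = _pick_drug(rng, table, DrugClass.MRA)
        med.mra_fraction = _draw_fraction(rng, config, "MRA")
    if rng.random() < rates["SGLT2I"]:
        med.sglt2i_drug = _pick_drug(rng, table, DrugClass.SGLT2I)
    return med


def _snapshot(day: int, med: _MedState, labs: LabPanel, vitals: tuple,
              lat: _Latent, table: DoseTable) -> PatientSnapshot:
    return PatientSnapshot(
        day=day,
        prescriptions=med.prescriptions(table),
        labs=labs,
        vitals_history=vitals,
        iron=med.iron,
        allergies=lat.allergies,
        symptomatic_hypotension=lat.symptomatic_hypotension,
    )


def simulate_cohort(config: SimConfig, table: Optional[DoseTable] = None) -> TrialDataset:
    """Draw the baseline cohort and randomize it (trajectories = baseline only)."""
    if table is None:
        table = default_dose_table()
    patients = []
    strata = []
    for i in range(config.n_patients):
        rng = _patient_rng(config.seed, i, 0)
        hospital = config.hospitals[
            int(rng.choice(len(config.hospitals), p=np.asarray(config.hospital_weights)))
        ]
        new_onset = bool(rng.random() < config.new_onset_prob)
        stratum = (new_onset, hospital)
        lat = _draw_latent(rng, config)
        med = _baseline_meds(rng, config, table)
        if rng.random() < config.iron["baseline_screened_prob"]:
            # recent enough that a screen valid at day 0 stays valid through
            # the follow-up horizon (window 365 days)
            max_age = max(1, 365 - config.horizon)
            med.iron = _draw_iron_screen(
                rng, config, lat,
                day=-int(rng.integers(0, max_age)),
                iv_given_prob=config.iron["baseline_iv_given_prob"],
            )
        cov = config.covariates
        age = float(np.clip(rng.normal(cov["age"]["mean"], cov["age"]["sd"]),
                            cov["age"]["min"], cov["age"]["max"]))
        baseline = _snapshot(
            0, med, _draw_labs(rng, config, lat, 0),
            (_draw_vitals(rng, config, lat, 0),), lat, table,
        )
        patients.append(TrialPatient(
            id=f"P{i:04d}",
            arm="",  # assigned below
            stratum=stratum,
            trajectory=(baseline,),
            age=round(age, 1),
            nyha_class=3 if rng.random() < cov["nyha3_prob"] else 2,
            ischemic=bool(rng.random() < cov["ischemic_prob"]),
            nurse_support=bool(rng.random() < cov["nurse_support_prob"]),
        ))
        strata.append(stratum)

    rand_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _RANDOMIZATION_STREAM])
    )
    arms = randomize([p.id for p in patients], strata,
                     block_sizes=config.block_sizes, rng=rand_rng)
    patients = [replace(p, arm=arms[p.id]) for p in patients]
    return TrialDataset(patients=tuple(patients), config=config)


# ---------------------------------------------------------------------------
# follow-up dynamics


def _rebuild_medstate(snapshot: PatientSnapshot, table: DoseTable) -> _MedState:
    med = _MedState()
    for p in snapshot.prescriptions:
        if p.drug_class in RASI_FAMILY:
            med.rasi_drug, med.rasi_class = p.drug_name, p.drug_class
            med.rasi_fraction = p.daily_dose / table.target_dose(p.drug_name)
        elif p.drug_class is DrugClass.BETA_BLOCKER:
            med.bb_drug = p.drug_name
            med.bb_fraction = p.daily_dose / table.target_dose(p.drug_name)
        elif p.drug_class is DrugClass.MRA:
            med.mra_drug = p.drug_name
            med.mra_fraction = p.daily_dose / table.target_dose(p.drug_name)
        elif p.drug_class is DrugClass.SGLT2I:
            med.sglt2i_drug = p.drug_name
    med.iron = snapshot.iron
    return med


def _excused(reasons, component: Component) -> bool:
    return any(r.excuses(component) for r in reasons)


def _followup_one(patient: TrialPatient, config: SimConfig, table: DoseTable,
                  rng: np.random.Generator) -> TrialPatient:
    arm = patient.arm
    lat = _Latent()
    base = patient.trajectory[0]
    # latent means recovered from the baseline snapshot (kept deterministic)
    lat.potassium = base.labs.potassium
    lat.log_egfr = float(np.log(base.labs.egfr))
    v0 = base.vitals_history[-1]
    lat.sbp, lat.dbp = v0.systolic_bp, v0.diastolic_bp
    lat.hr, lat.weight = v0.heart_rate, v0.weight
    lat.allergies = base.allergies
    lat.symptomatic_hypotension = base.symptomatic_hypotension
    lat.deficient = bool(rng.random() < config.iron["deficiency_prob"]) \
        if base.iron.screened_on is None else (
            base.iron.ferritin is not None and (
                base.iron.ferritin < 100
                or (base.iron.ferritin < 300 and (base.iron.tsat or 100) < 20)))

    dropout = rng.random() < config.dropout_prob
    end_day = int(rng.integers(7, config.horizon)) if dropout else config.horizon

    rates = config.consult_rate[arm]
    n_remote = rng.poisson(rates["remote"])
    n_physical = rng.poisson(rates["physical"])
    days = sorted(set(
        int(d) for d in rng.integers(1, config.horizon + 1, n_remote + n_physical)
    ))
    types = ["remote"] * n_remote + ["physical"] * n_physical
    rng.shuffle(types)
    consults = tuple(
        Consult(day=d, type=t, summary_sent=(arm == "DC"))
        for d, t in zip(days, types) if d <= end_day
    )

    p_up = config.uptitration_prob_per_consult[arm]
    p_screen = config.iron_screening_prob_per_consult[arm]
    grid = (0.0,) + tuple(config.dose_fraction_grid)

    med = _rebuild_medstate(base, table)
    trajectory = [base]
    vitals = list(base.vitals_history)
    hyperk = 0
    low_egfr = 0
    labs = base.labs
    omt_reached = is_omt(gdmt_score(base, table))

    # weekly home readings up to each consult; appended lazily
    reading_days = [d for d in range(7, end_day + 1, 7)]
    next_reading = 0

    for consult in consults:
        day = consult.day
        while next_reading < len(reading_days) and reading_days[next_reading] <= day:
            vitals.append(_draw_vitals(rng, config, lat, reading_days[next_reading]))
            next_reading += 1
        labs = _draw_labs(rng, config, lat, day)
        if labs.potassium > 5.0:
            hyperk += 1
        if labs.egfr < 30:
            low_egfr += 1
        provisional = _snapshot(day, med, labs, tuple(vitals), lat, table)
        reasons = valid_reasons(provisional)
        if not omt_reached:
            # RASi family: start, uptitrate, or switch to ARNI
            if not _excused(reasons, Component.RASI_DOSE):
                if med.rasi_drug is None:
                    if rng.random() < p_up:
                        med.rasi_class = (DrugClass.ARNI if rng.random() < 0.5
                                          else DrugClass.ACE)
                        med.rasi_drug = _pick_drug(rng, table, med.rasi_class)
                        med.rasi_fraction = grid[1]
                elif med.rasi_fraction < 1.0 and rng.random() < p_up:
                    med.rasi_fraction = _next_fraction(grid, med.rasi_fraction)
            if (med.rasi_drug is not None and med.rasi_class is not DrugClass.ARNI
                    and not _excused(reasons, Component.ARNI_SWITCH)
                    and rng.random() < p_up):
                med.rasi_class = DrugClass.ARNI
                med.rasi_drug = _pick_drug(rng, table, DrugClass.ARNI)
            if not _excused(reasons, Component.BB_DOSE):
                if med.bb_drug is None:
                    if rng.random() < p_up:
                        med.bb_drug = _pick_drug(rng, table, DrugClass.BETA_BLOCKER)
                        med.bb_fraction = grid[1]
                elif med.bb_fraction < 1.0 and rng.random() < p_up:
                    med.bb_fraction = _next_fraction(grid, med.bb_fraction)
            if not _excused(reasons, Component.MRA_DOSE):
                if med.mra_drug is None:
                    if rng.random() < p_up:
                        med.mra_drug = _pick_drug(rng, table, DrugClass.MRA)
                        med.mra_fraction = grid[1]
                elif med.mra_fraction < 1.0 and rng.random() < p_up:
                    med.mra_fraction = _next_fraction(grid, med.mra_fraction)
            if (med.sglt2i_drug is None
                    and not _excused(reasons, Component.SGLT2I)
                    and rng.random() < p_up):
                med.sglt2i_drug = _pick_drug(rng, table, DrugClass.SGLT2I)
            stale = (med.iron.screened_on is None
                     or day - med.iron.screened_on > 365
                     or (lat.deficient and not med.iron.iv_iron_given))
            if stale and rng.random() < p_screen:
                med.iron = _draw_iron_screen(
                    rng, config, lat, day,
                    iv_given_prob=config.iron["followup_iv_given_prob"],
                )
        snap = _snapshot(day, med, labs, tuple(vitals), lat, table)
        trajectory.append(snap)
        if not omt_reached and is_omt(gdmt_score(snap, table)):
            omt_reached = True  # absorbing: no further medication changes

    while next_reading < len(reading_days):
        vitals.append(_draw_vitals(rng, config, lat, reading_days[next_reading]))
        next_reading += 1
    if not trajectory or trajectory[-1].day < end_day:
        trajectory.append(_snapshot(end_day, med, labs, tuple(vitals), lat, table))

    qrng = _patient_rng(config.seed, int(patient.id[1:]), 2)
    q = config.questionnaires
    kccq0 = float(np.clip(qrng.normal(q["kccq_baseline"]["mean"],
                                      q["kccq_baseline"]["sd"]), 5.0, 100.0))
    kccq12 = float(np.clip(kccq0 + qrng.normal(q["kccq_change"]["mean"],
                                               q["kccq_change"]["sd"]), 0.0, 100.0))
    nps_p = np.asarray(q["nps_baseline_probs"])
    nps0 = int(qrng.choice(np.arange(1, 11), p=nps_p / nps_p.sum()))
    nps12 = int(np.clip(nps0 + qrng.integers(-1, 2), 1, 10))
    time_spent = float(np.exp(qrng.normal(q["time_spent_log"]["mean"],
                                          q["time_spent_log"]["sd"])))

    return replace(
        patient,
        trajectory=tuple(trajectory),
        consults=consults,
        hospitalizations=int(rng.poisson(config.hospitalization_rate)),
        hyperkalemia_events=hyperk,
        low_egfr_events=low_egfr,
        kccq_baseline=round(kccq0, 1),
        kccq_12wk=round(kccq12, 1),
        nps_baseline=nps0,
        nps_12wk=nps12,
        time_spent_h=round(time_spent, 2),
        completed=not dropout,
        censor_day=end_day,
    )


def simulate_followup(dataset: TrialDataset,
                      config: Optional[SimConfig] = None,
                      table: Optional[DoseTable] = None) -> TrialDataset:
    """Fill in 12-week trajectories, consults, safety and questionnaires."""
    if config is None:
        config = dataset.config
    if table is None:
        table = default_dose_table()
    filled = []
    for i, patient in enumerate(dataset.patients):
        rng = _patient_rng(config.seed, i, 1)
        filled.append(_followup_one(patient, config, table, rng))
    return TrialDataset(patients=tuple(filled), config=config)


def simulate_trial(config: Optional[SimConfig] = None,
                   table: Optional[DoseTable] = None,
                   seed: Optional[int] = None) -> TrialDataset:
    """Baseline + follow-up in one call."""
    if config is None:
        config = SimConfig.default()
    if seed is not None:
        config = replace(config, seed=seed)
    if table is None:
        table = default_dose_table()
    return simulate_followup(simulate_cohort(config, table), config, table)
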