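"""The 0-6 GDMT score for HFrEF pharmacotherapy.

The score awards up to one point for each of six items: dose of the
renin-angiotensin system inhibitor family (ACE/ARB/ARNI, as used dose over
guideline target dose), the switch from ACE/ARB to an ARNI, beta-blocker
dose, MRA dose, SGLT2 inhibitor prescription, and iron screening with
supplementation where indicated.  A documented contraindication ("valid
reason") scores its component as 1 despite sub-target dosing, so the score
measures clinician adherence to what is achievable for the patient rather
than raw prescription volume.

Optimal medical therapy (OMT) is every component at 1, i.e. a total of 6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import ConfigError, DataError, UnscreenedError

__all__ = [
    "DrugClass",
    "Component",
    "Basis",
    "Reason",
    "ValidReason",
    "DoseTable",
    "Prescription",
    "LabPanel",
    "VitalsReading",
    "IronStatus",
    "PatientSnapshot",
    "ComponentScore",
    "GDMTScore",
    "dose_ratio",
    "valid_reasons",
    "iron_deficiency",
    "score_component",
    "gdmt_score",
    "delta_gdmt",
    "is_omt",
    "time_to_omt",
    "default_dose_table",
    "RASI_FAMILY",
    "ALL_GDMT_CLASSES",
    "SBP_LOOKBACK_DAYS",
    "IRON_SCREENING_WINDOW_DAYS",
]


class DrugClass(str, Enum):
    ACE = "ACE"
    ARB = "ARB"
    ARNI = "ARNI"
    BETA_BLOCKER = "BETA_BLOCKER"
    MRA = "MRA"
    SGLT2I = "SGLT2I"


#: The ACE/ARB/ARNI family counts as one exclusive medication group.
RASI_FAMILY = frozenset({DrugClass.ACE, DrugClass.ARB, DrugClass.ARNI})

#: "All four drugs": the four pharmacotherapy groups constituting GDMT.
ALL_GDMT_CLASSES = frozenset(DrugClass)

#: Window for "persistent" systolic hypotension (>= 2 readings <= 90 mmHg).
SBP_LOOKBACK_DAYS = 14

#: Iron screening counts if performed no longer than one year before the snapshot.
IRON_SCREENING_WINDOW_DAYS = 365


class Component(str, Enum):
    RASI_DOSE = "RASI_DOSE"
    ARNI_SWITCH = "ARNI_SWITCH"
    BB_DOSE = "BB_DOSE"
    MRA_DOSE = "MRA_DOSE"
    SGLT2I = "SGLT2I"
    IRON = "IRON"


class Basis(str, Enum):
    DOSE_RATIO = "DOSE_RATIO"
    BINARY_MET = "BINARY_MET"
    BINARY_UNMET = "BINARY_UNMET"
    VALID_REASON = "VALID_REASON"


class Reason(str, Enum):
    PERSISTENT_SBP_LE_90 = "PERSISTENT_SBP_LE_90"
    SYMPTOMATIC_HYPOTENSION = "SYMPTOMATIC_HYPOTENSION"
    EGFR_LT_30 = "EGFR_LT_30"
    EGFR_LT_20 = "EGFR_LT_20"
    K_GT_5 = "K_GT_5"
    HR_LE_60 = "HR_LE_60"
    ALLERGY = "ALLERGY"


#: Drug classes whose components each valid reason excuses.
_REASON_SCOPE: dict[Reason, frozenset[DrugClass]] = {
    Reason.PERSISTENT_SBP_LE_90: ALL_GDMT_CLASSES,
    Reason.SYMPTOMATIC_HYPOTENSION: ALL_GDMT_CLASSES,
    Reason.EGFR_LT_30: RASI_FAMILY | {DrugClass.MRA},
    Reason.EGFR_LT_20: frozenset({DrugClass.SGLT2I}),
    Reason.K_GT_5: RASI_FAMILY | {DrugClass.MRA},
    Reason.HR_LE_60: frozenset({DrugClass.BETA_BLOCKER}),
}

#: Drug classes each score component draws on (IRON draws on none, so no
#: pharmacological contraindication can excuse it).
_COMPONENT_CLASSES: dict[Component, frozenset[DrugClass]] = {
    Component.RASI_DOSE: RASI_FAMILY,
    Component.ARNI_SWITCH: frozenset({DrugClass.ARNI}),
    Component.BB_DOSE: frozenset({DrugClass.BETA_BLOCKER}),
    Component.MRA_DOSE: frozenset({DrugClass.MRA}),
    Component.SGLT2I: frozenset({DrugClass.SGLT2I}),
    Component.IRON: frozenset(),
}


@dataclass(frozen=True)
class ValidReason:
    reason: Reason
    applies_to: frozenset

    def excuses(self, component: Component) -> bool:
        return bool(self.applies_to & _COMPONENT_CLASSES[component])


@dataclass(frozen=True)
class DoseTable:
    """Drug -> class -> guideline target total daily dose (mg/day).

    The shipped default is a reference table of common HFrEF target doses;
    it is a plain JSON file users can replace via :meth:`from_json` or
    :meth:`from_tsv`.
    """

    entries: tuple  # of (drug_name, DrugClass, target mg/day)

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate drug_name in dose table")
        for name, cls, dose in self.entries:
            if not isinstance(cls, DrugClass):
                raise ConfigError(f"unknown drug class for {name!r}: {cls!r}")
            if not dose > 0:
                raise ConfigError(f"target_daily_dose must be > 0 for {name!r}")
        present = {e[1] for e in self.entries}
        missing = set(DrugClass) - present
        if missing:
            raise ConfigError(
                "dose table must cover every drug class; missing: "
                + ", ".join(sorted(m.value for m in missing))
            )
        object.__setattr__(
            self, "_by_name", {n: (c, d) for n, c, d in self.entries}
        )

    def __contains__(self, drug_name: str) -> bool:
        return drug_name in self._by_name

    def target_dose(self, drug_name: str) -> float:
        try:
            return self._by_name[drug_name][1]
        except KeyError:
            raise ConfigError(f"drug {drug_name!r} not in dose table") from None

    def drug_class(self, drug_name: str) -> DrugClass:
        try:
            return self._by_name[drug_name][0]
        except KeyError:
            raise ConfigError(f"drug {drug_name!r} not in dose table") from None

    def drugs_in_class(self, cls: DrugClass) -> list:
        return [n for n, c, _ in self.entries if c is cls]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "DoseTable":
        entries = tuple(
            (
                r["drug_name"],
                DrugClass(r["drug_class"]),
                float(r["target_daily_dose_mg"]),
            )
            for r in records
        )
        return cls(entries)

    @classmethod
    def from_json(cls, path) -> "DoseTable":
        with open(path) as fh:
            return cls.from_records(json.load(fh))

    @classmethod
    def from_tsv(cls, path) -> "DoseTable":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            required = {"drug_name", "drug_class", "target_daily_dose_mg"}
            if not required <= set(header):
                raise ConfigError(
                    f"dose table TSV must have columns {sorted(required)}; got {header}"
                )
            for line in fh:
                if line.strip():
                    records.append(dict(zip(header, line.rstrip("\n").split("\t"))))
        return cls.from_records(records)


def default_dose_table() -> DoseTable:
    """The packaged reference dose table (editable via JSON/TSV overrides)."""
    with resources.files("gdmttrial.data").joinpath("target_doses.json").open() as fh:
        return DoseTable.from_records(json.load(fh))


@dataclass(frozen=True)
class Prescription:
    drug_name: str
    drug_class: DrugClass
    daily_dose: float  # mg/day, total

    def __post_init__(self) -> None:
        if self.daily_dose < 0:
            raise DataError(f"daily_dose < 0 for {self.drug_name!r}")


@dataclass(frozen=True)
class LabPanel:
    potassium: float  # mmol/L
    egfr: float  # mL/min/1.73 m^2
    ferritin: Optional[float] = None  # ug/L
    tsat: Optional[float] = None  # %
    hb: Optional[float] = None  # g/dL
    measured_on: int = 0

    def __post_init__(self) -> None:
        for name in ("potassium", "egfr", "ferritin", "tsat", "hb"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DataError(f"lab value {name}={v!r} must be > 0 when present")
        if self.tsat is not None and self.tsat > 100:
            raise DataError(f"tsat={self.tsat!r} must be in (0, 100]")


@dataclass(frozen=True)
class VitalsReading:
    day: int
    systolic_bp: float  # mmHg
    diastolic_bp: float  # mmHg
    heart_rate: float  # bpm
    weight: float  # kg

    def __post_init__(self) -> None:
        if not self.systolic_bp > self.diastolic_bp > 0:
            raise DataError(
                f"require systolic > diastolic > 0; got {self.systolic_bp}/{self.diastolic_bp}"
            )
        if not self.heart_rate > 0:
            raise DataError("heart_rate must be > 0")


@dataclass(frozen=True)
class IronStatus:
    screened_on: Optional[int] = None  # day index of most recent screening
    ferritin: Optional[float] = None
    tsat: Optional[float] = None
    iv_iron_given: bool = False

    def __post_init__(self) -> None:
        if self.screened_on is None and (
            self.ferritin is not None or self.tsat is not None
        ):
            raise DataError("iron labs present without a screening date")


@dataclass(frozen=True)
class PatientSnapshot:
    """Everything the score needs about one patient at one timepoint."""

    day: int
    prescriptions: tuple
    labs: LabPanel
    vitals_history: tuple = ()
    iron: IronStatus = IronStatus()
    allergies: frozenset = frozenset()
    symptomatic_hypotension: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "prescriptions", tuple(self.prescriptions))
        object.__setattr__(self, "vitals_history", tuple(self.vitals_history))
        object.__setattr__(self, "allergies", frozenset(self.allergies))
        seen: set = set()
        for p in self.prescriptions:
            key = "RASI" if p.drug_class in RASI_FAMILY else p.drug_class
            if key in seen:
                raise DataError(
                    f"more than one prescription in medication group {key} on day {self.day}"
                )
            seen.add(key)

    def prescription_in(self, classes: frozenset) -> Optional[Prescription]:
        for p in self.prescriptions:
            if p.drug_class in classes:
                return p
        return None


@dataclass(frozen=True)
class ComponentScore:
    component: Component
    value: float  # in [0, 1]
    basis: Basis

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise DataError(f"component value {self.value} outside [0, 1]")


@dataclass(frozen=True)
class GDMTScore:
    components: tuple  # six ComponentScore, one per Component in enum order

    @property
    def total(self) -> float:
        return sum(c.value for c in self.components)

    def __getitem__(self, component: Component) -> ComponentScore:
        for c in self.components:
            if c.component is component:
                return c
        raise KeyError(component)


# ---------------------------------------------------------------------------
# operations


def dose_ratio(p: Prescription, table: DoseTable) -> float:
    """Used dose over guideline target dose, capped at 1."""
    target = table.target_dose(p.drug_name)
    return min(1.0, p.daily_dose / target)


def valid_reasons(
    s: PatientSnapshot, sbp_lookback: int = SBP_LOOKBACK_DAYS
) -> list:
    """Contraindications documented in the snapshot, with the classes they excuse.

    Thresholds are applied with the comparison operators exactly as the
    protocol states them (strict where strict): persistent SBP <= 90 (two or
    more readings in the lookback window, asymptomatic patients only),
    symptomatic hypotension, eGFR < 30 (RASi family + MRA), eGFR < 20
    (SGLT2i), potassium > 5.0 (RASi family + MRA), HR <= 60 (beta-blocker),
    and per-class allergy.  A threshold reason never fires on missing data.
    """
    reasons: list = []

    low_sbp = [
        v
        for v in s.vitals_history
        if s.day - sbp_lookback <= v.day <= s.day and v.systolic_bp <= 90
    ]
    if len(low_sbp) >= 2 and not s.symptomatic_hypotension:
        reasons.append(
            ValidReason(Reason.PERSISTENT_SBP_LE_90, _REASON_SCOPE[Reason.PERSISTENT_SBP_LE_90])
        )
    if s.symptomatic_hypotension:
        reasons.append(
            ValidReason(Reason.SYMPTOMATIC_HYPOTENSION, _REASON_SCOPE[Reason.SYMPTOMATIC_HYPOTENSION])
        )
    if s.labs is not None:
        if s.labs.egfr < 30:
            reasons.append(ValidReason(Reason.EGFR_LT_30, _REASON_SCOPE[Reason.EGFR_LT_30]))
        if s.labs.egfr < 20:
            reasons.append(ValidReason(Reason.EGFR_LT_20, _REASON_SCOPE[Reason.EGFR_LT_20]))
        if s.labs.potassium > 5.0:
            reasons.append(ValidReason(Reason.K_GT_5, _REASON_SCOPE[Reason.K_GT_5]))
    recent = [v for v in s.vitals_history if v.day <= s.day]
    if recent:
        latest = max(recent, key=lambda v: v.day)
        if latest.heart_rate <= 60:
            reasons.append(ValidReason(Reason.HR_LE_60, _REASON_SCOPE[Reason.HR_LE_60]))
    for cls in sorted(s.allergies, key=lambda c: c.value):
        reasons.append(ValidReason(Reason.ALLERGY, frozenset({cls})))
    return reasons


def iron_deficiency(ferritin: Optional[float], tsat: Optional[float]) -> bool:
    """Iron deficiency: ferritin < 100 ug/L, or ferritin < 300 with TSAT < 20%.

    Raises :class:`UnscreenedError` when the values needed to decide are
    absent; "unscreened" is a distinct state from "not deficient".
    """
    if ferritin is None:
        raise UnscreenedError("ferritin not measured")
    if ferritin < 100:
        return True
    if ferritin >= 300:
        return False
    if tsat is None:
        raise UnscreenedError("ferritin in [100, 300) but TSAT not measured")
    return tsat < 20


def _raw_component(
    s: PatientSnapshot, component: Component, table: DoseTable,
    iron_window: int = IRON_SCREENING_WINDOW_DAYS,
) -> ComponentScore:
    if component is Component.RASI_DOSE:
        p = s.prescription_in(RASI_FAMILY)
        value = dose_ratio(p, table) if p is not None else 0.0
        return ComponentScore(component, value, Basis.DOSE_RATIO)
    if component is Component.ARNI_SWITCH:
        on_arni = s.prescription_in(frozenset({DrugClass.ARNI})) is not None
        return ComponentScore(
            component, 1.0 if on_arni else 0.0,
            Basis.BINARY_MET if on_arni else Basis.BINARY_UNMET,
        )
    if component is Component.BB_DOSE:
        p = s.prescription_in(frozenset({DrugClass.BETA_BLOCKER}))
        value = dose_ratio(p, table) if p is not None else 0.0
        return ComponentScore(component, value, Basis.DOSE_RATIO)
    if component is Component.MRA_DOSE:
        p = s.prescription_in(frozenset({DrugClass.MRA}))
        value = dose_ratio(p, table) if p is not None else 0.0
        return ComponentScore(component, value, Basis.DOSE_RATIO)
    if component is Component.SGLT2I:
        on = s.prescription_in(frozenset({DrugClass.SGLT2I})) is not None
        return ComponentScore(
            component, 1.0 if on else 0.0,
            Basis.BINARY_MET if on else Basis.BINARY_UNMET,
        )
    if component is Component.IRON:
        iron = s.iron
        screened_recently = (
            iron.screened_on is not None
            and 0 <= s.day - iron.screened_on <= iron_window
        )
        if screened_recently:
            try:
                deficient = iron_deficiency(iron.ferritin, iron.tsat)
            except UnscreenedError:
                deficient = None
            if deficient is False or (deficient is not None and iron.iv_iron_given):
                return ComponentScore(component, 1.0, Basis.BINARY_MET)
        return ComponentScore(component, 0.0, Basis.BINARY_UNMET)
    raise ConfigError(f"unknown component {component!r}")


def score_component(
    s: PatientSnapshot,
    component: Component,
    table: DoseTable,
    reasons: Optional[Sequence] = None,
    iron_window: int = IRON_SCREENING_WINDOW_DAYS,
    sbp_lookback: int = SBP_LOOKBACK_DAYS,
) -> ComponentScore:
    """Score one component; an applicable valid reason lifts it to 1."""
    if reasons is None:
        reasons = valid_reasons(s, sbp_lookback=sbp_lookback)
    raw = _raw_component(s, component, table, iron_window=iron_window)
    if raw.value < 1.0 and any(r.excuses(component) for r in reasons):
        return ComponentScore(component, 1.0, Basis.VALID_REASON)
    return raw


def gdmt_score(
    s: PatientSnapshot,
    table: DoseTable,
    iron_window: int = IRON_SCREENING_WINDOW_DAYS,
    sbp_lookback: int = SBP_LOOKBACK_DAYS,
) -> GDMTScore:
    """The full six-component score; total in [0, 6]."""
    reasons = valid_reasons(s, sbp_lookback=sbp_lookback)
    return GDMTScore(
        tuple(
            score_component(s, c, table, reasons=reasons, iron_window=iron_window)
            for c in Component
        )
    )


def delta_gdmt(baseline: GDMTScore, followup: GDMTScore) -> float:
    """Change in score over follow-up; positive means therapy improved."""
    return followup.total - baseline.total


def is_omt(score: GDMTScore, components: Optional[Iterable] = None) -> bool:
    """Optimal medical therapy: a score of 1 for every medication group.

    By default all six components must be at 1 (total = 6); ``components``
    narrows the definition (e.g. exclude IRON) if a different convention is
    wanted.
    """
    wanted = tuple(components) if components is not None else tuple(Component)
    return all(score[c].value == 1.0 for c in wanted)


def time_to_omt(
    trajectory: Sequence,
    table: DoseTable,
    horizon: int = 84,
    omt_components: Optional[Iterable] = None,
) -> tuple:
    """First day at which the trajectory satisfies OMT.

    Returns ``(day, True)`` for the earliest qualifying snapshot, else
    ``(horizon, False)`` (censored at the end of follow-up).
    """
    if not trajectory:
        raise DataError("empty trajectory")
    days = [s.day for s in trajectory]
    if days != sorted(days):
        raise DataError("trajectory snapshots must be time-ordered")
    for snap in trajectory:
        if snap.day > horizon:
            break
        if is_omt(gdmt_score(snap, table), components=omt_components):
            return (snap.day, True)
    return (horizon, False)
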