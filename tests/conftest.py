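import hypothesis
import hypothesis.strategies as st
import pytest

from gdmttrial.scoring import (
    DrugClass,
    IronStatus,
    LabPanel,
    PatientSnapshot,
    Prescription,
    VitalsReading,
    default_dose_table,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def dose_table():
    return default_dose_table()


TABLE = default_dose_table()

_RASI_DRUGS = {
    DrugClass.ACE: "ramipril",
    DrugClass.ARB: "candesartan",
    DrugClass.ARNI: "sacubitril/valsartan",
}


@st.composite
def snapshots(draw):
    """Arbitrary well-formed patient snapshots over the packaged dose table."""
    day = draw(st.integers(min_value=0, max_value=84))
    prescriptions = []
    rasi = draw(st.sampled_from([None, DrugClass.ACE, DrugClass.ARB, DrugClass.ARNI]))
    frac = st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0, 1.5])
    if rasi is not None:
        name = _RASI_DRUGS[rasi]
        prescriptions.append(
            Prescription(name, rasi, draw(frac) * TABLE.target_dose(name)))
    if draw(st.booleans()):
        prescriptions.append(Prescription(
            "bisoprolol", DrugClass.BETA_BLOCKER,
            draw(frac) * TABLE.target_dose("bisoprolol")))
    if draw(st.booleans()):
        prescriptions.append(Prescription(
            "spironolactone", DrugClass.MRA,
            draw(frac) * TABLE.target_dose("spironolactone")))
    if draw(st.booleans()):
        prescriptions.append(Prescription("dapagliflozin", DrugClass.SGLT2I, 10.0))
    labs = LabPanel(
        potassium=draw(st.floats(3.0, 6.5)),
        egfr=draw(st.floats(10.0, 120.0)),
        measured_on=day,
    )
    vitals = []
    for offset in sorted(draw(st.lists(st.integers(0, 14), max_size=4)),
                         reverse=True):
        sbp = draw(st.floats(80.0, 170.0))
        vitals.append(VitalsReading(
            day=day - offset, systolic_bp=sbp,
            diastolic_bp=min(sbp - 10.0, draw(st.floats(40.0, 100.0))),
            heart_rate=draw(st.floats(45.0, 110.0)), weight=80.0))
    vitals.sort(key=lambda v: v.day)
    if draw(st.booleans()):
        ferritin = draw(st.floats(10.0, 600.0))
        iron = IronStatus(
            screened_on=day - draw(st.integers(0, 500)),
            ferritin=ferritin, tsat=draw(st.floats(5.0, 60.0)),
            iv_iron_given=draw(st.booleans()))
    else:
        iron = IronStatus()
    allergies = frozenset(draw(st.sets(st.sampled_from(list(DrugClass)), max_size=2)))
    return PatientSnapshot(
        day=day, prescriptions=tuple(prescriptions), labs=labs,
        vitals_history=tuple(vitals), iron=iron, allergies=allergies,
        symptomatic_hypotension=draw(st.booleans()))
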