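import datetime as dt

import pytest

from phasecare import (
    CodeEntry, CodeList, CodingSystem, PatientRecord, Stream, VitalStatus,
    demo_config,
)

PREVALENCE = dt.date(2011, 1, 1)


@pytest.fixture(scope="session")
def prevalence_date():
    return PREVALENCE


@pytest.fixture(scope="session")
def tiny_dlist():
    """A three-stream miniature D-list used by unit tests."""
    return CodeList(
        (
            CodeEntry("85.21", CodingSystem.ICD9CM_PROC, Stream.HD,
                      "Surgery", "Lumpectomy"),
            CodeEntry("99.25", CodingSystem.ICD9CM_PROC, Stream.HD, "Chemotherapy"),
            CodeEntry("V58.0", CodingSystem.ICD9CM_DIAG, Stream.HD, "Radiotherapy"),
            CodeEntry("174.9", CodingSystem.ICD9CM_DIAG, Stream.HD,
                      "Diagnosis and monitoring", "Diagnosis"),
            CodeEntry("89.7", CodingSystem.OUTPATIENT_NATIONAL, Stream.OPS,
                      "Diagnosis and monitoring", "Specialist examination"),
            CodeEntry("90.62.2", CodingSystem.OUTPATIENT_NATIONAL, Stream.OPS,
                      "Diagnosis and monitoring", "Blood test",
                      excluded_from_frequency=True),
            CodeEntry("L02BA01", CodingSystem.ATC, Stream.DP, "Hormone therapy"),
            CodeEntry("L01XC03", CodingSystem.ATC, Stream.HP, "Chemotherapy"),
        ),
        label="tiny D-list",
    )


def make_patient(pid="P1", diagnosis=dt.date(2010, 6, 15), death=None,
                 cancer_death=None, sex="F"):
    return PatientRecord(
        pid=pid,
        sex=sex,
        birth_date=dt.date(1950, 3, 2),
        diagnosis_date=diagnosis,
        topography="C50.9",
        vital_status=VitalStatus.DEAD if death else VitalStatus.ALIVE,
        death_date=death,
        death_cause_cancer=cancer_death,
    )


@pytest.fixture(scope="session")
def demo_cfg():
    return demo_config(seed=20110101)
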