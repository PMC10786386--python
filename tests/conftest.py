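import pytest

from carepath import eventlog, synthdata

# A seven-row / two-patient event log in the documented CSV dialect, covering
# multi-agent records, info-system access, referrals between teams, and a
# trajectory that ends without a discharge action.
TOY_LOG_CSV = """\
patient,setting,presentation,date,time,agents,information_systems,action
1,ED,Associate,01/07/2018,12:52,Triage Nurse; Patient; Associate,EDIS,Referral to Emergency Medical
1,ED,Associate,01/07/2018,13:36,Consultant; Patient; Associate,Patient File,Referral to Emergency Psychiatry
1,ED,Associate,01/07/2018,13:37,Consultant; Psychiatric Liaison Nurse,,
2,ED,Ambulance,02/07/2018,12:15,Triage Nurse; Paramedic,,
2,ED,Ambulance,02/07/2018,12:16,Triage Nurse; Patient,EDIS,Referral to Emergency Medical
2,ED,Ambulance,02/07/2018,12:20,Triage Nurse; Paramedic,EDIS,
2,ED,Ambulance,02/07/2018,12:26,Nurse; Paramedic,Patient File,
"""

# hand-derived edge set of the toy log's interaction network (clique over
# agents plus agent-system pairs, forbidden pairs dropped)
TOY_EDGES = {
    ("Patient", "Triage Nurse"),
    ("Associate", "Triage Nurse"),
    ("Associate", "Patient"),
    ("EDIS", "Triage Nurse"),
    ("Consultant", "Patient"),
    ("Associate", "Consultant"),
    ("Consultant", "Patient File"),
    ("Consultant", "Psychiatric Liaison Nurse"),
    ("Paramedic", "Triage Nurse"),
    ("Nurse", "Paramedic"),
    ("Nurse", "Patient File"),
}


@pytest.fixture(scope="session")
def catalog():
    return synthdata.default_catalog()


@pytest.fixture()
def toy_log_path(tmp_path):
    path = tmp_path / "toy_log.csv"
    path.write_text(TOY_LOG_CSV, encoding="utf-8")
    return path


@pytest.fixture()
def toy_log(toy_log_path, catalog):
    return eventlog.read_event_log(toy_log_path, catalog)


@pytest.fixture(scope="session")
def fixture_log():
    return synthdata.study_scale_fixture()


@pytest.fixture(scope="session")
def fixture_log_with_truth():
    return synthdata.study_scale_fixture(with_truth=True)


@pytest.fixture(scope="session")
def ed_log(fixture_log):
    return eventlog.exclude_mhoa_only_patients(fixture_log)
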