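from datetime import datetime, timedelta

import pytest

from glucaudit.records import MeterRecord, PatientEpisode, TranscribedEntry
from glucaudit.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def study():
    """One full-size synthetic study shared by the expensive tests."""
    return generate_dataset(GeneratorConfig(), seed=1234)


@pytest.fixture(scope="session")
def small_study():
    """A small study for fast structural tests."""
    return generate_dataset(GeneratorConfig(n_patients=40), seed=99)


def mk_meter(rid="R1", vin="V1", t="2016-07-01 10:00", glucose=180, dock_h=4.0):
    tt = datetime.fromisoformat(t)
    return MeterRecord(
        record_id=rid,
        vin=vin,
        test_time=tt,
        glucose_mgdl=glucose,
        operator_id="TECH01",
        dock_time=tt + timedelta(hours=dock_h),
    )


def mk_entry(eid="E1", source="paper_log", vin="V1", t="2016-07-01 10:30", value=180):
    return TranscribedEntry(
        entry_id=eid,
        source=source,
        vin=vin,
        entry_time=datetime.fromisoformat(t),
        value_mgdl=value,
    )


def mk_episode(vin="V1", admit="2016-07-01 00:00", discharge="2016-07-20 00:00",
               diabetes="no", age=60, sex="male"):
    return PatientEpisode(
        vin=vin,
        age=age,
        sex=sex,
        diabetes=diabetes,
        admit=datetime.fromisoformat(admit),
        discharge=datetime.fromisoformat(discharge),
    )
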