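import datetime as dt

import pytest

from htn_rms import (
    BPReading,
    LabPanel,
    MedicationState,
    PatientProfile,
    default_config,
)

ENROLL = dt.date(2022, 1, 3)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def thresholds(config):
    return config[0]


@pytest.fixture(scope="session")
def dosing_table(config):
    return config[1]


def make_week(sbp, dbp, start=ENROLL, days=7, per_day=4, hr=70):
    """A constant week of home readings: `per_day` readings on `days` days."""
    readings = []
    for d in range(days):
        for k in range(per_day):
            hour = 8 if k < per_day / 2 else 20
            readings.append(BPReading(
                timestamp=dt.datetime.combine(
                    start + dt.timedelta(days=d), dt.time(hour, k)
                ),
                sbp=sbp, dbp=dbp, hr=hr,
            ))
    return readings


def make_labs(k=4.0, na=140.0, creatinine=1.0, egfr=80.0, uacr=10.0,
              draw_date=ENROLL - dt.timedelta(days=14), role="followup"):
    return LabPanel(draw_date=draw_date, k=k, na=na, creatinine=creatinine,
                    egfr=egfr, uacr=uacr, role=role)


def make_profile(**overrides):
    base = dict(
        patient_id="t-001", age=55, sex="male", weight=190.0,
        ascvd_risk_10yr=0.2, medication_naive=True,
    )
    base.update(overrides)
    return PatientProfile(**base)


def med(agent, step, weeks_ago=4, as_of=ENROLL + dt.timedelta(weeks=8), intolerant=False):
    """A regimen entry whose last change was `weeks_ago` weeks before `as_of`."""
    change = as_of - dt.timedelta(weeks=weeks_ago)
    return MedicationState(
        agent=agent, dose_step=step,
        start_date=change - dt.timedelta(weeks=4), last_change_date=change,
        intolerant=intolerant,
    )


@pytest.fixture(scope="session")
def helpers():
    class H:
        ENROLL = ENROLL
        make_week = staticmethod(make_week)
        make_labs = staticmethod(make_labs)
        make_profile = staticmethod(make_profile)
        med = staticmethod(med)
    return H
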