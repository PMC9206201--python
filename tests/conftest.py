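import datetime
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rhinodiary.diary import DiaryDay, MonitoringWindow, PatientSeries
from rhinodiary.simulate import SyntheticConfig, generate_cohort

START = datetime.date(2016, 5, 4)


def make_day(patient_id="P1", day_offset=0, vas=0, meds=(0, 0, 0), grades=(0,) * 6):
    """DiaryDay shorthand: day_offset counts from the default window start."""
    return DiaryDay(
        patient_id=patient_id,
        date=START + datetime.timedelta(days=day_offset),
        sneezing=grades[0],
        rhinorrhea=grades[1],
        nasal_pruritus=grades[2],
        nasal_congestion=grades[3],
        itchy_eyes=grades[4],
        watery_eyes=grades[5],
        antihistamine=meds[0],
        nasal_steroid=meds[1],
        systemic_steroid=meds[2],
        vas=vas,
    )


def make_series(patient_id="P1", n_days=56, offsets=(), **day_kwargs):
    window = MonitoringWindow(START, START + datetime.timedelta(days=n_days - 1))
    days = tuple(
        make_day(patient_id, offset, **day_kwargs) for offset in sorted(offsets)
    )
    return PatientSeries(patient_id=patient_id, window=window, days=days)


@pytest.fixture
def window56():
    return MonitoringWindow(START, START + datetime.timedelta(days=55))


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truths, manifest = generate_cohort(SyntheticConfig(n_patients=12, seed=7))
    return cohort, truths, manifest


@pytest.fixture(scope="session")
def default_cohort():
    cohort, truths, manifest = generate_cohort(SyntheticConfig(seed=11))
    return cohort, truths, manifest
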