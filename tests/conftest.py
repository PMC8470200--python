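from datetime import date, datetime, timedelta

import pytest

from wearkg.io import SampleStream, SleepSession
from wearkg.synthetic import SyntheticProfile, generate_subject_days

D0 = date(2021, 3, 1)


@pytest.fixture(scope="session")
def compliant_data():
    """Six problem-free days of one synthetic subject."""
    return generate_subject_days(SyntheticProfile(), 6, seed=1)


def make_stream(kind, values, start=datetime(2021, 3, 1, 8, 0), subject="tms6"):
    """Per-minute stream from a list of values (None = missing minute)."""
    samples = [(start + timedelta(minutes=i), float(v))
               for i, v in enumerate(values) if v is not None]
    return SampleStream(subject_id=subject, kind=kind, samples=samples)


def make_session(day=D0, asleep=420, fall=10, awake=6, awakenings=2,
                 bed_hour=23, efficiency=None, is_main=None, subject="tms6"):
    """Night sleep ending the morning of `day`."""
    start = datetime.combine(day - timedelta(days=1), datetime.min.time()) \
        + timedelta(hours=bed_hour)
    deep = round(0.2 * asleep)
    return SleepSession(
        subject_id=subject, start=start,
        end=start + timedelta(minutes=fall + asleep + awake),
        minutes_to_fall_asleep=fall, minutes_deep=deep,
        minutes_light=asleep - 2 * deep, minutes_rem=deep,
        minutes_awake=awake, awakenings_count=awakenings,
        efficiency=efficiency, is_main_sleep=is_main,
    )


def make_nap(day=D0, start_hour=14.0, asleep=30, subject="tms6"):
    start = datetime.combine(day, datetime.min.time()) + timedelta(hours=start_hour)
    return SleepSession(
        subject_id=subject, start=start,
        end=start + timedelta(minutes=asleep + 2),
        minutes_to_fall_asleep=2, minutes_light=asleep,
        awakenings_count=0, is_main_sleep=False,
    )
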