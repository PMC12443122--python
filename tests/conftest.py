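from __future__ import annotations

from datetime import date, datetime, time, timezone

import pytest

from medwindow import Formulary, Regimen, example_formulary, load_formulary

UTC = timezone.utc


@pytest.fixture(scope="session")
def table1() -> Formulary:
    return example_formulary()


@pytest.fixture
def once_daily_regimen() -> Regimen:
    return Regimen(
        generic_name="amlodipine",
        frequency_per_day=1,
        dose=(5.0,),
        anchor_times=(time(8, 0),),
        timezone="UTC",
        start_date=date(2025, 1, 6),
        end_date=date(2025, 1, 6),
    )


#: A twice-daily medication with a 3-hour safe window (the canonical
#: scheduling scenario), not present in the shipped excerpt.
BID_3H_CSV = """\
generic_name,brand_names,min_dose_mg,max_dose_mg,frequency_per_day,safe_window_hours,dose_options
examplol,N,25,100,2,3,25;50;100
"""


@pytest.fixture(scope="session")
def bid_3h_formulary() -> Formulary:
    return load_formulary(BID_3H_CSV, "csv")


@pytest.fixture
def bid_3h_regimen() -> Regimen:
    return Regimen(
        generic_name="examplol",
        frequency_per_day=2,
        dose=(50.0,),
        anchor_times=(time(8, 0), time(20, 0)),
        timezone="UTC",
        start_date=date(2025, 1, 6),
        end_date=date(2025, 1, 6),
    )


def dt(day: int, hour: int, minute: int = 0, month: int = 1, year: int = 2025) -> datetime:
    return datetime(year, month, day, hour, minute, tzinfo=UTC)
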