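import datetime as dt

import numpy as np
import pytest
from hypothesis import settings

from htarisk import datasets
from htarisk.records import AccidentRecord, RecordSet

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def china_series():
    """The packaged 19-group F-N series with its printed frequencies."""
    return datasets.fn_series_china()


@pytest.fixture(scope="session")
def china_table():
    return datasets.fn_table_china()


@pytest.fixture(scope="session")
def china_slopes():
    """The 18 printed per-point slopes."""
    return datasets.slopes_china().to_numpy()


def make_record(**overrides) -> AccidentRecord:
    base = dict(
        date=dt.date(2010, 6, 15),
        hour=3,
        province="region_01",
        hazmat_classes=frozenset({3}),
        species="oil",
        specific_type=6,
        cause_factor=4,
        road_level=1,
        deaths=1,
        serious_injuries=0,
        economic_loss=50.0,
    )
    base.update(overrides)
    return AccidentRecord(**base)


@pytest.fixture
def small_recordset():
    return RecordSet(
        [
            make_record(deaths=0, serious_injuries=0, economic_loss=5.0, hour=3),
            make_record(deaths=1, hour=8, specific_type=8),
            make_record(deaths=4, hour=14, hazmat_classes=frozenset({2, 3})),
            make_record(deaths=12, hour=20, cause_factor=3),
        ],
        provenance="unit-test",
    )
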