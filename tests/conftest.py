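from datetime import datetime

import numpy as np
import pytest

from emarisk.schema import EMARecord, PeriodSchedule, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def schedule():
    return PeriodSchedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def three_records(schema):
    """One patient answering 3 of 32 items on a single pre-lockdown day."""
    qids = schema.question_ids
    day = "2019-11-05"
    return [
        EMARecord("P001", datetime.fromisoformat(f"{day}T10:30"), qids[0], 7.0),
        EMARecord("P001", datetime.fromisoformat(f"{day}T14:00"), qids[5], 3.0),
        EMARecord("P001", datetime.fromisoformat(f"{day}T21:10"), qids[20], 9.0),
    ]
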