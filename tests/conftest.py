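from datetime import datetime, timedelta

import numpy as np
import pytest

from endoqc.optics import EndoscopeState
from endoqc.registry import Context, MeasurementRecord, Registry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pristine_state():
    return EndoscopeState(serial="SN-001", type_id="TYPE-A")


@pytest.fixture
def registry():
    with Registry(":memory:") as reg:
        yield reg


def make_record(
    serial="SN-001",
    type_id="TYPE-A",
    day=0,
    transmission=80.0,
    contrast=180.0,
    moisture=False,
    context=Context.CLINICAL,
):
    return MeasurementRecord(
        serial=serial,
        type_id=type_id,
        timestamp=datetime(2021, 7, 7) + timedelta(days=day),
        transmission=transmission,
        contrast=contrast,
        moisture=moisture,
        context=context,
    )


@pytest.fixture
def record_factory():
    return make_record
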