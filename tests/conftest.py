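import numpy as np
import pytest

from actirhythm import ActigraphyRecord, LightSchedule


@pytest.fixture
def ld() -> LightSchedule:
    return LightSchedule(cycle_kind="LD")


@pytest.fixture
def dd() -> LightSchedule:
    return LightSchedule(cycle_kind="DD")


def square_wave_record(
    days: int = 4,
    high: int = 10,
    bin_seconds: int = 300,
    schedule: LightSchedule | None = None,
) -> ActigraphyRecord:
    """Noiseless nocturnal square wave: 0 for ZT0-12, ``high`` for ZT12-24."""
    bpd = 86400 // bin_seconds
    day = np.r_[np.zeros(bpd // 2), np.full(bpd // 2, high)]
    act = np.tile(day, days).astype(np.int64)
    return ActigraphyRecord(
        animal_id="sq",
        group="test",
        bin_seconds=bin_seconds,
        activity=act,
        temperature=np.full(len(act), np.nan),
        schedule=schedule or LightSchedule(cycle_kind="LD"),
    )


@pytest.fixture
def square_wave() -> ActigraphyRecord:
    return square_wave_record()
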