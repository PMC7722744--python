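from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from callrhythm.cdr_io import CallRecord, Direction, Mode
from callrhythm.rhythm import DailyRhythm

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def call(owner="A", ts="2019-03-01 09:30", direction=Direction.OUTGOING, peer="C1", dur=60):
    return CallRecord(
        owner_id=owner,
        timestamp=datetime.fromisoformat(ts),
        direction=direction,
        peer_id=peer,
        duration_s=dur,
    )


@pytest.fixture
def make_call():
    return call


def rhythm_from_counts(counts, owner="A", period="T1", mode=Mode.TOTAL):
    counts = np.asarray(counts, dtype=float)
    return DailyRhythm(
        owner_id=owner,
        period=period,
        mode=mode,
        fractions=counts / counts.sum(),
        total_calls=int(counts.sum()),
    )


@pytest.fixture
def make_rhythm():
    return rhythm_from_counts


# 24-bin hourly count vectors with at least one call; normalising them
# yields exactly-representable probability vectors
count_vectors = st.lists(st.integers(0, 60), min_size=24, max_size=24).filter(
    lambda c: sum(c) > 0
)


@st.composite
def probability_vectors(draw):
    counts = draw(count_vectors)
    total = sum(counts)
    return np.array(counts, dtype=float) / total
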