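import numpy as np
import pytest

from fetalprsa import (
    OcclusionEvent,
    OcclusionSchedule,
    ProtocolPhase,
    RRSeries,
)


@pytest.fixture
def constant_series():
    """1200 beats of 500 ms (10 minutes), all original and eligible."""
    return RRSeries.from_rr(np.full(1200, 500.0), subject_id="const")


@pytest.fixture
def toy_schedule():
    """Two phases: BASELINE [0, 120) and MILD [120, 600) with two occlusions."""
    phases = [ProtocolPhase("BASELINE", 0.0, 120.0), ProtocolPhase("MILD", 120.0, 600.0)]
    events = [
        OcclusionEvent(120.0, 180.0, "MILD"),
        OcclusionEvent(270.0, 330.0, "MILD"),
    ]
    return OcclusionSchedule(events, phases)


def alternating_series(n=400, a=400.0, b=10.0):
    """RR alternating a-b, a+b, a-b, ... (even index low, odd high)."""
    rr = np.full(n, a)
    rr[0::2] -= b
    rr[1::2] += b
    return RRSeries.from_rr(rr, subject_id="alt")


def random_series(rng, n=500, base=400.0, sd=20.0):
    rr = base + sd * rng.standard_normal(n)
    rr = np.clip(rr, 50.0, None)
    return RRSeries.from_rr(rr, subject_id="rand")
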