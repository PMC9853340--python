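import sys
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from glucema.events import GlucoseTrace


def make_trace(values, start=datetime(2020, 3, 3, 10, 0), cadence_min=5, pid="P000"):
    """Trace at fixed cadence from a value list."""
    times = np.array(
        [np.datetime64(start) + np.timedelta64(i * cadence_min, "m") for i in range(len(values))],
        dtype="datetime64[ns]",
    )
    return GlucoseTrace(participant=pid, times=times, values=np.asarray(values, float),
                        cadence_min=cadence_min)


@pytest.fixture
def trace_factory():
    return make_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20200303)
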