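"""Hypoglycemia event detection in CGM traces (consensus-style rules).

An event begins with a run of sensor values below threshold (default 70 mg/dL)
containing at least two samples >= 15 minutes apart with no intervening value at
or above threshold.  Once begun, the event persists until a recovery run of at
least two samples at/above threshold >= 15 minutes apart with no intervening
sub-threshold value; the event end is the last sub-threshold sample before that
recovery run, so brief (<15 min) excursions above threshold do not terminate an
event.  Values exactly at threshold count as recovery, making the low/recovery
conditions exhaustive.

Detected events can then be flagged for exclusion (sensor-error jumps, missing
data inside the event) and restricted to the daytime interval used by the
capture analysis (08:00-22:00, one hour of padding around the 09:00-21:00 EMA
delivery span).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

GLUCOSE_MIN = 40.0
GLUCOSE_MAX = 400.0

#: minimum span (minutes) between first and last sample of a qualifying low run
#: or confirming recovery run
MIN_SPAN_MIN = 15.0


@dataclass
class GlucoseTrace:
    """One participant's ordered CGM samples.

    Timestamps must be strictly increasing; the nominal cadence is 5 minutes but
    larger gaps (dropouts) are permitted and simply appear as missing samples.
    """

    participant: str
    times: np.ndarray  # datetime64[ns]
    values: np.ndarray  # mg/dL
    cadence_min: float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > np.timedelta64(0, "ns")).all():
            raise ValueError("trace timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant,
                "timestamp": self.times,
                "glucose_mg_dl": self.values,
            }
        )


@dataclass
class HypoEvent:
    """A detected hypoglycemic episode."""

    participant: str
    start: datetime
    end: datetime
    nadir: float
    threshold: float = 70.0
    excluded: str | None = None  # None | "missing_data" | "jump_artifact"

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class EligibilityReport:
    participant: str
    cgm_hours: float
    eligible: bool


def _minutes(a: np.datetime64, b: np.datetime64) -> float:
    return (b - a) / np.timedelta64(60, "s")


def detect_events(trace: GlucoseTrace, threshold: float = 70.0) -> list[HypoEvent]:
    """Detect maximal, disjoint hypoglycemic events in a trace.

    Pure function of the trace and threshold.  An event truncated by the end of
    the trace (no confirmed recovery) is emitted with end = last sub-threshold
    sample.
    """
    if not 40.0 < threshold < 400.0:
        raise ValueError("threshold must lie in (40, 400) mg/dL")
    n = len(trace)
    if n == 0:
        return []
    t, v = trace.times, trace.values
    low = v < threshold

    # maximal runs of constant low/high state: list of (state, start_idx, end_idx)
    runs: list[tuple[bool, int, int]] = []
    s = 0
    for i in range(1, n + 1):
        if i == n or low[i] != low[s]:
            runs.append((bool(low[s]), s, i - 1))
            s = i

    def spans(i0: int, i1: int) -> bool:
        return i1 > i0 and _minutes(t[i0], t[i1]) >= MIN_SPAN_MIN

    events: list[HypoEvent] = []
    k = 0
    while k < len(runs):
        state, a, b = runs[k]
        if not (state and spans(a, b)):
            k += 1
            continue
        # qualifying onset run: extend through subsequent low runs until a
        # confirming recovery run (or end of trace)
        start_idx = a
        end_idx = b
        k += 1
        while k < len(runs):
            state, a2, b2 = runs[k]
            if state:
                end_idx = b2
                k += 1
            elif spans(a2, b2):
                break  # confirmed recovery
            else:
                k += 1  # sub-15-min blip above threshold: event persists
        seg = v[start_idx : end_idx + 1]
        events.append(
            HypoEvent(
                participant=trace.participant,
                start=pd.Timestamp(t[start_idx]).to_pydatetime(),
                end=pd.Timestamp(t[end_idx]).to_pydatetime(),
                nadir=float(seg[seg < threshold].min()),
                threshold=threshold,
            )
        )
    return events


def apply_exclusions(
    events: list[HypoEvent],
    trace: GlucoseTrace,
    max_jump: float = 40.0,
    max_gap_min: float = 20.0,
) -> list[HypoEvent]:
    """Flag events containing sensor-error jumps or missing data.

    Within each event's [start, end]: an adjacent-sample absolute difference
    greater than ``max_jump`` mg/dL flags ``jump_artifact``; an inter-sample gap
    greater than ``max_gap_min`` minutes flags ``missing_data``.  Flagged events
    are returned (with the flag set) but excluded from downstream counts.
    """
    t, v = trace.times, trace.values
    out: list[HypoEvent] = []
    for ev in events:
        lo = np.datetime64(pd.Timestamp(ev.start))
        hi = np.datetime64(pd.Timestamp(ev.end))
        mask = (t >= lo) & (t <= hi)
        idx = np.flatnonzero(mask)
        reason: str | None = None
        if len(idx) >= 2:
            tt = t[idx]
            vv = v[idx]
            gaps = np.diff(tt) / np.timedelta64(60, "s")
            if (gaps > max_gap_min).any():
                reason = "missing_data"
            elif (np.abs(np.diff(vv)) > max_jump).any():
                reason = "jump_artifact"
        out.append(replace(ev, excluded=reason))
    return out


def restrict_daytime(
    events: list[HypoEvent],
    day_start: time = time(8, 0),
    day_end: time = time(22, 0),
    containment: bool = False,
) -> list[HypoEvent]:
    """Keep events overlapping the daytime interval on any calendar day.

    Default interval 08:00-22:00 (one hour of padding around EMA delivery
    hours).  With ``containment=True`` an event must lie entirely within a
    single day's interval instead.
    """
    if day_start >= day_end:
        raise ValueError("day_start must precede day_end")
    kept: list[HypoEvent] = []
    for ev in events:
        day = ev.start.date()
        hit = False
        contained = False
        while day <= ev.end.date():
            w0 = datetime.combine(day, day_start)
            w1 = datetime.combine(day, day_end)
            if ev.start <= w1 and ev.end >= w0:
                hit = True
                if ev.start >= w0 and ev.end <= w1:
                    contained = True
            day += timedelta(days=1)
        if contained if containment else hit:
            kept.append(ev)
    return kept


def assess_eligibility(trace: GlucoseTrace, min_hours: float = 72.0) -> EligibilityReport:
    """Cadence-weighted CGM coverage; eligible iff coverage >= ``min_hours``.

    Each non-missing sample contributes one cadence interval of coverage, so a
    full 15-day trace at 5-minute cadence yields 360 hours.
    """
    hours = len(trace) * trace.cadence_min / 60.0
    return EligibilityReport(
        participant=trace.participant, cgm_hours=hours, eligible=hours >= min_hours
    )


def events_to_frame(events: list[HypoEvent]) -> pd.DataFrame:
    """Tabulate events in the CSV dialect used throughout the package."""
    return pd.DataFrame(
        {
            "participant_id": [e.participant for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "duration_min": [e.duration_min for e in events],
            "nadir": [e.nadir for e in events],
            "threshold": [e.threshold for e in events],
            "excluded_reason": [e.excluded or "" for e in events],
        }
    )
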