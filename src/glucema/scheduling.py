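"""EMA schedule construction: notification windows, crossover design, counterbalancing.

The pilot design delivers brief cognitive EMAs within prespecified daytime windows
(all between 09:00 and 21:00 local time), under two frequencies arranged in a
crossover: three EMAs/day for 10 days and six EMAs/day for 5 days.  Each EMA
administers one test from each of three cognitive domains, counterbalanced so that
every test appears in exactly half the occasions of each phase (15 of 30), i.e.
30 administrations per test per participant over the full crossover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
import yaml

THREE_PER_DAY = "three_per_day"
SIX_PER_DAY = "six_per_day"

#: Cognitive battery: three domains, two interchangeable tests per domain.
DOMAINS: dict[str, tuple[str, str]] = {
    "processing_speed": ("choice_rt", "dsm"),
    "sustained_attention": ("gradcpt", "psat"),
    "working_memory": ("mot", "flicker"),
}

DEFAULT_BATTERY: tuple[str, ...] = tuple(t for pair in DOMAINS.values() for t in pair)

# Notification windows, inclusive at 1-minute resolution on both bounds.
_WINDOWS = {
    THREE_PER_DAY: (
        (time(9, 0), time(12, 59)),
        (time(13, 0), time(16, 59)),
        (time(17, 0), time(21, 0)),
    ),
    SIX_PER_DAY: (
        (time(9, 0), time(10, 59)),
        (time(11, 0), time(12, 59)),
        (time(13, 0), time(14, 59)),
        (time(15, 0), time(16, 59)),
        (time(17, 0), time(18, 59)),
        (time(19, 0), time(21, 0)),
    ),
}

_DEFAULT_DAYS = {THREE_PER_DAY: 10, SIX_PER_DAY: 5}


@dataclass(frozen=True)
class ScheduleConfig:
    """One EMA frequency schedule: daily windows, duration and response rule."""

    label: str
    windows: tuple[tuple[time, time], ...]
    days: int
    response_window_min: int = 30
    tests_per_ema: int = 3
    battery: tuple[str, ...] = DEFAULT_BATTERY

    def __post_init__(self) -> None:
        if len(self.battery) != 6:
            raise ValueError("battery must contain 6 tests (3 domains x 2)")
        earliest, latest = time(9, 0), time(21, 0)
        prev_end: time | None = None
        for start, end in self.windows:
            if not (earliest <= start <= end <= latest):
                raise ValueError(f"window {start}-{end} outside 09:00-21:00")
            if prev_end is not None and start <= prev_end:
                raise ValueError("windows must be ordered and non-overlapping")
            prev_end = end

    @property
    def per_day(self) -> int:
        return len(self.windows)

    @property
    def total_occasions(self) -> int:
        return self.per_day * self.days

    def to_yaml(self) -> str:
        """Serialize as YAML with windows rendered as "HH:MM-HH:MM" strings."""
        payload = {
            "label": self.label,
            "windows": [
                f"{s.strftime('%H:%M')}-{e.strftime('%H:%M')}" for s, e in self.windows
            ],
            "days": self.days,
            "response_window_min": self.response_window_min,
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScheduleConfig":
        payload = yaml.safe_load(text)
        windows = []
        for w in payload["windows"]:
            s, e = w.split("-")
            windows.append((time.fromisoformat(s), time.fromisoformat(e)))
        return cls(
            label=payload["label"],
            windows=tuple(windows),
            days=int(payload["days"]),
            response_window_min=int(payload.get("response_window_min", 30)),
        )


def build_schedule(label: str, days: int | None = None) -> ScheduleConfig:
    """Return the schedule configuration for a known label.

    Parameters
    ----------
    label : {"three_per_day", "six_per_day"}
    days : optional override of the phase length (defaults: 10 and 5 days).
    """
    if label not in _WINDOWS:
        raise ValueError(
            f"unknown schedule label {label!r}; valid labels: {sorted(_WINDOWS)}"
        )
    return ScheduleConfig(
        label=label,
        windows=_WINDOWS[label],
        days=days if days is not None else _DEFAULT_DAYS[label],
    )


@dataclass(frozen=True)
class Occasion:
    """One scheduled EMA slot in the crossover (a date, window and phase)."""

    day: date
    window_index: int
    schedule: str
    phase: int


@dataclass(frozen=True)
class CrossoverPlan:
    """A participant's two-phase crossover assignment.

    Group A runs three_per_day for 10 days then six_per_day for 5 days; group B
    the reverse.  ``start_date`` is the first analysis day (study day 3: days 1-2
    hold sensor warm-up, baseline and the onboarding EMA, which is excluded from
    analysis and carried only as ``onboarding_date``).
    """

    group: str
    phases: tuple[ScheduleConfig, ...]
    start_date: date = date(2020, 3, 3)
    onboarding_date: date = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        labels = [p.label for p in self.phases]
        if sorted(labels) != sorted([THREE_PER_DAY, SIX_PER_DAY]):
            raise ValueError("plan must contain both schedules exactly once")
        if self.onboarding_date is None:
            object.__setattr__(
                self, "onboarding_date", self.start_date - timedelta(days=1)
            )

    @property
    def total_days(self) -> int:
        return sum(p.days for p in self.phases)

    def occasions(self) -> list[Occasion]:
        """The deterministic 60-occasion skeleton (30 per phase)."""
        out: list[Occasion] = []
        day0 = self.start_date
        for phase_idx, cfg in enumerate(self.phases):
            for d in range(cfg.days):
                for w in range(cfg.per_day):
                    out.append(Occasion(day0 + timedelta(days=d), w, cfg.label, phase_idx))
            day0 += timedelta(days=cfg.days)
        return out

    def phase_dates(self) -> dict[str, tuple[date, date]]:
        """Inclusive calendar range of each phase, keyed by schedule label."""
        ranges: dict[str, tuple[date, date]] = {}
        day0 = self.start_date
        for cfg in self.phases:
            ranges[cfg.label] = (day0, day0 + timedelta(days=cfg.days - 1))
            day0 += timedelta(days=cfg.days)
        return ranges


def build_crossover(group: str, start_date: date = date(2020, 3, 3)) -> CrossoverPlan:
    """Build the group A or B crossover plan (3/day x 10 d and 6/day x 5 d)."""
    three = build_schedule(THREE_PER_DAY)
    six = build_schedule(SIX_PER_DAY)
    phases = (three, six) if group == "A" else (six, three)
    return CrossoverPlan(group=group, phases=phases, start_date=start_date)


def assign_battery(
    occasions: Sequence[Occasion],
    battery: Sequence[str] = DEFAULT_BATTERY,
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Counterbalanced test assignment: one test per domain per occasion.

    Within each schedule phase, each domain's two tests are each assigned to
    exactly half of that phase's occasions, in a seed-reproducible shuffled
    order.  Raises if a phase has an odd occasion count (exact balance would
    be impossible).
    """
    if len(battery) != 6:
        raise ValueError("battery must list 6 tests in 3 domain pairs")
    pairs = [tuple(battery[i : i + 2]) for i in range(0, 6, 2)]
    if not occasions:
        return []

    rng = np.random.default_rng(seed)
    # preserve encounter order of phases
    phase_keys: list[tuple[int, str]] = []
    members: dict[tuple[int, str], list[int]] = {}
    for i, occ in enumerate(occasions):
        key = (occ.phase, occ.schedule)
        if key not in members:
            members[key] = []
            phase_keys.append(key)
        members[key].append(i)

    result: list[tuple[str, str, str] | None] = [None] * len(occasions)
    for key in phase_keys:
        idx = members[key]
        k = len(idx)
        if k % 2:
            raise ValueError(
                f"phase {key[0]} ({key[1]}) has an odd occasion count ({k}); "
                "exact counterbalancing requires an even count"
            )
        per_domain: list[list[str]] = []
        for a, b in pairs:
            seq = [a] * (k // 2) + [b] * (k // 2)
            per_domain.append([str(t) for t in rng.permutation(seq)])
        for j, i in enumerate(idx):
            result[i] = (per_domain[0][j], per_domain[1][j], per_domain[2][j])
    return result  # type: ignore[return-value]


def draw_notification_times(
    config: ScheduleConfig,
    seed: int,
    start_date: date = date(2020, 3, 3),
) -> list[datetime]:
    """Draw one notification per window per day, uniform at 1-minute resolution.

    Both window bounds are inclusive (a 12:59 end admits a 12:59 notification
    but not 13:00).  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    out: list[datetime] = []
    for d in range(config.days):
        day = start_date + timedelta(days=d)
        for w_start, w_end in config.windows:
            lo = w_start.hour * 60 + w_start.minute
            hi = w_end.hour * 60 + w_end.minute
            minute = int(rng.integers(lo, hi + 1))
            out.append(
                datetime.combine(day, time(minute // 60, minute % 60))
            )
    return out


def with_days(config: ScheduleConfig, days: int) -> ScheduleConfig:
    """Copy of ``config`` with a different phase length."""
    return replace(config, days=days)
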