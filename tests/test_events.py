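"""Hypoglycemia detection rules, exclusions, daytime restriction, eligibility."""

from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucema.events import (
    GlucoseTrace,
    apply_exclusions,
    assess_eligibility,
    detect_events,
    restrict_daytime,
)
from oracles import brute_force_events


def _ts(trace, idx):
    return pd.Timestamp(trace.times[idx]).to_pydatetime()


class TestDetectEvents:
    def test_no_low_samples_no_events(self, trace_factory):
        tr = trace_factory([80, 90, 100, 85, 95] * 10)
        assert detect_events(tr) == []

    def test_spec_single_event(self, trace_factory):
        tr = trace_factory([80, 65, 66, 64, 65, 80, 82, 81, 79])
        evs = detect_events(tr)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.start == _ts(tr, 1)
        assert ev.end == _ts(tr, 4)
        assert ev.nadir == 64
        assert ev.duration_min == 15

    def test_sub_15_minute_dip_is_not_an_event(self, trace_factory):
        tr = trace_factory([80, 65, 64, 80, 82, 85, 90, 95])
        assert detect_events(tr) == []

    def test_blip_above_threshold_does_not_end_event(self, trace_factory):
        # 20 min low, 10 min of 75-78, 20 min low, then full recovery
        vals = [80, 65, 64, 63, 64, 65, 75, 78, 66, 64, 63, 62, 61, 80, 85, 90, 95]
        tr = trace_factory(vals)
        evs = detect_events(tr)
        assert len(evs) == 1
        assert evs[0].start == _ts(tr, 1)
        assert evs[0].end == _ts(tr, 12)
        assert evs[0].nadir == 61

    def test_value_exactly_70_counts_as_recovery(self, trace_factory):
        tr = trace_factory([80, 65, 64, 70, 70, 70, 70, 65, 64, 63, 62, 80])
        # the run of 70s spans 15 min => confirmed recovery; neither low run
        # spans 15 min on its own... first run 5 min, second 15 min
        evs = detect_events(tr)
        assert len(evs) == 1
        assert evs[0].start == _ts(tr, 7)

    def test_event_truncated_by_trace_end(self, trace_factory):
        tr = trace_factory([80, 65, 64, 63, 62])
        evs = detect_events(tr)
        assert len(evs) == 1
        assert evs[0].end == _ts(tr, 4)

    def test_empty_trace(self, trace_factory):
        assert detect_events(trace_factory([])) == []

    def test_unordered_timestamps_rejected(self):
        times = np.array(
            [np.datetime64("2020-03-03T10:00"), np.datetime64("2020-03-03T09:55")],
            dtype="datetime64[ns]",
        )
        with pytest.raises(ValueError, match="increasing"):
            GlucoseTrace("x", times, np.array([65.0, 64.0]))

    def test_two_events_separated_by_recovery(self, trace_factory):
        vals = [65, 64, 63, 62, 80, 85, 90, 95, 66, 65, 64, 63, 80]
        tr = trace_factory(vals)
        evs = detect_events(tr)
        assert len(evs) == 2
        assert evs[0].end < evs[1].start

    def test_threshold_54_events_nest_in_threshold_70_events(self, rng):
        from conftest import make_trace

        for _ in range(50):
            n = int(rng.integers(20, 200))
            vals = rng.choice([45, 50, 52, 56, 60, 65, 72, 90, 120], size=n).astype(float)
            tr = make_trace(vals)
            evs54 = detect_events(tr, threshold=54)
            evs70 = detect_events(tr, threshold=70)
            for e in evs54:
                assert any(E.start <= e.start <= E.end for E in evs70)

    def test_determinism(self, rng):
        from conftest import make_trace

        vals = rng.choice([50, 65, 69, 71, 90], size=100).astype(float)
        tr = make_trace(vals)
        a = detect_events(tr)
        b = detect_events(tr)
        assert [(e.start, e.end, e.nadir) for e in a] == [
            (e.start, e.end, e.nadir) for e in b
        ]


class TestOracleEquivalence:
    """The scan detector must agree exactly with brute-force pair enumeration."""

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.sampled_from([50.0, 60.0, 65.0, 69.0, 70.0, 71.0, 80.0, 120.0]),
            min_size=1,
            max_size=60,
        ),
        gaps=st.lists(st.sampled_from([5, 10, 15, 25]), min_size=60, max_size=60),
    )
    def test_matches_brute_force(self, values, gaps):
        t0 = datetime(2020, 3, 3)
        times = [t0]
        for g in gaps[: len(values) - 1]:
            times.append(times[-1] + timedelta(minutes=g))
        tr = GlucoseTrace("x", np.array(times, dtype="datetime64[ns]"),
                          np.asarray(values))
        got = [
            (np.datetime64(pd.Timestamp(e.start)), np.datetime64(pd.Timestamp(e.end)), e.nadir)
            for e in detect_events(tr)
        ]
        exp = [(tr.times[i], tr.times[j], nad) for i, j, nad in brute_force_events(times, values)]
        assert got == exp

    def test_disjoint_with_recovery_between(self, rng):
        from conftest import make_trace

        for _ in range(200):
            n = int(rng.integers(2, 200))
            vals = rng.choice([50, 60, 65, 69, 71, 80, 120], size=n).astype(float)
            tr = make_trace(vals)
            evs = detect_events(tr)
            for a, b in zip(evs, evs[1:]):
                assert a.end < b.start
                between = np.flatnonzero(
                    (tr.times > np.datetime64(pd.Timestamp(a.end)))
                    & (tr.times < np.datetime64(pd.Timestamp(b.start)))
                )
                # a confirmed recovery run exists between consecutive events:
                # a clean >=70 stretch whose first/last samples span >=15 min
                found = False
                for i in range(len(between)):
                    for j in range(i + 1, len(between)):
                        seg = tr.values[between[i] : between[j] + 1]
                        span = (tr.times[between[j]] - tr.times[between[i]]) / np.timedelta64(60, "s")
                        if (seg >= 70).all() and span >= 15:
                            found = True
                            break
                    if found:
                        break
                assert found


class TestExclusions:
    def test_clean_event_unflagged(self, trace_factory):
        tr = trace_factory([80, 65, 64, 63, 62, 80, 85, 90, 95])
        evs = apply_exclusions(detect_events(tr), tr)
        assert evs[0].excluded is None

    def test_jump_artifact(self, trace_factory):
        tr = trace_factory([80, 65, 64, 63, 62, 120, 62, 61, 80, 85, 90, 95])
        # 62->120 is a 58 mg/dL jump inside the event interval (>40 default)
        evs = detect_events(tr)
        assert len(evs) == 1
        flagged = apply_exclusions(evs, tr)
        assert flagged[0].excluded == "jump_artifact"

    def test_missing_data_gap(self):
        times = [datetime(2020, 3, 3, 10, 0)]
        for g in [5, 5, 25, 5, 5, 5, 5, 5, 5]:
            times.append(times[-1] + timedelta(minutes=g))
        vals = [80, 65, 64, 63, 62, 61, 80, 85, 90, 95]
        tr = GlucoseTrace("x", np.array(times, dtype="datetime64[ns]"), np.array(vals, float))
        flagged = apply_exclusions(detect_events(tr), tr)
        assert flagged[0].excluded == "missing_data"

    def test_jump_outside_event_ignored(self, trace_factory):
        tr = trace_factory([80, 200, 80, 65, 64, 63, 62, 80, 85, 90, 95])
        flagged = apply_exclusions(detect_events(tr), tr)
        assert flagged[0].excluded is None


class TestDaytimeRestriction:
    def _event(self, trace_factory, start_hms, n_low=5):
        tr = trace_factory([80] + [64] * n_low + [80, 85, 90, 95],
                           start=start_hms)
        return detect_events(tr)

    def test_night_event_dropped(self, trace_factory):
        evs = self._event(trace_factory, datetime(2020, 3, 3, 2, 0))
        assert restrict_daytime(evs) == []

    def test_boundary_overlap_kept(self, trace_factory):
        evs = self._event(trace_factory, datetime(2020, 3, 3, 7, 45), n_low=8)
        kept = restrict_daytime(evs)
        assert len(kept) == 1

    def test_daytime_event_kept(self, trace_factory):
        evs = self._event(trace_factory, datetime(2020, 3, 3, 10, 0))
        assert len(restrict_daytime(evs)) == 1

    def test_containment_mode_drops_boundary_event(self, trace_factory):
        evs = self._event(trace_factory, datetime(2020, 3, 3, 7, 45), n_low=8)
        assert restrict_daytime(evs, containment=True) == []

    def test_invalid_window(self, trace_factory):
        evs = self._event(trace_factory, datetime(2020, 3, 3, 10, 0))
        with pytest.raises(ValueError):
            restrict_daytime(evs, day_start=time(22), day_end=time(8))


class TestEligibility:
    def test_full_wear_eligible(self, trace_factory):
        tr = trace_factory([100.0] * (15 * 288))
        rep = assess_eligibility(tr)
        assert rep.eligible and rep.cgm_hours == 360.0

    def test_short_wear_ineligible(self, trace_factory):
        tr = trace_factory([100.0] * (60 * 12))  # 60 hours at 5-min cadence
        assert not assess_eligibility(tr).eligible

    def test_exact_72h_boundary_eligible(self, trace_factory):
        tr = trace_factory([100.0] * (72 * 12))
        rep = assess_eligibility(tr)
        assert rep.cgm_hours == 72.0 and rep.eligible
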