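"""Independent brute-force references used to check the fast implementations.

These enumerate candidate index pairs straight from the rule statements
(onset: two sub-threshold samples >= 15 min apart with no intervening value at
or above threshold; recovery: the mirror image), rather than scanning runs the
way the package detector does.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np


def brute_force_events(times, values, threshold=70.0, min_span_min=15.0):
    """Enumerate events as (start_idx, end_idx, nadir) triples.

    O(n^2) candidate-pair search over sample indices.  ``times`` is a sequence
    of datetimes (or datetime64), ``values`` a float sequence.
    """
    times = list(times)
    values = np.asarray(values, dtype=float)
    n = len(values)

    def minutes(i, j):
        d = times[j] - times[i]
        if isinstance(d, timedelta):
            return d.total_seconds() / 60.0
        return d / np.timedelta64(60, "s")

    def clean_pair(i, j, low):
        seg = values[i : j + 1]
        inside = (seg < threshold) if low else (seg >= threshold)
        return bool(inside.all()) and minutes(i, j) >= min_span_min

    events = []
    pos = 0
    while pos < n:
        # earliest onset pair at/after pos
        onset = None
        for i in range(pos, n):
            if values[i] >= threshold:
                continue
            for j in range(i + 1, n):
                if values[j] >= threshold:
                    break
                if clean_pair(i, j, low=True):
                    onset = i
                    break
            if onset is not None:
                break
        if onset is None:
            break
        # earliest recovery pair after onset
        rec = None
        for a in range(onset + 1, n):
            if values[a] < threshold:
                continue
            for b in range(a + 1, n):
                if values[b] < threshold:
                    break
                if clean_pair(a, b, low=False):
                    rec = (a, b)
                    break
            if rec is not None:
                break
        if rec is None:
            lows = [i for i in range(onset, n) if values[i] < threshold]
            end = lows[-1]
            seg = values[onset : end + 1]
            events.append((onset, end, float(seg[seg < threshold].min())))
            break
        lows = [i for i in range(onset, rec[0]) if values[i] < threshold]
        end = lows[-1]
        seg = values[onset : end + 1]
        events.append((onset, end, float(seg[seg < threshold].min())))
        pos = rec[1]
    return events


def capture_by_minute_enumeration(ev_start, ev_end, s_start, s_end,
                                  lookback_min=60, post_min=15):
    """Truth-table capture check by minute-level set membership.

    Builds the episode's minute set and the lookback window's minute set and
    tests the three criteria by explicit membership, independent of interval
    arithmetic.  All datetimes must be minute-aligned.
    """
    def minute_range(a, b):
        out = set()
        cur = a
        while cur <= b:
            out.add(cur)
            cur += timedelta(minutes=1)
        return out

    episode = minute_range(ev_start, ev_end)
    lookback = minute_range(s_start - timedelta(minutes=lookback_min), s_start)
    c1 = bool(episode & lookback)
    c2 = ev_start in minute_range(s_start, s_end)
    c3 = ev_start in minute_range(s_end + timedelta(minutes=1),
                                  s_end + timedelta(minutes=post_min))
    return c1 or c2 or c3
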