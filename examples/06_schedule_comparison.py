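"""Compare the two EMA schedules with paired statistics (a Table-3 analogue).

Participant-level means are computed first; each metric then gets a paired
two-tailed t test and Cohen's dz (= t / sqrt(n)).
"""

from glucema import (
    SimulationParams,
    apply_exclusions,
    detect_events,
    restrict_daytime,
    schedule_table,
    score_sessions,
    simulate_cohort,
    summarize_capture,
)
from glucema.compare import round_for_display

params = SimulationParams(n_participants=18, seed=42)
cohort = simulate_cohort(params)

events = {}
for pid, trace in cohort.traces.items():
    evs = apply_exclusions(detect_events(trace), trace)
    events[pid] = restrict_daytime([e for e in evs if not e.excluded])
capture = summarize_capture(events, cohort.sessions)

scores = score_sessions(cohort.trials)
sched = {s.session_id: s.schedule for ss in cohort.sessions.values() for s in ss}
scores["schedule"] = scores["session_id"].map(sched)

table = round_for_display(schedule_table(scores, capture))
cols = ["metric", "three_per_day_mean", "three_per_day_sd",
        "six_per_day_mean", "six_per_day_sd", "t", "p", "dz", "n"]
print(table[cols].to_string(index=False))
print("\n-> total/captured events favor the 3/day schedule (it spans twice the")
print("   days); performance metrics show no schedule effect by construction.")
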