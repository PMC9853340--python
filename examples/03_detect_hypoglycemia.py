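"""Detect hypoglycemic events in a simulated trace and apply the exclusions.

An event needs a run of sensor values <70 mg/dL spanning >=15 minutes; it ends
at the last low sample before a >=15-minute recovery run at/above threshold.
Events with sensor-error jumps or data gaps are flagged and excluded, and the
capture analysis keeps only events overlapping 08:00-22:00.
"""

from glucema import (
    SimulationParams,
    apply_exclusions,
    assess_eligibility,
    detect_events,
    restrict_daytime,
    simulate_glucose_trace,
)

params = SimulationParams(days=10, seed=5)
trace, truth = simulate_glucose_trace(params, participant_index=0)

events = apply_exclusions(detect_events(trace, threshold=70.0), trace)
kept = restrict_daytime([e for e in events if not e.excluded])

print(f"injected events: {len(truth)}; detected: {len(events)}; "
      f"daytime & unexcluded: {len(kept)}")
for e in kept:
    print(f"  {e.start:%m-%d %H:%M} -> {e.end:%H:%M}  "
          f"({e.duration_min:.0f} min, nadir {e.nadir:.0f} mg/dL)")

rep = assess_eligibility(trace)
print(f"CGM coverage: {rep.cgm_hours:.0f} h -> "
      f"{'eligible' if rep.eligible else 'excluded'} (72 h minimum)")
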