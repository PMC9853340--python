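"""Simulate a small coupled CGM + EMA cohort and look at the ground truth.

The generator writes glucose traces with injected hypoglycemic excursions
(registered in a truth table), EMA sessions with stochastic completion, and
trial-level cognitive records.
"""

from glucema import SimulationParams, simulate_cohort

params = SimulationParams(n_participants=4, seed=11)
cohort = simulate_cohort(params)

pid = "P000"
trace = cohort.traces[pid]
print(f"{pid}: {len(trace)} CGM samples over {params.days} days "
      f"({trace.values.min():.0f}-{trace.values.max():.0f} mg/dL)")
truth = cohort.truth_events
print(f"injected hypoglycemic events (whole cohort): {len(truth)}")
print(truth.head().to_string(index=False))

completed = sum(s.completed for s in cohort.sessions[pid])
print(f"\n{pid} completed {completed}/60 EMA sessions; "
      f"{len(cohort.trials):d} trial records in the cohort")
print("-> the truth table is what detector tests measure recall against.")
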