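"""Build the two EMA schedules and a crossover plan; show the design counts.

Each participant gets 60 EMA occasions (3/day x 10 d plus 6/day x 5 d) with
one test per cognitive domain per occasion, counterbalanced so every test is
administered 15 times per phase, 30 times overall.
"""

from collections import Counter

from glucema import assign_battery, build_crossover, build_schedule

for label in ("three_per_day", "six_per_day"):
    cfg = build_schedule(label)
    windows = ", ".join(f"{s.strftime('%H:%M')}-{e.strftime('%H:%M')}" for s, e in cfg.windows)
    print(f"{label}: {cfg.days} days, windows {windows}")

plan = build_crossover("A")
occasions = plan.occasions()
triples = assign_battery(occasions, seed=7)
counts = Counter(test for triple in triples for test in triple)
print(f"\ngroup A: {len(occasions)} scheduled occasions")
print("administrations per test:", dict(sorted(counts.items())))
print("-> every test is administered 30 times (15 per phase); with even/odd")
print("   halves that is a maximum of 60 half-score measurements per test.")
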