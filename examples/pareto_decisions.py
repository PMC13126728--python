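"""The multi-objective decision layer, one context at a time.

An immune agent weighs candidate actions (attack, proliferate, migrate,
rest) against two objectives - expected pathogens killed vs metabolic
cost - under hard feasibility constraints: an action's energy demand
must be covered by local glucose, and proliferation is forbidden once
systemic lactate reaches the suppression threshold (7.0 mmol/L
equivalents, the severe-intensity-domain criterion).
"""

import numpy as np

from openwindow import DecisionContext, decide_action, nondominated_front

rng = np.random.default_rng(0)
scenarios = [
    ("quiet tissue, fed", DecisionContext(0, local_glucose=10, lactate=0, energy=10)),
    ("one pathogen near", DecisionContext(1, local_glucose=10, lactate=0, energy=10)),
    ("infection cluster", DecisionContext(5, local_glucose=10, lactate=0, energy=10)),
    ("cluster + high lactate", DecisionContext(5, local_glucose=10, lactate=9, energy=10)),
    ("cluster + drained patch", DecisionContext(5, local_glucose=0.2, lactate=0, energy=10)),
]
for label, ctx in scenarios:
    x = decide_action(ctx, rng)
    print(f"{label:>24} -> {x.action}")

print("\nHigh lactate removes 'proliferate' from the feasible set (the")
print("suppression constraint); a drained patch leaves only cost-free rest.")

points = [[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [1.0, 1.0]]
print(f"\nnon-dominated front of {points}: indices {nondominated_front(points)}")
print("(the [1,1] point is dominated; the rest are efficient trade-offs)")
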