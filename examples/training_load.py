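"""From the 4-week session schedule to the simulator's stress input.

The 28-day high-intensity block (22 training days, 6 rest/test slots) is
converted into a per-tick series of lactate injections and glucose
drains: each training day fires a pulse whose lactate amplitude is drawn
from that session's measured blood-lactate distribution and whose
glucose drain scales with the intensity zone; pulses decay with a
3-tick half-life.
"""

import numpy as np

from openwindow import generate_stress_series, table_training_schedule

schedule = table_training_schedule()
series = generate_stress_series(schedule, ticks_per_day=10, seed=1)

print(f"{len(series)} ticks covering {len(schedule)} days "
      f"({series.pulse_days} training-day pulses)")
lac = series.lactate_injection
print(f"peak lactate injection : {lac.max():.1f} mmol/L-equivalents "
      f"(tick {int(lac.argmax())}, day {int(lac.argmax()) // 10 + 1})")
week = lac.reshape(4, 70).sum(axis=1)
for w, total in enumerate(week, start=1):
    print(f"  week {w}: total injected lactate {total:.0f}")
print("Week 4 tapers sharply - the final three days carry no training pulse,")
print("which is what lets glucose and lactate relax before the post-test.")
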