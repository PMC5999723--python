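"""Render the elastic force field and build one block schedule.

The virtual object is a one-sided spring: zero force below the onset
position y0, F = k (y - y0) above it, with a C1 quadratic blend around the
boundary.  Stiffness and onset co-vary on a fixed grid, from a soft spring
engaged at 3 cm (33.3 N/m) to a near-rigid contact engaged 0.5 cm below the
target (2800 N/m).
"""

import numpy as np

from gripswitch import FieldParams, elastic_force, make_schedule

fp = FieldParams(k=2800.0, y0=0.145, w=0.005)
for y_cm in (13.5, 14.0, 14.5, 14.75, 15.0):
    f = elastic_force(y_cm / 100.0, fp)
    print(f"y = {y_cm:5.2f} cm -> F = {f:6.2f} N")
print("(force ramps from 0 to 14 N over the last centimetre of the reach)\n")

sch = make_schedule("ascending", seed=0)
ks = [fp.expected_k for fp in sch.trials]
print(f"ascending block: {len(sch)} trials, {sch.n_real} real + "
      f"{len(sch.catch_indices)} catch")
print(f"stiffness runs {ks[0]:.2f} -> {ks[40]:.0f} N/m over 41 onsets "
      f"(step 0.2875 cm), then a 4-trial plateau")
print(f"catch trials (field silently off) at positions "
      f"{sorted(i + 1 for i in sch.catch_indices)}")
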