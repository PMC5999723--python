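"""Locate when real and catch trials become kinematically distinguishable.

Catch trials carry the same motor plan as real trials but meet no force, so
their acceleration departs from the real-trial acceleration shortly after
the (expected) force onset.  A 20-ms-binned iterative t-test finds the
earliest sustained divergence per participant and stiffness group.
"""

import numpy as np

from gripswitch import ControllerParams, iter_cohort
from gripswitch.pipeline import aligned_accel_snippets
from gripswitch.stats import divergence_time

snippets = {}
for pid, trials in iter_cohort(4, ControllerParams(), seed=9):
    snippets.update(aligned_accel_snippets(trials))

by_group = {}
for (pid, group), mats in snippets.items():
    if len(mats["real"]) < 2 or len(mats["catch"]) < 2:
        continue
    td = divergence_time(mats["real"], mats["catch"], fs=500.0)
    if td is not None:
        by_group.setdefault(group, []).append(td)

print("divergence of real vs catch acceleration after force onset")
print("(stiffness group 1 = softest fields ... 7 = stiffest)")
for g in sorted(by_group):
    vals = by_group[g]
    print(f"  group {g}: {np.mean(vals):5.1f} ms  (n={len(vals)} participants)")
all_vals = [v for vals in by_group.values() for v in vals]
print(f"mean over groups and participants: {np.mean(all_vals):.1f} ms")
print("— catch trials betray themselves within a few tens of ms, while the")
print("  grip force was programmed identically: feedforward, not feedback.")
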