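# gripswitch

Synthetic experiments and switching-detection statistics for feedforward
grip-force control during interaction with elastic force fields.

## The scientific problem

When we move a hand-held object, grip force is adjusted *in anticipation* of
the load force — a hallmark of feedforward control. With smoothly varying
(soft) loads the grip-force peak is synchronized with the load-force peak;
with impact-like (stiff) contacts the grip peak trails the load peak by tens
of milliseconds. Both behaviours are feedforward, yet the underlying
mechanics is a single continuously varying stiffness parameter *k*. Does the
nervous system interpolate between the two timings, or does it *switch*
between two discrete control strategies at a stiffness threshold?

This package provides the full computational apparatus to study that
question on synthetic cohorts:

* **`gripswitch.design`** — the haptic environment: one-sided elastic fields
  `F = k (y − y₀)` for `y ≥ y₀` with a C1 onset blend, and 45-trial block
  schedules in which stiffness ascends from 33.3 to 2800 N/m (or descends),
  with 6 silent catch trials (`k` set to 0) per block.
* **`gripswitch.simulate`** — a generative participant: bell-shaped planned
  reaches whose motor command compensates the expected field, a *switched*
  grip controller whose grip-peak lag rises linearly in ln *k* from ~4 ms to
  a 40 ms plateau at a hysteretic threshold (ln k = 5.07 ascending, 4.89
  descending, crossed with a few trials of inertia), and an inverted-U
  grip-peak amplitude centred on the same threshold.
* **`gripswitch.preprocess`** — the measurement chain: zero-phase 20 Hz
  filtering of central differences, movement-onset (3 cm/s sustained
  100 ms) and impact detection (argmax of the rendered — or, on catch
  trials, reconstructed — elastic force), and per-trial scalar features.
* **`gripswitch.stats`** — the switching estimators: 4th-order polynomial
  extremum of grip peak vs ln *k*, participant-resampling bootstrap CIs,
  continuous hinge regression at a fixed breakpoint with Gaussian
  least-squares AIC (`n·ln(RSS/n) + 2(p+1)`), the 20-ms-binned iterative
  t-test locating the real-vs-catch acceleration divergence, and the
  acceleration-sign threshold.
* **`gripswitch.pipeline`** — `RunConfig`/`run_all` orchestration and the
  deterministic test fixtures; a thin `gripswitch` CLI
  (`simulate | preprocess | analyze | report | fixtures`) wraps it.

## Worked example

`examples/detect_switch.py` simulates six participants (10 blocks × 45
trials each), runs the full pipeline and prints:

```
grip-peak extremum (asc): ln k = 5.074  (159.8 N/m)
grip-peak extremum (desc): ln k = 4.864  (129.6 N/m)
switch threshold:         144.7 N/m
lag, softest field:       4.5 ms
lag, stiffest field:      40.4 ms
hinge slopes:             24.4 (below) / 0.0 (above) ms per ln-unit
hysteresis CI (asc-desc): [0.190, 0.222] excludes 0
slope-difference CI:      [23.6, 25.2] excludes 0
AIC piecewise vs linear:  asc 50.6 vs 165.5; desc 46.2 vs 168.1
real/catch divergence:    26.6 ms after force onset
```

Reading: grip-force peaks are largest near *k* ≈ 145 N/m and that maximum
sits at higher stiffness in ascending than in descending series — the
hysteresis expected of a switch with inertia. The grip/load peak lag rises
~24 ms per ln-unit of stiffness below the threshold and is flat above it; a
two-slope (hinge) model beats a single line by >100 AIC points. Real and
catch accelerations separate ~25 ms after force onset even though grip was
programmed identically, confirming the grip timing is feedforward. The
other example scripts (`render_field_and_schedule.py`,
`simulate_and_extract.py`, `acceleration_divergence.py`) exercise each
capability in isolation.

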