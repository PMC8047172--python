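# batgaze

Acoustic-gaze analysis for echolocating big brown bats (*Eptesicus fuscus*)
flying through narrow, clutter-lined corridors.

When a bat flies down a 40-cm corridor flanked by dense arrays of hanging
chains and has to negotiate an abrupt 90° turn, it steers both its flight
and its *sonar beam*: the beam (−6 dB full width ≈ 55°) is held on the
corridor midline during straight flight and swung proactively into the turn
tens of centimetres before the bat physically arrives.  At the same time
the bat restructures its call timing, packing calls into *sonar sound
groups* (SSGs) — runs of ≥ 2 calls with short, stable internal intervals
flanked by longer ones — at higher rates when the scene is harder to parse.

`batgaze` is a library and CLI for quantifying this behaviour from
multichannel ultrasonic microphone-array recordings, for researchers in
bioacoustics and behavioural neuroethology.  It covers the full chain:

* **synthetic data** — a ground-truthed generator (trajectory, call
  schedule, directional FM chirps, propagation to a 14-microphone
  perimeter array) so every stage is testable by parameter recovery;
* **acoustic front end** — band-limited energy detection per channel,
  received-level measurement, sub-sample time-difference-of-arrival
  (cross-correlation with parabolic peak interpolation, GCC-PHAT
  optional), and multichannel association;
* **localization & beam aim** — planar hyperbolic multilateration
  (closed-form initialization + nonlinear least squares), flight-speed
  segments, and per-call beam-aim estimation by fitting a calibrated
  directivity pattern (circular piston by default) to spreading- and
  absorption-corrected levels;
* **call timing** — inter-pulse intervals, SSG classification with fully
  configurable criteria, SSG proportions, pre/post-IPI "fingerprints";
* **statistics** — the two linear mixed-effects models of post-IPI
  (nested random intercepts bat / condition / day / trial, profiled REML),
  performance ANOVAs, SSG χ² tests, Kolmogorov–Smirnov speed tests,
  Welch t tests, and first-vs-last-day beam regressions
  (Bonferroni-corrected α = 0.004).

## The statistics at the core

**Beam aim.**  Each call is localized from TDOAs
(τ̂ᵢ minimising Σ[(‖x−mᵢ‖−‖x−m_ref‖)/c − τᵢ]²), then the aim azimuth φ is
fitted to corrected levels Lᵢ + 20 log₁₀(rᵢ/r₀) + α rᵢ ≈ SL + G(θᵢ − φ),
where G is the piston pattern 20 log₁₀|2J₁(ka sin θ)/(ka sin θ)| with ka
calibrated so G(±27.5°) = −6 dB.  Angles are signed against the corridor
midline, positive to the bat's right; flightpath position is centimetres
to the turn (0 at the turn, 300 at the start of the measured path).

**Beam segments and shift onset.**  Beam statistics are reported for
beam 1 (300–150 cm) and beam 2 (150–0 cm) and in 10-cm bins; the *shift
onset* is the first beam-2 bin whose mean deviates from the beam-1 mean by
more than one beam-1 SD in the turn direction.

**IPI mixed models.**  Post-IPI is modelled as
`post_ipi ~ condition + covariate + condition:covariate` with nested
random intercepts for bat / bat:condition / :day / :trial, where the
covariate is calls-to-turn (approach model) or day number (days model) and
condition enters as an integer code.  The per-condition slope is
`covariate + interaction × code` (sign-flipped for the count-down
calls-to-turn covariate); `per_condition_slopes` cross-checks any coding
against fitted or published coefficient pairs.

## Worked example

Simulate one right-turn flight and push the rendered 14-channel recording
back through the full measurement chain:

```python
import numpy as np
from batgaze import (Condition, default_room, default_mic_array,
                     simulate_flight, analyze_flight, segment_stats,
                     bin_beam, shift_onset, compute_ipis, classify_ssgs,
                     ssg_proportions)

room = default_room(Condition.RIGHT_TURN)
mics = default_mic_array()
wave, truth = simulate_flight(room, mics, seed=7)   # (14, N) float array
calls = analyze_flight(wave, mics, room)            # per-call table

beam1 = segment_stats(calls, "BEAM1")
beam2 = segment_stats(calls, "BEAM2")
onset = shift_onset(bin_beam(calls), beam1, "right")
labels = classify_ssgs(compute_ipis(calls["emission_time_s"].to_numpy()))
```

Output:

```
calls scheduled: 62, reconstructed: 62
beam 1 (300-150 cm): N=20  M=-0.05 deg  SD=5.66 deg
beam 2 (150-0 cm):   N=22  M=+8.13 deg  SD=12.30 deg
shift onset: 45 cm before the turn
SSG call proportions: {'1': 0.26, '2': 0.65, '3': 0.1}
```

Every scheduled call is recovered; the beam rides the midline over
300–150 cm (mean −0.05°, SD ≈ 6°), swings right over the last
150 cm, and commits to the turn 45 cm before it — with doublets (65 % of
calls) dominating the call timing.  `truth.calls` carries the generating
ground truth for every quantity.

The same stages run from the shell:

```bash
batgaze simulate --out data/ --bats 2 --days 3 --trials 5 --seed 1
batgaze analyze  --dataset data/ --out results/
batgaze validate data/
batgaze report   --results results/
```

`analyze` writes `calls.csv`, `segment_stats.csv`, `binned_beam.csv`,
`shift_onset.csv`, `ssg_labels.csv`, `ssg_proportions.csv`,
`flight_speeds.csv`, `stats.json` and SVG figures, every table keyed by
bat/day/trial/condition and stamped with the configuration hash.

## Layout

```
src/batgaze/
  geometry.py     flight room, conditions, path coordinates, mic arrays
  beam.py         calibrated piston/gaussian directivity patterns
  propagation.py  spreading loss, ISO 9613-1 atmospheric absorption
  simulate.py     trajectories, call schedules, chirps, array rendering
  frontend.py     detection, levels, TDOA, association
  localize.py     multilateration, beam aim, beam statistics, regressions
  timing.py       IPIs, SSG classification, proportions, fingerprints
  lmm.py          nested-random-intercept REML models of post-IPI
  stats.py        ANOVA, χ², KS, Welch wrappers
  experiments.py  study-scale parameter-recovery experiments
  pipeline.py     dataset layout, orchestration, validation
  cli.py          `batgaze` command-line interface
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
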