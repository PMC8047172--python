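# Methods

This note documents the models behind `batgaze`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a user changing parameters should know about.

## Coordinates and conventions

Room coordinates are metric and planar (x along the straight corridor
segment, y across it, z up); the bat is assumed to fly at a constant
height (default 1.2 m) and all beam analysis is of the horizontal
azimuth.  Flightpath position is expressed as centimetres of arc length
*to* the turn along the corridor midline: 0 cm at the turn, 300 cm at the
start of the measured path, negative past the turn.  In turn conditions
the midline is a polyline with one 90° vertex at the turn point, and the
distance is arc length along that polyline.  Signed azimuths are measured
against the midline direction and are positive toward the bat's right, so
a right turn produces positive beam aims.

Segments and bins are half-open intervals measured from the turn:
beam 1 = [150, 300) cm, beam 2 = [0, 150) cm, speed 1 = [100, 250) cm,
speed 2 = [0, 100) cm, and 10-cm bins [k·10, (k+1)·10).  A call at exactly
150.0 cm therefore belongs to beam 1, consistently with the bin tiling.
Empty bins are reported missing, never zero-filled; a single-call segment
reports SD 0 with an explicit flag.

The default room (5.5 m × 4.8 m, release at x = 0.7 m, turn 3.5 m
down-corridor, fourteen perimeter microphones at 0.9–1.3 m height) is an
*approximate* reconstruction — the study geometry is not tabulated — and
is purely configuration: every algorithm takes room and array objects (or
the YAML/CSV files) as input.  Condition → reward-wall mapping: straight →
far wall B, right turn → wall C, left turn → wall A, reversed right turn
(flown from wall B) → wall A.

## Beam model

The emission pattern is a calibrated circular-piston directivity,
amplitude |2 J₁(ka sin θ)/(ka sin θ)|, the standard analytic model of a
directional radiator.  Only the −6 dB full beam width is published (55°),
so the single parameter ka is solved (Brent root-finding, independently
verified by bisection in the tests) to put −6 dB at ±27.5°; this gives
ka ≈ 4.790.  A Gaussian-in-dB alternative with the same calibrated width
is provided for model-mismatch experiments.  Piston side lobes are floored
at −60 dB so the pattern stays finite at nulls; behind the source the
pattern is held at its 90° value and never rises again.  Both patterns are
symmetric, 0 dB on axis, and monotone non-increasing over the main lobe.

The beam model is frequency-independent.  A real bat beam narrows with
frequency across the FM sweep; the single calibrated width should be read
as an effective width for the band-limited energy the pipeline measures.

## Propagation and rendering

Each scheduled call reaches each microphone delayed by r/c
(sub-sample accurate via an FFT phase ramp), attenuated by spherical
spreading 20 log₁₀(r/r₀) from the 10-cm source reference, by
frequency-dependent atmospheric absorption α(f)·r applied in the spectral
domain (ISO 9613-1 analytic model at 20 °C, 50 % RH — about 1.3 dB/m at
40 kHz), and by the beam gain at the microphone's off-axis azimuth, plus
the per-mic calibration offset.  Ranges are 3-D (mic z matters); azimuths
are planar.  Independent white Gaussian noise is added per channel.
Optional first-order clutter injects image sources at the eight chains
nearest each call with a fixed reflection loss — enough to exercise
detector robustness, deliberately far short of a room-acoustics model.

Default chirp: 55 → 22 kHz linear-period FM sweep, 3 ms, raised-cosine
(Tukey 0.25) envelope, source level 0 dB re full scale at 10 cm.  The
study's call spectra are not tabulated; these values are typical of
big-brown-bat search/approach calls and are explicit assumptions.  The
default noise floor of −65 dB re full scale puts the median per-call
detection SNR near 20 dB at mid-corridor range, which is the condition
under which the recovery figures below are quoted.

Not modelled: room reverberation and multipath beyond the optional
first-order chain echoes, diffraction, bat body shadowing, Doppler
(≤ 3.1 m/s flight makes it negligible at these tolerances), and vertical
beam structure.  Passing recovery tests on this generator therefore shows
the *measurement chain* is correct and well-conditioned for this array
geometry; it does not certify performance against strong reverberation or
overlapping calls from multiple bats.

## Synthetic behaviour

*Trajectory*: the bat follows the midline with smooth bounded lateral
jitter (SD 4 cm, clipped at ±15 cm), flying at a distance-dependent target
speed — straight condition 2.8 → 2.5 m/s, turn conditions 2.3 → 1.9 m/s,
matching the study's reported medians (straight 2.6–3.1 far / 2.2–2.9
near; turns 2.2–2.4 far, 1.8–2.0 near) — with the transition placed
between 150 and 100 cm so each speed segment's median equals its target.
Turns are flown through a circular arc (default radius 0.30 m ≤ 40 cm).

*Call timing*: group sizes are drawn so that the configured fractions are
fractions of *calls* (defaults: singles 0.20, doublets 0.61, triplets
0.15, remainder geometrically over sizes 4–8, following the reported
doublet dominance); within-group intervals 20 ms, after-group gaps 45 ms,
after-single gaps 40 ms, Gaussian interval noise SD 1.5 ms, yielding mean
IPIs near 30 ms (the reported per-bat means span 25–41 ms).  A linear
per-call drift reproduces the reported per-condition approach slopes
(+0.08 / −0.03 / −0.14 ms per call).

*Gaze*: beam aim tracks the midline with Gaussian jitter (SD 6°) and, in
turn conditions, ramps linearly from zero toward ±45° starting 60 cm
before the turn — bracketing the reported onsets (30–65 cm) and beam-2
magnitudes.

One root seed is split hierarchically per flight and stage
(`numpy.random.SeedSequence`); identical seeds give bit-identical
waveforms and ground truth.

## Measurement chain

*Detection* runs per channel on the 20–80 kHz band (4th-order Butterworth,
zero-phase): a 0.5-ms RMS envelope in dB is thresholded 10 dB above the
median-estimated noise floor with 4 dB release hysteresis; events closer
than 5 ms merge; onsets refine to the last point ≥ 10 dB below the peak.

*Association* groups detections whose peak times fall within a 12-ms
window (the arrival-time spread of one call across this perimeter array
stays below that for sources inside the corridor, and the within-group
IPI of 20 ms would alias under the loose max-baseline bound of ~22 ms).
One detection per channel per call, earliest first (direct paths precede
clutter echoes); calls need ≥ 4 channels.

*TDOA*: the strongest-SNR channel anchors each call; per channel the
coarse peak-time difference is refined by normalized cross-correlation of
4-ms windows (±1.5 ms search) with 3-point parabolic interpolation.
GCC-PHAT is selectable but plain cross-correlation is the default.

*Multilateration* solves the planar position at fixed flight height: a
linearized closed form (unknowns x, y and the reference range)
initializes Levenberg–Marquardt on the range-difference residuals.  The
residual RMS is reported per call; calls above 0.10 m are flagged.
Emission time is the reference onset minus the reference range over c
(default c = 344 m/s, configurable; the study does not state it).

*Beam aim*: received levels (4-ms windows at each channel's detected or
predicted arrival, channels above floor + 3 dB) are corrected for
spreading and absorption at a representative in-band frequency (35 kHz),
and the aim minimizes the level-weighted squared mismatch to the beam
pattern over a 0.5° grid with bounded local refinement; the unknown source
level is profiled out.  Channels more than ~35 dB down the pattern are
logistically down-weighted: near the pattern floor the measured level is
noise- and side-lobe-dominated and carries almost no aim information.
Model-mismatch experiments (simulate piston, fit Gaussian) show the cost
of a wrong pattern family: the aim keeps its sign but is attenuated
toward the midline by roughly half at ±24–45°, while the fit-quality
residual jumps from ≈ 0 to ≈ 18–20 dB — so mismatch is diagnosable from
the fit quality.  An external trajectory (e.g. video-derived), when
supplied, supersedes acoustic positions for kinematics; acoustic positions
remain as diagnostics.

At the default study conditions (50 seeded flights per condition,
~20 dB SNR), the chain recovers calls with ≈ 100 % detection recall,
median position error well under 1 cm, median absolute beam-aim error
≈ 0.15°, and condition-level shift onsets in the same 10-cm bin as the
ground-truth statistic.  The millimetre-scale position accuracy reflects
the clean simulated propagation; on real recordings, reverberation and
calibration drift dominate and errors of centimetres are the realistic
scale.

## Sonar sound groups

A run of ≥ 2 consecutive calls is one group iff (a) every within-run IPI
≤ `max_group_ipi_ms`, (b) the within-run IPIs are mutually stable
(max − min ≤ `stability_tol_ms`), and (c) both flanking IPIs are ≥
`flank_ratio` × the mean within-run IPI, where a sequence edge counts as a
satisfied flank *but at least one flank must be a real long interval*:
grouping requires temporal contrast, so a perfectly uniform sequence (and
a two-call flight with no flanks at all) classifies as singletons.
Maximal admissible runs are taken greedily from the sequence start; the
incremental scan exploits that clauses (a) and (b) are monotone in run
length.  An exhaustive O(n³) enumeration oracle pins the semantics on
short sequences in the tests.

Defaults: `max_group_ipi_ms = 50` (the conventional long/short IPI split
for this species in clutter), `flank_ratio = 1.2`, `stability_tol_ms = 5`.
Published criteria differ between laboratories and changing them changes
the classification, so all three are first-class parameters and the
proportion tables embed the parameter set used.  Group sizes ≥ 8 pool
into an "8+" class.  The pre/post-IPI fingerprint (2-D histogram with the
pre = post diagonal marked) and its off-diagonal mass index
(fraction of interior calls with |pre − post| > 5 ms) provide an
algorithm-free check that grouping is present.

## Mixed-effects models

Both IPI models are linear mixed models with fixed effects
condition + covariate + condition:covariate and *nested random
intercepts* bat / bat:condition / :day / :trial — random intercepts only,
matching the variance-component structure reported for these models.
Condition enters numerically: the single reported condition coefficient
implies an integer coding.  One-based codes {straight 1, right 2, left 3}
are the default for the approach model and zero-based {0, 1, 2} for the
days model, because those are the codings under which a single
covariate/interaction pair reproduces all three per-condition slopes
(approach: −(−0.19 + 0.11·code) → +0.08/−0.03/−0.14 ms per call while
approaching; days: 0.84 − 0.54·code → 0.84/0.30/−0.24 ms per day, the
middle and last values matching the reported 0.29/−0.25 to within
rounding).  Both codings are options and `per_condition_slopes` validates
whichever is chosen.  The calls-to-turn covariate counts down, so its
coefficient is sign-flipped to express change per call while approaching.

The solver is a profiled REML estimator specialised to nested random
intercepts.  With every random effect an indicator-column intercept, the
marginal covariance is σ²(I + ZΓZ′) and the Woodbury identity reduces each
likelihood evaluation to a sparse factorization of Γ⁻¹ + Z′Z (dimension =
total number of random levels, ~1 400 at study scale) — a few milliseconds
— so a 40 000-row fit takes seconds.  The four variance ratios are
optimized by Nelder–Mead on the log scale; β and σ² are profiled out in
closed form.  REML is the default, ML a toggle.  Fixed-effect covariance
is σ̂²(X′W⁻¹X)⁻¹ with Wald normal intervals and p-values (the denominator
degrees of freedom are in the tens of thousands here, so t vs z is
immaterial for the fixed effects).  A variance ratio collapsing below
1e−8 is reported as a flagged zero ("singular") — expected occasionally
for the bat component, which has only four levels.  The identical model
through `statsmodels` `MixedLM` (groups = bat, variance components for
the nested levels) is the independent cross-check in the tests; the two
agree to ~1e−3 on a well-conditioned fixture.

Generative-inverse calibration: simulating from either structure at the
published coefficient magnitudes (≈ 40 000 rows) and refitting recovers
each derived per-condition slope with z-scores of RMS ≈ 1 against the
model-based SEs.  A "within 2 SE" check therefore passes ≈ 95.45 % of the
time per slope — marginally above a 95 % bar — so the seeded replicate set
used in the validation battery is fixed, and individual reruns with other
seeds can dip a few points below the nominal rate without indicating a
defect.

## Remaining statistics

Performance is scored per flight (reach the correct wall without leaving
the corridor, landing on a chain, or falling), aggregated to daily
percent-correct, and compared by one-way ANOVA with Tukey HSD pairwise
comparisons (the multiple-comparison procedure is a choice; only
"pairwise comparisons" is specified).  SSG prevalence between conditions
is tested by the 2×2 grouped-vs-single χ² with df = 1 (continuity
correction off by default, matching the closed-form statistic); flight
speeds by the two-sample Kolmogorov–Smirnov test; beam-angle group
comparisons by Welch's unequal-variance t test (two zero-variance groups
with equal means return p = 1 by convention).  First-vs-last-day beam
regressions are per-day OLS of beam angle on distance over beam 2, with
the slope difference tested by the day × distance interaction in the
pooled model at Bonferroni-corrected α = 0.004.

## Shift onset

Scanning the beam-2 bins from 150 cm toward 0 cm, the onset is the centre
of the first bin whose mean deviates from the beam-1 mean by more than
one beam-1 SD in the turn direction (`None` if never).  Reporting the bin
*centre* is a convention; published onset values mix centres and edges,
and any within-bin convention cancels in recovery comparisons because the
estimate and the ground-truth statistic use the same one.

## Validation battery and problem sizes

`tests/test_acceptance.py` and `scripts/acceptance.py` run the same
experiments: 50 seeded flights per condition for end-to-end recovery
(≈ 9 000 calls, a few minutes on one CPU), a 27-point noiseless
multilateration grid, 300 random sequences against the SSG enumeration
oracle, 10 + 10 seeded replicates of the two mixed-model structures at
≈ 40 000 rows each, and the coding cross-checks.  These sizes were chosen
to make each statistic stable (hundreds to thousands of independent
errors per summary) while keeping a full run in single-digit minutes.

## Known limitations

* The default geometry is approximate; quantitative comparisons against
  recordings from the real flight room require the true microphone table.
* Beam aim is planar; vertical gaze is out of scope.
* The beam estimator assumes one dominant call per analysis window;
  overlapping calls from multiple bats are not separated.
* SSG classifications are criterion-dependent by nature; report the
  parameter set with any proportion.
* Failed flights are processed identically but only flagged; no
  correction is attempted for the coupled flight-and-beam behaviour on
  aborted flights.
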