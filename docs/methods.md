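# Methods

This note documents the models, algorithms and numerical choices behind
`turncoord`, including where the design was genuinely open and what the
synthetic-data tests do and do not demonstrate about real recordings.

## Coordinate conventions and data model

The lab frame is right-handed, z vertical (gravity axis), x along the
walkway; yaw is rotation about z, in degrees. Marker positions are meters.
Occluded samples are NaN end to end: the C3D reader maps negative residuals
to NaN, the occlusion policy linearly interpolates interior gaps of at most
10 samples (50 ms at 200 Hz), and longer gaps stay NaN so that any turn
overlapping them is discarded rather than imputed.

## Segment yaw

Each of head, sternum and pelvis carries a rigid cluster of ≥3 markers. Per
frame, the least-squares rotation mapping the first valid frame's (centered)
cluster onto the current one is found by orthogonal Procrustes/Kabsch (SVD
with reflection guard), batched over frames. Yaw is the z angle of the
z–y–x Euler decomposition, extracted first; pitch and roll are discarded —
only rotation about the vertical enters any downstream measure, so the
sequence choice is documented for reproducibility rather than load-bearing.
Yaw is unwrapped within each contiguous valid run. Collinear reference
clusters (second singular value ≈ 0) are rejected: yaw would be
unobservable.

Angular velocity = zero-phase 4th-order Butterworth low-pass of yaw
(default cutoff 6 Hz — turning dynamics live below ~2 Hz, marker jitter
well above) followed by central differences.

## Turn detection

The detector is built entirely on the two-region mean-shift statistic: the
best single split of a window is the index minimizing the summed residual
squared error of the two sides around their own means (ties to the smallest
index). Three stages:

1. **Global segmentation.** Penalized binary segmentation of the filtered
   yaw: a split is accepted when it reduces the residual error by more than
   a penalty; accepted regions are re-split recursively. The default
   penalty is BIC-style, `3 σ̂² log T`, with σ̂ a MAD estimate from first
   differences of the raw yaw, floored at 1 deg²·sample so that noise-free
   signals do not degenerate to a zero penalty.
2. **Plateau identification.** Segments between change points are
   classified by mean |yaw rate| against 20 deg/s; maximal low-rate runs of
   at least 0.8 s are heading plateaus (straight-walking stretches are
   seconds long). Consecutive plateaus whose levels differ by at least the
   minimum turn magnitude (default 90°, since the paradigm contains only
   ~180° turns) bracket one candidate turn.
3. **Boundary refinement.** The outermost *global* change point of a smooth
   transition is poorly localized: near the plateau junction the signal
   leaves its mean only cubically, so under noise its position — and worse,
   the classification of the small adjacent segments — can wander by
   ~100 ms. Each boundary is therefore re-estimated by one local mean-shift
   split on a window reaching 3.5 s into the plateau from the transition's
   15%-of-level-change crossing (that crossing sits on the steep part of
   the transition and is stable to a couple of samples). On noise-free
   synthetic trials this reproduces onset latencies exactly; with 2 mm
   marker noise, per-turn pair latencies are recovered within 25 ms in
   ≥95% of turns.

A turn's magnitude is |yaw(end) − yaw(start)| at the refined boundaries.
Because those boundaries lie strictly inside a smooth transition, detected
magnitudes under-read the nominal angle — ≈162° for a 180° sigmoid turn at
the defaults, i.e. a systematic ~10% clipping that is a property of
plateau-based boundary placement, not noise. Peak angular velocity is taken
within each segment's own turn window.

## Gait events and steps while turning

Vertical velocity of toe and heel markers (2nd-order Butterworth at 6 Hz,
then central differences — the gentler roll-off biases the swing bump's
extremum less than a sharper filter whose longer impulse response reaches
the stance-phase truncation). Initial contacts are prominent local minima
of toe vertical velocity; final contacts prominent maxima of heel vertical
velocity; peaks below 0.2 m/s prominence or closer than 0.3 s are
suppressed, and an alternation-repair pass drops the less prominent of two
consecutive same-kind events. Steps while turning are initial contacts of
both feet in the half-open pelvis turn window `[start, end)` — the pelvis
being the most whole-body-representative segment; this window convention
was an open choice and is configurable in spirit by counting against any
other segment's events.

## Coordination measures

Turns are matched across segments greedily, anchored on head events:
nearest-onset events of the other segments within 1.5 s and with the same
direction. Turns any segment missed are excluded from all averages.

Onset latency of a pair = `start(cranial) − start(caudal)`: negative
exactly when the more cranial segment started first. Latencies average
*signed* across turns — the sign carries the top-down/bottom-up
information — and are additive by construction
(`head→pelvis = head→sternum + sternum→pelvis`).

Maximum intersegmental angle = max |ψ_cranial − ψ_caudal| over the union of
the pair's turn windows, after subtracting each signal's mean over a
pre-turn reference window (0.5 s long, ending 0.1 s before the earlier turn
start) so static posture offsets between segments cancel. Whether raw or
re-referenced differences are "the" intersegmental angle was open;
re-referencing makes the en bloc limit exact (identical signals → 0°).

## Dual-task cost

`DTC = 100 (ST − DT)/ST` (default), so a dual-task-related drop in a
higher-is-better measure (peak angular velocity) is a positive cost; the
`relative_change` convention returns `100 (DT − ST)/ST` for measures that
grow under load (duration, steps). The two differ only by sign and all
identities (zero at ST=DT, scale invariance, `DTC(st, st(1−x)) = 100x`)
hold under either.

## Statistics

`mixed_anova` runs the split-plot ANOVA (between: group; within: condition)
via pingouin, preceded by an optional gait-speed covariate adjustment: the
covariate is grand-mean centered, a single common slope is estimated from
variation *within* group×condition cells (so group or condition differences
cannot leak into the slope), and values are replaced by their adjusted
counterparts. The covariate enters per subject×condition cell by default
(speed varies by condition); `covariate_mode="subject_mean"` switches to a
per-subject covariate. Greenhouse-Geisser correction is applied to the
repeated factor when Mauchly's test rejects sphericity at .05; the working
p value records which was used. Degenerate inputs (identical values in all
cells) short-circuit to F = 0, p = 1. Post hoc pairwise t tests
(independent for group, paired for condition) are Bonferroni-adjusted,
`min(1, m·p)`, and by convention run only behind a significant main effect
(`force=True` overrides).

Null-cohort simulations (2 groups × 10 subjects × 3 conditions, standard
normal values, 1000 replicates) put the empirical type-I error of each
factor within [0.035, 0.065] at α = .05; F statistics agree with an
independently coded textbook sums-of-squares computation to 1e-8 on
balanced integer designs.

## The synthetic trial generator

The generator emulates the walkway paradigm: straight bouts of
`walkway_length / speed` seconds alternate with turn blocks long enough for
the slowest segment's transition; turn direction alternates (up-and-down
walking); the realized trial length is whatever the configured pattern
needs (~30 s at the defaults).

**Transitions** are quintic smoothstep sigmoids,
`s(u) = 6u⁵ − 15u⁴ + 10u³` on compact support, with `turn_duration_s`
defined as the 5–95% span (a fixed ≈0.6215 of the support) and analytic
peak rate `1.875 · magnitude / support`. A logistic was the obvious
alternative and was rejected: its tails never reach the plateau, leaving
~0.02° residue at realistic inter-turn spacing, whereas plateau-level
ground truth should be exact. Duration and per-segment peak velocity are
redundant for a fixed-shape transition, so duration is primary and an
optional per-segment peak-velocity map rescales that segment's support.

**Locomotion** continues through the turn at constant horizontal speed: the
motion heading ramps 0↔180° with the same smoothstep over the full turn
block, so the path is a straight bout joined to a semicircular arc —
closer to the real paradigm's continuous walking than stopping to turn, and
it makes configured gait speed recoverable to <0.1%. The heading ramp is
deliberately common to all segments; only the triad rotations carry the
per-segment latencies.

**Feet** step continuously at the configured cadence (default 1.8 steps/s,
40% swing): each swing lifts toe (5 cm) and heel (7 cm) markers along a
sin² bump. Ground-truth final/initial contact are the analytic extrema of
heel/toe vertical velocity at 1/4 and 3/4 of swing — "contact" is defined
*as* the velocity-extremum instant, which is exactly the feature the
detector targets.

**Defaults** represent a healthy young adult on the study paradigm: 4 turns
of 180°, 2.0 s transitions (peak yaw rate ≈105 deg/s), onset latencies
sternum 80 ms and pelvis 180 ms after the head (a typical healthy top-down
sequence), 1.2 m/s walking speed, 5-m walkway, 200 Hz sampling, 2 mm
Gaussian marker noise (typical optical-capture jitter). Cohort simulation
layers lognormal multipliers (median 1) on duration, speed and latencies:
SD 0.10/0.10/0.15 between subjects and half that between trials within a
subject, then condition-effect multipliers on top.

**What the generator does not model** — and hence what passing tests do not
establish about real data: soft-tissue artifact and systematic (non-white,
non-stationary) marker error; pitch/roll motion of the segments; speed
fluctuation within bouts; asymmetric, hesitant or multi-step "stepping"
turns; turn-to-turn learning or fatigue; and any true coupling between
cognitive load and kinematics beyond imposed parameter shifts. Recovery
accuracy quoted above is accuracy *under this generative model*.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
recovery checks use 100 synthetic trials per condition (≈35 s trials at
200 Hz), oracle equivalence uses 1000 random signals (T ≤ 200) plus 60
short staircases against a dynamic-programming segmentation oracle, and
ANOVA calibration uses 1000 null replicates. The full suite runs in under
two minutes on one CPU.

## Known limitations

- Binary segmentation is greedy; it provably matches the optimal
  segmentation only in the strong-signal regime the tests exercise.
- The boundary-refinement window (3.5 s into the plateau) assumes plateaus
  of at least ~1 s; trials with extremely short straight bouts fall back to
  whatever plateau is available and lose boundary precision.
- The C3D support is a deliberately small subset (Intel byte order, float
  or integer point data, no analog channels) sufficient for marker
  pipelines; files from exotic acquisition systems may need conversion.
- Latencies are estimated from detected boundaries, so segments whose turn
  a change-point pass misses entirely (heavy occlusion) drop the whole turn
  from every measure rather than biasing it.
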