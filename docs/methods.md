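# Methods

This note documents the models, conventions and parameter choices behind
`efrp`, in the order the pipeline runs them, followed by the synthetic
data model and the validation strategy.

## Streams and clock

All streams share one session clock in float seconds, mirroring a
lab-streaming-layer style acquisition; each stream carries absolute
timestamps, and no resampling is performed.  Event-to-EEG mapping uses
floor rounding on 0-based sample indices throughout:
`sample = floor((t − start_time) · fs)`.  All sample windows are
half-open.  These conventions make every result bit-reproducible.

Screen geometry defaults to the centre monitor of the simulator: 1024×768
pixels viewed from 100 cm.  The physical panel size is not part of the
study description; we default to 38.4 × 28.8 cm — a 4:3 panel with square
pixels at 26.67 px/cm (≈19″ viewable) — and expose it in the
configuration.  One degree of visual angle is then ≈46.6 px.

## Fixation detection

* **Cyclopean gaze** is the mean of the valid eyes; if one eye is invalid
  the other is used alone; if both are invalid the sample is excluded and
  breaks fixation runs.  The binocular-fusion rule is our choice; the
  source analysis does not state one.
* **Velocity** is a two-point backward difference of the cyclopean
  position converted to visual angle (`pixels → cm → atan(d/D)`), with no
  smoothing by default (a centred moving average is available).  The first
  sample copies the second sample's velocity.
* **I-VT**: samples with velocity `< 30°/s` belong to fixations; maximal
  sub-threshold runs become fixations with onset at the first member
  sample and duration equal to the first-to-last timestamp span.
  Fixations shorter than 60 ms are discarded.
* **Merging**: adjacent fixations with centroid separation `< 0.5°` and
  gap `< 75 ms` merge (onset of the first, span of both plus gap,
  duration-weighted centroid), leftmost pair first, iterated to a fixed
  point; the 60 ms filter is re-applied afterwards.  Whether the original
  analysis merged before or after the duration filter is unstated; we
  filter, merge, re-filter, which is idempotent and never loses a long
  fixation to an unmergeable short neighbour.

A consequence of the backward difference worth noting: the first sample
of a plateau inherits the preceding saccade's velocity, so detected
onsets lag true fixation onsets by exactly one gaze sample (1/120 s ≈
8.3 ms).  This is inherent to backward-difference I-VT, shifts all epoch
time-locks uniformly, and is accounted for explicitly in the recovery
analysis (below).

## Areas of interest

AOI tracks are keyframed bounding boxes (≈3 keyframes per second while a
target is in useful view), linearly interpolated between keyframes and
clamped to the edge boxes outside their span.  Padding is physical:
3 cm for the speedometer, 10 cm for the billboard (viewers aim at the
centre of large targets), 2 cm for the speed sign (our choice; unstated).
Padded boxes are clamped to the screen.  Sign and billboard tracks exist
per road region and participate in hit-testing only while active (between
their first and last keyframe); the speedometer track is constant and
spans the session.  Fixations are hit-tested at onset time — boxes move
slowly relative to fixation durations — with fixed precedence speed sign
→ speedometer → billboard for the rare overlap.

Segments are anchored to the billboard-pass events: each window ends at
its pass time and spans `min(15 s, time since previous pass)`
("approximately 15 s" is read as exactly 15 s; windows never overlap).

## Condition events

Epoch-locking events are fixations longer than 200 ms.  For conditions A
and B, the speedometer fixation's most recent preceding non-white-space
fixation within the same segment must be on the speed sign: intervening
"other" fixations are tolerated (drivers saccade through empty scene
between targets) but intervening sign/billboard fixations break the
sequence.  The speed-change criterion — a change of at least 2 km/h
within 3 s of the fixation onset, boundary inclusive — is a configurable
default of this package, not a value inherited from the source analysis,
which does not quantify "speed change".  Condition C requires onset
strictly after the billboard-change event (ties go to not-C); condition D
takes the last billboard fixation with onset before the pass.  Each
fixation yields at most one label.

## EEG processing

* **Filter**: Hamming-windowed sinc band-pass, 0.16–30 Hz, order 424
  (425 symmetric taps), applied in one forward pass with group-delay
  compensation (shift by order/2); a zero-phase two-pass variant is
  available via configuration.
* **Channel rejection**: a channel is dropped when the robust z-score
  (median/MAD) of its log variance exceeds 5, or when its variance
  exceeds the lower-quartile variance a thousandfold (an absolute
  criterion that keeps majority-bad montages detectable).  Rejection is
  one-sided — only high-variance channels are artifact candidates — so
  noiseless synthetic recordings with quiet channels pass through
  unchanged.  This is a documented stand-in for the unspecified automatic
  criterion of the original toolbox.  Dropped channels are excluded from
  all downstream averages, never interpolated: the 16-site montage is too
  sparse to reconstruct a site from neighbours.  Rejecting more than half
  the montage is a hard error.
* **Epochs**: −200..800 ms around each event onset — at 512 Hz exactly
  512 samples with the onset at sample 102 (`floor(0.2·512)` pre-onset
  samples, half-open end).  Baseline correction subtracts the per-channel
  mean of the samples strictly before onset.  Epochs in which any
  retained channel exceeds ±75 µV are rejected; with independent-component
  artifact removal out of scope, this threshold is the sole guard against
  blink contamination, and the synthetic blink amplitude (200 µV) is
  chosen so it always triggers.
* **Grand averages** are pointwise means per condition over artifact-free
  epochs, pooling participants on the intersection of retained channels.
* **Component peaks**: window maximum (positive components) or minimum
  (negative) per electrode, ties to the earliest sample; P1 at PO1/PO2 in
  50–100 ms, N1 at PO1/PO2 in 75–125 ms, P2 at Pz/P2/Cz in 150–225 ms,
  N2 at Cz in 225–275 ms.
* For statistics, per-electrode measures are taken per participant per
  condition from that participant's own average, giving the
  condition × electrode ANOVA its expected cell structure (e.g. 4
  conditions × 2 electrodes × 8 participants → residual df 56; with three
  electrodes → 84).

## Statistics

Means use sample SD (n−1) and SE = SD/√n.  The paired t-test is
`t = mean(d)/(SD(d)/√n)` with df = n−1 and a two-sided p; for eight
participants we therefore report t(7).  (The published write-up of the
packaged table prints "t(8)" alongside eight non-primed participants; the
t values themselves reproduce exactly, and we report the conventional
df = n−1 rather than replicate the label.)  The two-way ANOVA is a
fixed-effects fit with interaction on (near-)balanced cell tables; Tukey
HSD uses the studentized-range distribution with the ANOVA error df and
the Tukey–Kramer standard error for unequal group sizes.  Welch's ANOVA
uses the standard weighted form with Welch–Satterthwaite fractional
denominator df.

The AOI time-share percentages are computed from the non-primed mean row
of the packaged table: `share(aoi) = (dynamic mean + static mean) / grand
total`.  This definition — and only this one — reproduces the published
shares (18.4 / 26.8 / 9.0 / 45.2 %).  The published "average 26 %
increase" of dynamic over static billboard dwell is ambiguous between a
ratio of means (32.9 %) and a difference over the dynamic mean (24.8 %);
the report prints both candidates, labelled, and targets neither.  One
cell of the all-participants block (SE of static speed-sign dwell) prints
as 16.68 in the published table but recomputes as 16.83 = 53.23/√10; we
treat this as a typo and report the recomputed value.

## Synthetic sessions

The generator emulates the study conditions with known ground truth.

**Course and kinematics.** 50 regions; sign spacing 300/400/500 m at
40/60/80 km/h limits with counts 18/13/19; no two consecutive equal
limits; 25 static and 25 dynamic billboards; dynamic content changes at
80 m.  The car drives piecewise-constant speeds with 2 s linear
adjustment ramps; in each region the driver adjusts towards the posted
limit with probability 0.65 (when the difference is ≥ 2 km/h), starting
95 m before the billboard.  One run lasts ≈20 min.  Only event timing
matters downstream, so no richer vehicle dynamics are modelled.

**Scanpath.** Within each region the driver fixates the sign (one or two
fixations, ≈1.1–1.5 s each, beginning ≈150–200 m out), then the
speedometer (≈1.5 s, anchored 105 m out so an adjustment falls inside the
3 s speed-change window), then the billboard (a ≈0.95 s engagement after
the change for dynamic regions, with optional pre-change and follow-up
glances; a ≈0.85 s final fixation before the pass for static regions,
scheduled while the billboard is still on screen).  White-space fixations
(≈0.4 s) fill the remaining time, sampled outside every active padded AOI
box over the fixation's whole time horizon and at least 1° from the
previous target.  Dwell distributions are free parameters calibrated only
in aggregate to resemble the published per-segment proportions (long
sign/speedometer dwell, short billboard engagement, dynamic > static).
Gaze is 120 Hz: plateaus with 1.5 px jitter (sub-threshold by a wide
margin) joined by 3–5-sample saccades whose every inter-sample step is
supra-threshold, plus a ±1 px vergence offset, 0.5 px per-eye sensor
noise, and sporadic single-eye dropouts (0.4 %).

Ground-truth condition labels are derived by applying the package's own
event rules to the true fixation list, so truth and streams are
consistent by construction; agreement tests between the pipeline and the
truth therefore isolate detection and AOI-assignment error, while the
rules themselves are tested separately against a brute-force evaluator.

**EEG.** The recording is the sum of per-condition component templates —
Gaussian bumps with per-electrode weights, giving analytically known
peaks — locked to the labelled fixation onsets, plus noise.  Default
templates place P1 (+5 µV, 70–78 ms, σ = 10 ms) and N1 (−4 to −5.5 µV,
104–110 ms, σ = 12 ms) at PO1/PO2, P2 (+3.8 to +5 µV, 185–195 ms,
σ = 14 ms) centrally, and, in condition A only, an N2 (−4.5 µV, 247 ms,
σ = 12 ms) at Cz — the speed-adjustment motor-preparation signature.
Conditions differ qualitatively as in the study: earlier P1 and larger
N1/P2 for billboard fixations, N2 only with speed adjustment.

Noise is pink (1/f power, flattened below 0.5 Hz) at 3 µV per-sample
standard deviation — chosen once, before any acceptance measurement, as a
realistic residual background for an artifact-cleaned recording in the
0.16–30 Hz band, with a design-stage power analysis confirming that a
≈100-trial grand average then determines peak latency to one sample and
amplitude to well under 15 % — plus 50 Hz mains (1 µV, removed by the
filter) and 200 µV, 300 ms frontal blink lobes at 6/min.  Blinks occupy
white-space scan intervals and keep a guard zone around labelled fixation
onsets, modelling blink suppression during task-relevant fixation
sequences; the ±75 µV rejection mechanism is exercised separately with
the guard disabled and with constructed epochs.  Without ICA, the
blink-dominated frontal channels (AF3/AF4) are flagged by the variance
criterion and excluded — none of the measured electrodes is affected.

## Parameter recovery and problem sizes

Recovery compares pipeline measurements on pooled grand averages against
an expectation computed by direct arithmetic on the template definitions:
the filtered template (discrete convolution with the same taps — a known
linear map, so residual error isolates pipeline defects rather than
filter roll-off), averaged over the 15 possible phases of the
120 Hz-grid onset relative to the 512 Hz grid including the one-sample
detector lag, baseline-corrected, and peak-picked in the component
window.  Noiseless recovery is exact to one EEG sample in latency and
0.1 % in amplitude; at default noise, cohorts of 4 participants
(≈90–110 trials per condition after rejection) recover latencies within
one sample and amplitudes within 15 % in ≈9 of 10 seeds.

Test problem sizes are chosen for tight feedback: oracle-equivalence
suites use 1000 random small inputs each; integration tests use an
8-region course (the full 50-region course appears in the acceptance
checks and the acceptance script); the dwell-contrast power check uses 25
cohorts of 8 drivers on the 8-region course.

## What passing tests do and do not show

The generator's scanpath is schedule-driven and far more regular than
human scanning: no smooth pursuit of the scene flow, no microsaccades or
saccadic suppression, no pupil dynamics, no attention lapses, and blink
timing is behaviourally idealised.  EEG noise is spatially independent
across channels, while real background EEG is strongly correlated; real
EFRPs also overlap between successive fixations, which the generator
avoids by spacing labelled events beyond the epoch span.  Passing
recovery therefore validates the pipeline's arithmetic and bookkeeping —
detection conventions, epoch alignment, rejection logic, averaging and
measurement — not robustness to every artifact of real recordings.
Primed-participant behaviour is not modelled (their ERP data were
excluded from the contrasts in the source study), and no claims are made
about real-cohort grand-average amplitudes, latencies or trial counts.
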