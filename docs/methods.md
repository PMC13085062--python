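# Methods

`sts2walk` analyzes the smartphone-instrumented one-minute sit-to-stand
test (1MSTST): a subject, phone held against the chest, stands up and
sits down as many times as possible in 60 seconds while the phone logs
triaxial acceleration (g) and angular velocity (deg/s) at a nominal
100 Hz.  The pipeline detects and timestamps every repetition, computes
movement features, and evaluates regression models that predict the
6-minute walk distance (6MWD, metres) — the standard field measure of
functional exercise capacity — from those features.  Because clinical
recordings of this kind are rarely shareable, the package includes a
kinematic simulator and a calibrated cohort generator that together form
its validation bed.

## Signal conditioning

Raw acceleration is low-pass filtered with a 51-tap Hamming-window FIR
filter (cutoff 5 Hz) followed by a 0.25 s centered moving average.
Sit-to-stand movement energy lies below ~3 Hz, so these defaults pass the
movement intact while suppressing tremor and sensor noise; both are
configurable (`preprocess:` section of the config).  Filters are applied
zero-phase (forward–backward), so downstream timestamps carry no group
delay.  The moving average uses shrinking windows at the series edges, so
constant inputs are exact fixed points.

The gravity direction is estimated once per recording as the normalized
mean of heavily smoothed (2 s moving average) acceleration.  Slow
orientation drift while leaning is deliberately treated as trunk-lean
signal, not as gravity change: the phone is strapped to the trunk, so a
per-sample gravity estimate would absorb the very signal the features
measure.  The *gravity-axis projection* — raw acceleration dotted with
this unit vector — isolates vertical dynamics and reads ≈1 g at rest.

## Repetition detection and timestamping

Each stand-up produces a biphasic pulse in vertical specific force
(accelerate up, brake: peak then trough); each sit-down is the mirror
image.  Detection operates on the median-detrended, filtered
gravity-axis projection (acceleration modulus is a config alternative):

1. **Extrema.** Candidate peaks and troughs with prominence ≥ 0.08 g and
   same-type spacing ≥ 0.25 s (`scipy.signal.find_peaks`); the spacing
   bound must remain below the smallest trough-to-trough gap between a
   stand-up and the next sit-down, which approaches ~0.3 s at 40
   cycles/min.  Adjacent same-type extrema are merged keeping the more
   extreme (ties: earliest).
2. **Pairing.** Consecutive opposite-type extrema within the transition
   duration bound and with amplitude ≥ 0.08 g are paired greedily left to
   right: peak-first = stand-up, trough-first = sit-down.  Weak extrema
   (e.g. ripples during dwells) fail the amplitude gate and are skipped.
3. **Timestamps.** A transition nominally spans the zero level of the
   detrended signal flanking its extrema.  Two refinements make this
   robust: boundaries are located on the FIR-only signal (the moving
   average that stabilizes extremum detection smears a one-sided onset
   outward by half its window), and instead of walking to an actual sign
   change — which sensor noise hovering around zero triggers erratically
   — the walk stops where the signal decays to 15% of the extremum
   amplitude and the local least-squares tangent (±2 samples) is
   extrapolated to zero.  On clean signals this equals the plain zero
   crossing; with 0.05 g noise it keeps the mean absolute timestamp error
   near 0.03 s.
4. **Screening.** Transition durations must lie in [0.2, 3.0] s and cycle
   durations in [1.0, 12.0] s (physiological bounds for a COPD cohort
   whose median cadence is 23 cycles/min); everything rejected is counted
   in the diagnostics.  A final stand-up whose sit-down does not fit in
   the 60 s window still counts as a repetition, following the consensus
   convention for the test; it is reported separately from the complete
   cycles.

On the synthetic benchmark (50 recordings, 10–35 cycles, σ = 0.05 g
acceleration and 2 deg/s gyro noise) the pipeline recovers ≈100% of
transitions within the 0.5 s matching tolerance with mean |Δt| ≈ 0.03 s;
these are the quantities `scripts/acceptance.py` recomputes.

## Features

Seven headline features: repetition `count`; `mean_sts_time`, the mean
stand-up transition duration; `down_pct`, seated dwell divided by
seated-plus-standing dwell within the span of complete cycles
(transitions belong to neither state); `samp_en`, sample entropy of the
filtered acceleration modulus; `acc_max`, the maximum filtered
acceleration modulus; `g_cv`, SD/|mean| of the gravity-axis projection;
and `trunk_ang`, the maximum forward trunk lean during stand-up.  They
are extended to a fixed, versioned 39-column set (`FEATURE_COLUMNS`,
tag `v1`) by per-phase duration statistics, per-axis and magnitude signal
summaries, cycle-time variability, a fatigue proxy (first-half minus
second-half completed cycles), and jerk summaries.

**Sample entropy.** SampEn(m, r) = −ln(A/B), with m = 2 and
r = 0.2·SD of the series.  Both match counts use the N−m templates that
admit an (m+1)-length extension, matched pairs only, self-matches
excluded, Chebyshev distance — the standard matched-template convention,
which keeps A ≤ B and the statistic non-negative and scale-invariant.
(Printed formulas for SampEn sometimes index N−m+1 templates at length m;
that count cannot be paired with the m+1 count one-to-one, so the matched
convention is used and is what the brute-force oracle in the tests
defines as ground truth.)  No match at length m+1 yields +∞, which the
feature layer treats as missing; zero-variance input is an error.

**Trunk lean.** A complementary filter blends integrated gyro pitch rate
(weight 0.98 per 10 ms step) with the accelerometer tilt angle, signed by
the gyro estimate.  The pitch axis is the principal component of the
angular velocity *after projecting out the gravity axis* — rotation about
gravity (yaw) cannot tilt the trunk and must not leak into pitch.  Tilt
is referenced to the mean acceleration of the first second (initial
seated posture) rather than the whole-recording gravity mean: a subject
who spends much of the minute inclined would otherwise bias the
reference toward the lean and clip the measured peak.  Missing or flat
gyro channels trigger an accelerometer-only fallback.

## Cohort generator

One latent capacity factor Z ~ N(0, 1) per subject drives everything.
6MWD is a two-sided Gaussian transform of Z — scale 100.1 m below the
median, 48.2 m above — whose quartiles equal the published 350 / 417.5 /
450 m exactly in distribution.  Each feature is linear in Z plus
independent Gaussian noise; its loading is solved in closed form so the
Pearson correlation with the transformed distance hits the published
target (count +0.77, mean transition time −0.75, down% −0.73, sample
entropy −0.69, peak acceleration +0.67, gravity CV +0.59, trunk lean
−0.57), correcting for the transform's attenuation factor
cov(Z, g(Z))/sd(g(Z)) ≈ 0.979 and, for the integer-rounded count, for the
~1/12 rounding variance.  Targets that would require |loading| ≥ 1 raise
a parameter error.  Feature medians/IQRs not published (transition time,
entropy, peak acceleration, gravity CV, lean, down%) use plausible
clinical magnitudes; they affect scale only, not the correlation
structure.  Inter-feature correlations are an emergent consequence of the
single factor, not calibration targets.

The recording simulator renders a chest-frame sensor model: trunk pitch
about a horizontal axis with raised-cosine-squared lean profiles, vertical
chest acceleration a_v = ±A·sin(2πs) per transition phase s (A = peak
modulus − 1), accelerometer = (1 + a_v)·(sin θ, cos θ) plus white noise,
gyroscope = pitch rate plus noise.  Transition boundaries are the exact
ground-truth timestamps.  `simulate_study` maps latent capacity
monotonically to kinematics (more cycles, faster transitions, larger peak
acceleration, smaller lean, smaller seated share), reproducing the signs
of all seven published correlations from raw signals alone.

What the generator does *not* emulate: multi-segment body dynamics,
arm/hand micro-motion, phone slippage, non-white sensor noise, aborted or
hesitated transitions, and chairs of varying height.  Passing tests on
this bed therefore demonstrate algorithmic correctness under the stated
sensor model, not clinical performance.

## Selection and modeling

Interactions default to pairwise products of the top-3 |r| features (not
all pairs).  Standardization stores its location/scale so held-out folds
are transformed with training-fold parameters; zero-variance columns are
dropped.  Redundancy pruning removes, from each pair with |r| > 0.90, the
member less correlated with distance, visiting pairs in descending |r|
(idempotent).  "Autocorrelation" has no intrinsic meaning across a
cross-sectional cohort's arbitrary row order, so features exceeding the
threshold at small lags are flagged in the report, never silently
dropped.  RFE (scikit-learn, step 1) on standardized features uses a
linear estimator by default (random forest optional).

Model comparison is a nested scheme: seeded shuffled outer 5-fold split;
per training fold, a 3-fold grid search over small documented grids
(forest: 200/500 trees × depth ∞/6; SVR: C ∈ {1, 10, 100}, RBF, scale γ;
boosting: learning rate 0.05/0.1, and depth 3/6 for the
gradient-boosting-tree variant), standardization inside the pipeline.
R², MAE, and Bland–Altman statistics are computed on pooled out-of-fold
predictions — one prediction per subject, which is exactly what an
agreement plot needs.  Limits of agreement use bias ± 1.96·SD with the
n−1 SD denominator.

## Numerical conventions and degenerate inputs

- Recordings: strictly increasing time, median step within 10% of 1/fs;
  isolated one-sample gaps linearly interpolated, >1% missing rejected;
  durations outside [55, 75] s warn by default (configurable to error).
  Declared-unit headers (`acc_unit`, `gyro_unit`) drive m/s² → g and
  rad/s → deg/s conversion, making double conversion impossible.
- Zero cycles: count 0, every cycle-dependent feature missing (NaN).
- Constant/flat signals: no extrema, empty segmentation, not an error.
- Equal-valued extremum ties resolve to the earliest sample.
- Segmentation JSON keeps full float precision so write→read is lossless
  to better than 1 ns.
- All stochastic components (simulators, fold shuffling, tree ensembles)
  take explicit integer seeds; identical seeds give byte-identical
  outputs.

## Problem sizes

The validation suite uses 50 benchmark recordings (≈2 300 transitions)
for segmentation accuracy, 5 000 subjects for cohort calibration
(sampling error of a correlation near 0.7 is ~0.007 there), 100 seeded
replicates for the planted-design RFE recovery rate, and 40–66-subject
cohorts for the cross-validation contracts — the scale of the clinical
study the pipeline is designed around.

## Known limitations

- The segmentation defaults assume the biphasic vertical-acceleration
  signature of free-standing sit-to-stand; hand-assisted or very slow
  (>3 s) transitions fall outside the default screening bounds.
- The trunk-lean estimator reports lean relative to initial posture and
  assumes the subject starts seated and still for ~1 s.
- The cohort generator's single-factor structure implies all features
  share one axis of variation; real cohorts may have richer structure,
  which only real recordings can supply.
- Headline clinical metrics (e.g. cohort-level R² against measured 6MWD)
  depend on data that are not redistributable and are out of scope for
  the synthetic validation here.
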